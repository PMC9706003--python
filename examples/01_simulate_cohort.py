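"""Generate a virtual TDM cohort and simulate tacrolimus concentrations.

Builds the default 139-child design (q12h oral dosing titrated toward
5-10 ug/L troughs, trough sampling 0.5 h pre-dose at three visits plus
sporadic 0.5-3 h peaks), simulates whole-blood concentrations from the
final population model, and writes a NONMEM-style CSV.
"""

import tacropk as tp

design = tp.CohortDesign(seed=20220711)
truth = tp.final_model_spec()

table, etas = tp.generate_cohort(design, truth=truth)
sim = tp.simulate_observations(table, truth, rng=1, etas=etas)

obs = sim.observations()
troughs = obs[obs["SAMPLE"] == "trough"]["DV"]
peaks = obs[obs["SAMPLE"] == "peak"]["DV"]
cov = sim.covariates()

print(f"subjects:              {sim.n_subjects}")
print(f"concentration samples: {len(obs)} ({len(peaks)} peaks)")
print(f"median age:            {cov['AGE'].median():.1f} y "
      f"(range {cov['AGE'].min():.1f}-{cov['AGE'].max():.1f})")
print(f"median weight:         {cov['WT'].median():.1f} kg")
print(f"Wuzhi co-medication:   {int(cov['COMBWZ'].sum())}/{len(cov)}")
print(f"median trough:         {troughs.median():.2f} ug/L "
      f"(target window 5-10)")
print(f"median peak:           {peaks.median():.2f} ug/L")

tp.write_event_table(sim, "virtual_cohort.csv")
print("wrote virtual_cohort.csv (ID, TIME, AMT, DV, EVID, covariates)")
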