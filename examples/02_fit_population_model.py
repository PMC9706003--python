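"""Fit the covariate-free base model and the final covariate model.

FOCE-ELS estimation with Ka fixed at 4.48 1/h.  Prints the parameter
table (estimate, SE, CV%), the -2LL objective, AIC and eta shrinkage for
both models; the OFV drop from base to final reflects the covariate
effects present in the simulated data.
"""

import tacropk as tp

truth = tp.final_model_spec()
design = tp.CohortDesign(seed=42)
table, etas = tp.generate_cohort(design, truth=truth)
sim = tp.simulate_observations(table, truth, rng=43, etas=etas)

base_fit = tp.fit_nlme(sim, tp.initial_spec(sim, tp.base_model_spec()))
final_init = tp.initial_spec(sim, truth)   # same structure, neutral start
final_fit = tp.fit_nlme(sim, final_init)

for name, fit in [("base", base_fit), ("final", final_fit)]:
    print(f"--- {name} model: OFV {fit.ofv:.2f}  AIC {fit.aic:.2f}  "
          f"shrinkage CL {fit.eta_shrinkage['cl']:.0f}% / "
          f"V {fit.eta_shrinkage['v']:.0f}%")
    print(fit.summary().round(4).to_string(index=False))

drop = base_fit.ofv - final_fit.ofv
print(f"\ncovariates drop the OFV by {drop:.1f} "
      "(chi-square thresholds: 3.84 per df at p<0.05)")
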