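"""Qualify a fitted model: GOF, VPC, NPDE and a subject-resampling bootstrap.

Prints the headline numbers of each diagnostic and saves the standard
figure layouts (DV vs PRED/IPRED + CWRES panels, VPC percentile bands,
NPDE QQ/histogram) as PNGs in the working directory.
"""

import matplotlib

matplotlib.use("Agg")

import tacropk as tp
from tacropk.diagnostics import bootstrap, npde, run_vpc
from tacropk.plots import gof_panel, npde_panel, vpc_plot

truth = tp.final_model_spec()
design = tp.CohortDesign(seed=7)
table, etas = tp.generate_cohort(design, truth=truth)
sim = tp.simulate_observations(table, truth, rng=8, etas=etas)
fit = tp.fit_nlme(sim, tp.initial_spec(sim, truth), uncertainty=False)

gof = tp.gof_quantities(fit, sim)
inside = ((gof["CWRES"] > -2) & (gof["CWRES"] < 2)).mean()
print(f"CWRES within (-2, 2): {100 * inside:.1f}% of observations "
      "(~95% expected under a correct model)")
gof_panel(gof).savefig("gof_panel.png", dpi=120)

vpc = run_vpc(fit.spec, sim, n_sim=500, rng=9)
print(f"VPC: observed percentile inside its 95% simulation band in "
      f"{100 * vpc.coverage():.0f}% of bin/percentile cells")
vpc_plot(vpc).figure.savefig("vpc.png", dpi=120)

res = npde(fit.spec, sim, n_sim=1000, rng=10)
print("NPDE: mean {mean:.3f}, variance {variance:.3f}, "
      "normality p {shapiro_p:.2f}".format(**res.tests))
npde_panel(res).savefig("npde_panel.png", dpi=120)

boot = bootstrap(sim, fit.spec, n_boot=100, rng=11,
                 restarts=1, maxiter=60, outer_tol=1e-8)
print(f"bootstrap ({len(boot.replicates)} converged of 100 replicates):")
print(boot.summary.round(3).to_string(index=False))
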