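"""Predict individual clearance from the screened covariates with six
machine-learning regressors.

The regression target is each subject's empirical-Bayes clearance from
the population fit; features are the PPK-screened covariates (age, Wuzhi
co-medication, CYP3A5 *3/*3 and the CTLA4 level indicators).  The
protocol repeats {70/30 split, 5-fold-CV grid search, held-out scoring}
five times and reports the mean metrics per algorithm.
"""

import tacropk as tp
from tacropk.ml import build_ml_table, run_protocol

truth = tp.final_model_spec()
design = tp.CohortDesign(seed=7)
table, etas = tp.generate_cohort(design, truth=truth)
sim = tp.simulate_observations(table, truth, rng=8, etas=etas)
fit = tp.fit_nlme(sim, tp.initial_spec(sim, truth), uncertainty=False)

ml = build_ml_table(fit, sim)
print(f"feature table: {len(ml)} subjects x {ml.shape[1] - 2} features; "
      f"target = EBE clearance (median {ml['CL'].median():.2f} L/h)")

report = run_protocol(ml, seed=1)
cols = ["algorithm", "R2", "MSE", "MAE", "MedAE", "RE", "RMSE"]
print(report[cols].round(3).to_string(index=False))
print("\nR2 is bounded by the variance fraction the covariates explain; "
      "residual IIV is irreducible noise for any regressor.")
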