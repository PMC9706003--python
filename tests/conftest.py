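"""Shared fixtures: small virtual cohorts and a reference final-model fit.

Everything is generated programmatically and deterministically; the heavy
final-cohort fit is session-scoped so diagnostics, GOF and ML tests reuse
one estimation run.
"""

import numpy as np
import pytest

import tacropk as tp


@pytest.fixture(scope="session")
def truth_spec():
    return tp.final_model_spec()


@pytest.fixture(scope="session")
def study_sim(truth_spec):
    """One full-size (139-subject) cohort simulated from the final model."""
    design = tp.CohortDesign(seed=7)
    table, etas = tp.generate_cohort(design)
    sim = tp.simulate_observations(table, truth_spec, rng=8, etas=etas)
    return sim, etas


@pytest.fixture(scope="session")
def study_fit(study_sim, truth_spec):
    """Final-model fit of the study-sized cohort (shared across tests)."""
    sim, _ = study_sim
    init = tp.initial_spec(sim, truth_spec)
    fit = tp.fit_nlme(sim, init, uncertainty=False)
    assert np.isfinite(fit.ofv)
    return fit


@pytest.fixture(scope="session")
def small_sim():
    """A 40-subject cohort simulated from the covariate-free base model."""
    base = tp.base_model_spec()
    design = tp.CohortDesign(n_subjects=40, seed=11)
    table, etas = tp.generate_cohort(design, truth=base)
    sim = tp.simulate_observations(table, base, rng=12, etas=etas)
    return sim
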