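"""One-compartment oral PK model with covariate sub-models.

Structural model: first-order absorption into a single disposition
compartment with first-order elimination, all parameters apparent
(CL/F, V/F; bioavailability is not separately identified from oral
data).  After a single dose D at t=0,

    C(t) = D * ka / (V * (ka - k)) * (exp(-k t) - exp(-ka t)),   k = CL/V,

with the continuous limit D * ka * t * exp(-k t) / V when ka -> k.
Multiple dosing is handled by superposition (the model is linear in dose).

Between-subject variability is log-normal:  P_i = TV(P) * exp(eta_i),
eta ~ N(0, omega^2), on CL and V.  Covariates scale the typical value:

    continuous:   TV(P) * (cov / cov_ref) ** theta     (cov_ref = cohort median)
    categorical:  TV(P) * exp(theta * indicator)

Residual error supports additive, proportional, combined and exponential
(log-transform-both-sides) forms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "StructuralParams",
    "CovariateTerm",
    "ModelSpec",
    "conc_single_dose",
    "conc_profile",
    "residual_variance",
    "covariate_factors",
    "individual_params",
    "base_model_spec",
    "final_model_spec",
]

#: relative tolerance below which ka and k are treated as equal (flip-flop
#: degeneracy of the biexponential closed form)
_KA_K_RTOL = 1e-8

ERROR_MODELS = ("additive", "proportional", "combined", "exponential")


@dataclass(frozen=True)
class StructuralParams:
    """Individual structural parameters: ka (1/h), cl (L/h), v (L)."""

    ka: float
    cl: float
    v: float

    def __post_init__(self):
        for name in ("ka", "cl", "v"):
            if not np.all(np.asarray(getattr(self, name)) > 0):
                raise ValueError(f"{name} must be strictly positive")

    @property
    def k(self):
        """Elimination rate constant (1/h)."""
        return self.cl / self.v


@dataclass(frozen=True)
class CovariateTerm:
    """One covariate effect on a structural parameter.

    ``kind="power"`` needs a positive ``reference`` (the covariate median,
    frozen into the fitted model); ``kind="indicator"`` multiplies by
    exp(theta * x) for a 0/1 column.
    """

    parameter: str          # "cl" or "v"
    covariate: str          # covariate column name
    kind: str               # "power" | "indicator"
    reference: float | None = None

    def __post_init__(self):
        if self.parameter not in ("cl", "v"):
            raise ValueError("parameter must be 'cl' or 'v'")
        if self.kind not in ("power", "indicator"):
            raise ValueError("kind must be 'power' or 'indicator'")
        if self.kind == "power" and not (self.reference and self.reference > 0):
            raise ValueError("power terms need a positive reference value")

    @property
    def key(self) -> str:
        return f"{self.parameter}~{self.covariate}"


@dataclass
class ModelSpec:
    """Full population model: structural + covariate + random effects + error.

    ``theta`` maps each covariate term's key to its coefficient; ``sigma``
    is a scalar for single-scale error models and a (prop, add) pair for
    the combined model.
    """

    tv_cl: float
    tv_v: float
    ka: float = 4.48
    covariate_terms: tuple = ()
    theta: dict = field(default_factory=dict)
    omega2_cl: float = 0.1
    omega2_v: float = 0.1
    error_model: str = "proportional"
    sigma: float | tuple = 0.2

    def __post_init__(self):
        if self.error_model not in ERROR_MODELS:
            raise ValueError(f"unknown error model {self.error_model!r}")
        if self.error_model == "combined":
            if np.ndim(self.sigma) != 1 or len(self.sigma) != 2:
                raise ValueError("combined error model needs sigma=(prop, add)")
        for term in self.covariate_terms:
            self.theta.setdefault(term.key, 0.0)

    @property
    def omega(self) -> np.ndarray:
        return np.diag([self.omega2_cl, self.omega2_v])

    def with_updates(self, **kw) -> "ModelSpec":
        out = replace(self, **{k: v for k, v in kw.items() if k != "theta"})
        if "theta" in kw:
            out.theta = dict(kw["theta"])
        else:
            out.theta = dict(self.theta)
        return out

    def add_terms(self, terms) -> "ModelSpec":
        out = self.with_updates()
        out.covariate_terms = tuple(self.covariate_terms) + tuple(terms)
        for t in terms:
            out.theta.setdefault(t.key, 0.0)
        return out

    def drop_terms(self, keys) -> "ModelSpec":
        keys = set(keys)
        out = self.with_updates()
        out.covariate_terms = tuple(
            t for t in self.covariate_terms if t.key not in keys
        )
        out.theta = {k: v for k, v in out.theta.items() if k not in keys}
        return out


# -- concentration closed forms -----------------------------------------

def conc_single_dose(dose, t, p: StructuralParams):
    """Concentration (ug/L) at ``t`` hours after one oral dose (ug).

    Vectorized over ``t``.  Negative times (before the dose) contribute 0.
    """
    t = np.asarray(t, dtype=float)
    k = p.cl / p.v
    active = t >= 0
    tt = np.where(active, t, 0.0)
    if abs(p.ka - k) < _KA_K_RTOL * p.ka:
        c = dose * p.ka * tt * np.exp(-k * tt) / p.v
    else:
        c = (
            dose * p.ka / (p.v * (p.ka - k))
            * (np.exp(-k * tt) - np.exp(-p.ka * tt))
        )
    c = np.where(active, c, 0.0)
    return c if c.ndim else float(c)


def conc_profile(dose_amounts, dose_times, times, p: StructuralParams):
    """Superposed concentration at each of ``times`` given a dosing history.

    Doses at times after an evaluation point contribute nothing.  Evaluation
    times must be sorted (contract shared with the estimation engine).
    """
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) < 0):
        raise ValueError("evaluation times must be sorted non-decreasing")
    dose_amounts = np.asarray(dose_amounts, dtype=float)
    dose_times = np.asarray(dose_times, dtype=float)
    if dose_amounts.shape != dose_times.shape:
        raise ValueError("dose amounts and times must align")
    out = np.zeros_like(times)
    for amt, td in zip(dose_amounts, dose_times):
        out += conc_single_dose(amt, times - td, p)
    return out


def residual_variance(pred, error_model: str, sigma):
    """Residual variance of an observation given its model prediction.

    additive: sigma^2; proportional: (sigma*pred)^2; combined:
    (sigma1*pred)^2 + sigma2^2.  The exponential model is fitted on the
    log scale where it is additive, so its variance here is sigma^2 in
    log-concentration units.
    """
    pred = np.asarray(pred, dtype=float)
    if np.any(pred < 0):
        raise ValueError("predictions must be non-negative")
    if error_model == "additive" or error_model == "exponential":
        out = np.full_like(pred, float(sigma) ** 2)
    elif error_model == "proportional":
        out = (float(sigma) * pred) ** 2
    elif error_model == "combined":
        s1, s2 = sigma
        out = (s1 * pred) ** 2 + s2 ** 2
    else:
        raise ValueError(f"unknown error model {error_model!r}")
    return out if out.ndim else float(out)


# -- covariate machinery -------------------------------------------------

def covariate_factors(spec: ModelSpec, cov: "pd.DataFrame"):
    """Multiplicative covariate factors on CL and V for each subject row.

    Returns ``(factor_cl, factor_v)`` arrays aligned with ``cov``'s rows.
    """
    n = len(cov)
    fac = {"cl": np.ones(n), "v": np.ones(n)}
    for term in spec.covariate_terms:
        theta = spec.theta[term.key]
        x = np.asarray(cov[term.covariate], dtype=float)
        if term.kind == "power":
            if np.any(x <= 0):
                raise ValueError(
                    f"non-positive {term.covariate} with a power term"
                )
            fac[term.parameter] = fac[term.parameter] * (x / term.reference) ** theta
        else:
            fac[term.parameter] = fac[term.parameter] * np.exp(theta * x)
    return fac["cl"], fac["v"]


def individual_params(spec: ModelSpec, cov_row, eta=(0.0, 0.0)) -> StructuralParams:
    """Individual (ka, CL_i, V_i) for one subject.

    ``cov_row`` is a mapping/Series of covariate values; ``eta`` the
    subject's (eta_CL, eta_V).
    """
    import pandas as pd

    cov = pd.DataFrame([dict(cov_row)])
    fcl, fv = covariate_factors(spec, cov)
    eta = np.asarray(eta, dtype=float)
    return StructuralParams(
        ka=spec.ka,
        cl=spec.tv_cl * float(fcl[0]) * float(np.exp(eta[0])),
        v=spec.tv_v * float(fv[0]) * float(np.exp(eta[1])),
    )


# -- published model presets --------------------------------------------

#: cohort median age (years) frozen into the fitted covariate model
AGE_REFERENCE = 5.3


def base_model_spec() -> ModelSpec:
    """Covariate-free model: Ka=4.48 fixed, CL=7.05*exp(etaCL), V=144.52*exp(etaV)."""
    return ModelSpec(
        tv_cl=7.05,
        tv_v=144.52,
        ka=4.48,
        omega2_cl=0.13,
        omega2_v=1.13,
        error_model="proportional",
        sigma=0.2995,
    )


def final_model_spec() -> ModelSpec:
    """Fitted final model.

    CL (L/h) = 10.54 * (AGE/5.3)^0.31 * exp(-0.34*CTLA4_GA)
               * exp(-0.15*CTLA4_AA) * exp(-0.25*CYP3A5_33)
               * exp(-0.34*COMBWZ) * exp(etaCL),
    V (L)    = 192.03 * exp(etaV),
    omega2_CL = 0.13, omega2_V = 1.13, proportional sigma = 0.2995.
    """
    terms = (
        CovariateTerm("cl", "AGE", "power", reference=AGE_REFERENCE),
        CovariateTerm("cl", "CTLA4_GA", "indicator"),
        CovariateTerm("cl", "CTLA4_AA", "indicator"),
        CovariateTerm("cl", "CYP3A5_33", "indicator"),
        CovariateTerm("cl", "COMBWZ", "indicator"),
    )
    theta = {
        "cl~AGE": 0.31,
        "cl~CTLA4_GA": -0.34,
        "cl~CTLA4_AA": -0.15,
        "cl~CYP3A5_33": -0.25,
        "cl~COMBWZ": -0.34,
    }
    return ModelSpec(
        tv_cl=10.54,
        tv_v=192.03,
        ka=4.48,
        covariate_terms=terms,
        theta=theta,
        omega2_cl=0.13,
        omega2_v=1.13,
        error_model="proportional",
        sigma=0.2995,
    )
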