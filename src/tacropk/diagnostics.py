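"""Simulation-based model qualification: VPC, bootstrap, NPDE.

All three diagnostics re-simulate the fitted model at the observed design
(doses, sampling times, covariates), so a sparse trough-dominated dataset
is compared against what the model itself would generate for the same
patients.  Binning for the VPC follows the study design rather than
uniform time cuts: peaks (0.5-3 h post-dose) form their own bin and
troughs are binned by monitoring visit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .events import EventTable
from .foce import PredictionEngine, fit_nlme
from .model import ModelSpec, covariate_factors

__all__ = ["VPCResult", "BootstrapResult", "NPDEResult",
           "run_vpc", "bootstrap", "npde"]


# ----------------------------------------------------------------------
# shared simulation helper
# ----------------------------------------------------------------------

def _simulate_matrix(engine: PredictionEngine, spec: ModelSpec,
                     cov: pd.DataFrame, rng, n_sim: int) -> np.ndarray:
    """(n_sim, n_obs) matrix of datasets simulated at the observed design."""
    fcl, fv = covariate_factors(spec, cov)
    out = np.empty((n_sim, engine.n_obs))
    for r in range(n_sim):
        eta = rng.multivariate_normal(np.zeros(2), spec.omega,
                                      size=engine.n_subjects)
        f = engine.predict(
            spec.tv_cl * fcl * np.exp(eta[:, 0]),
            spec.tv_v * fv * np.exp(eta[:, 1]),
            spec.ka,
        )
        if spec.error_model == "additive":
            y = f + float(spec.sigma) * rng.standard_normal(engine.n_obs)
        elif spec.error_model == "proportional":
            y = f * (1.0 + float(spec.sigma) * rng.standard_normal(engine.n_obs))
        elif spec.error_model == "combined":
            s1, s2 = spec.sigma
            y = (f * (1.0 + s1 * rng.standard_normal(engine.n_obs))
                 + s2 * rng.standard_normal(engine.n_obs))
        elif spec.error_model == "exponential":
            y = f * np.exp(float(spec.sigma) * rng.standard_normal(engine.n_obs))
        else:
            raise ValueError(f"unknown error model {spec.error_model!r}")
        out[r] = y
    return out


def _prep(table: EventTable, spec_unused=None):
    table = table.with_indicators()
    engine = PredictionEngine(table)
    cov = table.covariates().set_index("ID").loc[engine.subject_ids].reset_index()
    return table, engine, cov


def _time_after_dose(table: EventTable, engine: PredictionEngine) -> np.ndarray:
    tad = np.full(engine.n_obs, np.nan)
    df = table.df
    for i, idx in enumerate(engine.obs_index):
        row = df.loc[idx]
        prior = df[(df["ID"] == row["ID"]) & (df["EVID"] == 1)
                   & (df["TIME"] <= row["TIME"])]
        if not prior.empty:
            tad[i] = row["TIME"] - prior["TIME"].iloc[-1]
    return tad


# ----------------------------------------------------------------------
# VPC
# ----------------------------------------------------------------------

@dataclass
class VPCResult:
    """Observed percentiles per bin with simulation-based confidence bands."""

    bins: pd.DataFrame          # one row per (bin, percentile)
    n_sim: int
    percentiles: tuple = (5, 50, 95)

    def coverage(self) -> float:
        """Fraction of (bin, percentile) cells whose observed value lies
        inside its simulated 95% band."""
        b = self.bins
        inside = (b["observed"] >= b["band_lo"]) & (b["observed"] <= b["band_hi"])
        return float(inside.mean())


def _assign_bins(table, engine, n_trough_bins):
    """Bin label per observation: peak bin + per-visit trough bins."""
    tad = _time_after_dose(table, engine)
    df = table.df.loc[engine.obs_index]
    if "SAMPLE" in df.columns and df["SAMPLE"].notna().any():
        is_peak = (df["SAMPLE"] == "peak").to_numpy()
    else:
        is_peak = tad <= 4.0
    labels = np.empty(engine.n_obs, dtype=object)
    labels[is_peak] = "peak"
    tr_times = engine.obs_time[~is_peak]
    if len(tr_times):
        edges = np.quantile(
            tr_times, np.linspace(0, 1, min(n_trough_bins, len(tr_times)) + 1)
        )
        edges = np.unique(edges)
        which = np.clip(
            np.searchsorted(edges, tr_times, side="right") - 1,
            0, max(len(edges) - 2, 0),
        )
        labels[~is_peak] = [f"trough_{w}" for w in which]
    return labels


def run_vpc(spec: ModelSpec, table: EventTable, n_sim=500, n_trough_bins=3,
            rng=None, percentiles=(5, 50, 95), min_bin=5) -> VPCResult:
    """Visual predictive check of a (fitted) model against a dataset.

    Simulates ``n_sim`` replicate datasets under ``spec`` at the observed
    design, and per bin compares the observed 5th/50th/95th percentiles
    with the 2.5-97.5% band of the same percentile across replicates.
    Bins with fewer than ``min_bin`` observations are merged into their
    neighbor.
    """
    rng = np.random.default_rng(rng)
    table, engine, cov = _prep(table)
    labels = _assign_bins(table, engine, n_trough_bins)
    # merge undersized trough bins leftward
    counts = pd.Series(labels).value_counts()
    order = sorted(set(labels), key=lambda s: (s == "peak", s))
    for i, lab in enumerate(order):
        if counts.get(lab, 0) < min_bin and i > 0:
            labels[labels == lab] = order[i - 1]
    sims = _simulate_matrix(engine, spec, cov, rng, n_sim)
    rows = []
    for lab in sorted(set(labels)):
        mask = labels == lab
        for p in percentiles:
            obs_p = float(np.percentile(engine.y[mask], p))
            sim_p = np.percentile(sims[:, mask], p, axis=1)
            rows.append(
                {
                    "bin": lab,
                    "n": int(mask.sum()),
                    "percentile": p,
                    "observed": obs_p,
                    "sim_median": float(np.median(sim_p)),
                    "band_lo": float(np.percentile(sim_p, 2.5)),
                    "band_hi": float(np.percentile(sim_p, 97.5)),
                }
            )
    return VPCResult(bins=pd.DataFrame(rows), n_sim=n_sim,
                     percentiles=tuple(percentiles))


# ----------------------------------------------------------------------
# bootstrap
# ----------------------------------------------------------------------

@dataclass
class BootstrapResult:
    """Replicate parameter estimates with medians and 95% percentile CIs."""

    replicates: pd.DataFrame
    summary: pd.DataFrame          # parameter, median, ci_lo, ci_hi
    convergence_rate: float
    reliable: bool = True

    def ci(self, name):
        row = self.summary.set_index("parameter").loc[name]
        return float(row["ci_lo"]), float(row["ci_hi"])


def bootstrap(table: EventTable, spec: ModelSpec, n_boot=1000, rng=None,
              indices_list=None, **fit_kw) -> BootstrapResult:
    """Nonparametric bootstrap: resample subjects with replacement, refit.

    The resampling unit is the subject (all of a subject's rows move
    together, preserving within-subject correlation); each replicate
    keeps the original subject count.  The covariate-model *structure*
    is fixed — only parameters are re-estimated.  Replicates whose fit
    fails are dropped and counted; a convergence rate below 80% flags
    the result unreliable.
    """
    rng = np.random.default_rng(rng)
    table = table.with_indicators()
    ids = table.subject_ids
    n = len(ids)
    rows, n_fail = [], 0
    for b in range(n_boot):
        if indices_list is not None:
            take = np.asarray(indices_list[b])
        else:
            take = rng.integers(0, n, size=n)
        sub = table.subset(ids[take], relabel=True)
        try:
            fit = fit_nlme(sub, spec, uncertainty=False, **fit_kw)
            if not np.isfinite(fit.ofv):
                raise RuntimeError("non-finite OFV")
        except Exception:
            n_fail += 1
            continue
        from .foce import _named_parameters

        rows.append({"replicate": b, **_named_parameters(fit.spec)})
    reps = pd.DataFrame(rows)
    conv = len(rows) / n_boot if n_boot else 0.0
    summary = []
    for col in reps.columns.drop("replicate") if len(reps) else []:
        vals = reps[col].to_numpy()
        summary.append(
            {
                "parameter": col,
                "median": float(np.median(vals)),
                "ci_lo": float(np.percentile(vals, 2.5)),
                "ci_hi": float(np.percentile(vals, 97.5)),
            }
        )
    return BootstrapResult(
        replicates=reps,
        summary=pd.DataFrame(summary),
        convergence_rate=conv,
        reliable=conv >= 0.8,
    )


# ----------------------------------------------------------------------
# NPDE
# ----------------------------------------------------------------------

@dataclass
class NPDEResult:
    """Normalized prediction distribution errors and their global tests."""

    table: pd.DataFrame            # ID, TIME, npde
    tests: dict = field(default_factory=dict)

    @property
    def values(self) -> np.ndarray:
        return self.table["npde"].to_numpy()


def npde(spec: ModelSpec, table: EventTable, n_sim=1000, rng=None,
         ridge=1e-8) -> NPDEResult:
    """Normalized prediction distribution errors under ``spec``.

    Per subject, ``n_sim`` observation vectors are simulated; observed and
    simulated vectors are decorrelated with the simulated mean and the
    lower-triangular Cholesky factor of the simulated covariance
    (ridge-regularized if near singular); the prediction discrepancy
    pde_j is the fraction of simulated values below the observed one,
    clamped to (1/(2 n_sim), 1 - 1/(2 n_sim)); npde = Phi^-1(pde).

    Under a correct model the npde are approximately iid N(0,1); the
    returned tests are a t-test of mean 0, a chi-square test of unit
    variance, a Shapiro-Wilk normality test, and a KS test against N(0,1).
    """
    rng = np.random.default_rng(rng)
    table, engine, cov = _prep(table)
    sims = _simulate_matrix(engine, spec, cov, rng, n_sim)
    y = engine.y
    npde_vals = np.empty(engine.n_obs)
    clamp = 1.0 / (2.0 * n_sim)
    for si in range(engine.n_subjects):
        mask = engine.obs_subj == si
        S = sims[:, mask]                       # (n_sim, n_i)
        m = S.mean(axis=0)
        C = np.cov(S, rowvar=False)
        C = np.atleast_2d(C)
        try:
            L = np.linalg.cholesky(C)
        except np.linalg.LinAlgError:
            C = C + ridge * np.eye(C.shape[0]) * max(1.0, np.trace(C))
            L = np.linalg.cholesky(C)
        y_dec = np.linalg.solve(L, y[mask] - m)
        s_dec = np.linalg.solve(L, (S - m).T)   # (n_i, n_sim)
        pde = (s_dec < y_dec[:, None]).mean(axis=1)
        pde = np.clip(pde, clamp, 1.0 - clamp)
        npde_vals[mask] = stats.norm.ppf(pde)

    t_stat, t_p = stats.ttest_1samp(npde_vals, 0.0)
    nv = len(npde_vals)
    var = float(np.var(npde_vals, ddof=1))
    chi2_stat = (nv - 1) * var
    var_p = 2.0 * min(stats.chi2.cdf(chi2_stat, nv - 1),
                      stats.chi2.sf(chi2_stat, nv - 1))
    sw_stat, sw_p = stats.shapiro(npde_vals)
    ks_stat, ks_p = stats.kstest(npde_vals, "norm")
    obs = table.df.loc[engine.obs_index]
    out = pd.DataFrame(
        {"ID": obs["ID"].to_numpy(), "TIME": obs["TIME"].to_numpy(),
         "DV": y, "npde": npde_vals}
    )
    return NPDEResult(
        table=out,
        tests={
            "mean": float(npde_vals.mean()),
            "variance": var,
            "t_p": float(t_p),
            "var_p": float(var_p),
            "shapiro_p": float(sw_p),
            "ks_p": float(ks_p),
        },
    )
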