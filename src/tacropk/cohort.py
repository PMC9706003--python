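"""Virtual study cohorts: covariates, genotypes, TDM dosing, simulation.

The study population this generator emulates is a pediatric refractory
nephrotic syndrome cohort on oral tacrolimus: 139 subjects, q12h dosing
of 500-3000 ug per dose titrated by therapeutic drug monitoring toward
trough concentrations of 5-10 ug/L, sampling dominated by pre-dose
troughs (drawn half an hour before the morning dose at scheduled visits)
plus occasional peaks 0.5-3 h post-dose, and twelve genotyped SNPs at
the cohort's allele frequencies under Hardy-Weinberg equilibrium.

The generator is the stand-in for the (undeposited) patient data: every
parameter-recovery and calibration experiment in this package simulates
from it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .events import EventTable, SNP_COLUMNS
from .model import ModelSpec, covariate_factors, conc_profile, StructuralParams, final_model_spec

__all__ = [
    "SNP_TABLE",
    "CohortDesign",
    "allele_frequency",
    "hwe_chi_square",
    "hwe_exact_test",
    "sample_genotypes",
    "generate_cohort",
    "simulate_observations",
]


@dataclass(frozen=True)
class SNPInfo:
    """Genotype counts and allele labels for one SNP of the study cohort."""

    column: str
    genotypes: tuple          # (hom_A, het, hom_B) labels, A = first allele
    counts: tuple             # observed subject counts in the same order
    alleles: tuple            # (A, B) labels
    reported_freq: float      # printed frequency of allele A

    @property
    def freq(self) -> float:
        return allele_frequency(*self.counts)


#: Observed genotype distribution of the 139-subject cohort (the input the
#: allele-frequency and HWE operations run on, and the frequencies the
#: genotype sampler reproduces).
SNP_TABLE = (
    SNPInfo("CYP3A5_rs776746", ("*1/*1", "*1/*3", "*3/*3"), (18, 58, 63),
            ("*1", "*3"), 0.338),
    SNPInfo("MYH9_rs2239781", ("TT", "TC", "CC"), (52, 64, 23),
            ("T", "C"), 0.604),
    SNPInfo("LAMB2_rs62119873", ("AA", "AG", "GG"), (73, 56, 10),
            ("A", "G"), 0.727),
    SNPInfo("ACTN4_rs62121818", ("CC", "CT", "TT"), (27, 61, 51),
            ("C", "T"), 0.414),
    SNPInfo("ACTN4_rs3745859", ("TT", "TC", "CC"), (28, 60, 51),
            ("T", "C"), 0.417),
    SNPInfo("MAP3K11_rs7946115", ("CC", "CG", "GG"), (3, 31, 105),
            ("C", "G"), 0.133),
    SNPInfo("ACTN4_rs56113315", ("TT", "TC", "CC"), (51, 60, 28),
            ("T", "C"), 0.582),
    SNPInfo("MYH9_rs4821478", ("AA", "AG", "GG"), (11, 43, 85),
            ("A", "G"), 0.233),
    SNPInfo("INF2_rs1128880", ("GG", "GT", "TT"), (3, 24, 112),
            ("G", "T"), 0.108),
    SNPInfo("IL2RA_rs12722489", ("CC", "CT", "TT"), (110, 26, 3),
            ("C", "T"), 0.885),
    SNPInfo("NPHS2_rs2274622", ("CC", "CT", "TT"), (22, 53, 64),
            ("C", "T"), 0.349),
    SNPInfo("CTLA4_rs4553808", ("GG", "GA", "AA"), (2, 29, 108),
            ("G", "A"), 0.119),
)

assert tuple(s.column for s in SNP_TABLE) == SNP_COLUMNS


# ----------------------------------------------------------------------
# genotype arithmetic
# ----------------------------------------------------------------------

def allele_frequency(hom_a, het, hom_b) -> float:
    """Frequency of allele A from genotype counts (AA, AB, BB)."""
    counts = np.asarray([hom_a, het, hom_b], dtype=float)
    if np.any(counts < 0):
        raise ValueError("genotype counts must be non-negative")
    total = counts.sum()
    if total == 0:
        raise ValueError("allele frequency undefined for all-zero counts")
    return float((2 * counts[0] + counts[1]) / (2 * total))


def hwe_chi_square(hom_a, het, hom_b):
    """Pearson chi-square test of Hardy-Weinberg proportions (df=1).

    Expected counts are n*(p^2, 2pq, q^2) at the estimated allele
    frequency.  Monomorphic samples return (0.0, 1.0) by convention.
    """
    n = hom_a + het + hom_b
    if n <= 0:
        raise ValueError("empty genotype sample")
    p = allele_frequency(hom_a, het, hom_b)
    if p in (0.0, 1.0):
        return 0.0, 1.0
    expected = n * np.array([p ** 2, 2 * p * (1 - p), (1 - p) ** 2])
    observed = np.array([hom_a, het, hom_b], dtype=float)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    return chi2, float(stats.chi2.sf(chi2, df=1))


def hwe_exact_test(hom_a, het, hom_b) -> float:
    """Exact SNP-HWE p-value (sum of probabilities of heterozygote counts
    no more likely than the observed one, conditioning on allele counts)."""
    n = hom_a + het + hom_b
    if n <= 0:
        raise ValueError("empty genotype sample")
    rare = min(2 * hom_a + het, 2 * hom_b + het)
    if rare == 0:
        return 1.0
    # probabilities over all heterozygote counts with the same parity
    het_min = rare % 2
    hets = np.arange(het_min, rare + 1, 2)
    logp = np.zeros(len(hets))
    for i in range(1, len(hets)):
        h = hets[i]
        n_rr = (rare - h) / 2
        n_cc = (2 * n - rare - h) / 2
        # P(h)/P(h-2) = 4 * n_rr_prev * n_cc_prev / (h * (h - 1))
        logp[i] = logp[i - 1] + math.log(
            4.0 * (n_rr + 1) * (n_cc + 1) / (h * (h - 1))
        )
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    obs_p = prob[np.searchsorted(hets, het)]
    return float(min(1.0, prob[prob <= obs_p * (1 + 1e-12)].sum()))


def sample_genotypes(n, snps=SNP_TABLE, rng=None) -> pd.DataFrame:
    """Independent Hardy-Weinberg genotype draws for each SNP (no linkage)."""
    if n < 1:
        raise ValueError("need n >= 1")
    rng = np.random.default_rng(rng)
    out = {}
    for snp in snps:
        p = snp.freq
        probs = [p ** 2, 2 * p * (1 - p), (1 - p) ** 2]
        out[snp.column] = rng.choice(snp.genotypes, size=n, p=probs)
    return pd.DataFrame(out)


# ----------------------------------------------------------------------
# cohort design and generation
# ----------------------------------------------------------------------

@dataclass
class CohortDesign:
    """Study-design knobs for the virtual cohort.

    Defaults reproduce the study conditions: 139 subjects, right-skewed
    ages with median 5.3 y in [1.1, 15.6], weights on an age-indexed
    growth curve clamped to [9.5, 88] kg, 6/139 Wuzhi co-administration,
    q12h dosing of 500-3000 ug titrated toward 5-10 ug/L troughs, trough
    sampling 0.5 h pre-dose at three monitoring visits plus sporadic
    peaks 0.5-3 h post-dose (~432 samples of which ~35 peaks).
    """

    n_subjects: int = 139
    # covariate laws (medians/ranges of the study cohort)
    age_median: float = 5.3
    age_sigma: float = 0.55
    age_range: tuple = (1.1, 15.6)
    weight_median: float = 19.7
    weight_exponent: float = 0.75
    weight_sigma: float = 0.18
    weight_range: tuple = (9.5, 88.0)
    male_p: float = 37 / 139
    alb_median: float = 18.3
    alb_sigma: float = 0.35
    alb_range: tuple = (7.6, 46.8)
    hct_mean: float = 41.2
    hct_sd: float = 5.0
    hct_range: tuple = (23.4, 55.0)   # upper bound chosen physiologic
    comb_wz_p: float = 6 / 139
    snps: tuple = SNP_TABLE
    # dosing and sampling
    dose_per_kg: float = 25.0         # ug/kg per 12 h starting dose
    dose_step: float = 250.0          # titration increment, ug
    dose_range: tuple = (500.0, 3000.0)
    tau: float = 12.0                 # h between doses
    visit_days: tuple = (14, 28, 56)
    trough_p: float = 0.95            # P(trough drawn at a visit)
    peak_p: float = 0.084             # P(peak drawn at a visit)
    peak_window: tuple = (0.5, 3.0)   # h after the visit dose
    trough_offset: float = 0.5        # h before the visit dose
    target_range: tuple = (5.0, 10.0)  # ug/L trough target
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1 or not self.visit_days:
            raise ValueError("design needs >=1 subject and >=1 visit")
        for p in (self.trough_p, self.peak_p, self.comb_wz_p, self.male_p):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        lo, hi = self.dose_range
        if not (500.0 <= lo <= hi <= 3000.0):
            raise ValueError("dose bounds must lie within 500-3000 ug")


def _truncated_lognormal(rng, median, sigma, lo, hi, size):
    out = np.empty(size)
    mu = math.log(median)
    for i in range(size):
        for _ in range(1000):
            x = rng.lognormal(mu, sigma)
            if lo <= x <= hi:
                out[i] = x
                break
        else:
            out[i] = np.clip(math.exp(mu), lo, hi)
    return out


def _draw_covariates(design: CohortDesign, rng) -> pd.DataFrame:
    n = design.n_subjects
    age = _truncated_lognormal(
        rng, design.age_median, design.age_sigma, *design.age_range, size=n
    )
    wt_mean = design.weight_median * (age / design.age_median) ** design.weight_exponent
    wt = np.clip(
        wt_mean * rng.lognormal(0.0, design.weight_sigma, size=n),
        *design.weight_range,
    )
    alb = np.clip(
        rng.lognormal(math.log(design.alb_median), design.alb_sigma, size=n),
        *design.alb_range,
    )
    hct = np.clip(
        rng.normal(design.hct_mean, design.hct_sd, size=n), *design.hct_range
    )
    cov = pd.DataFrame(
        {
            "ID": np.arange(1, n + 1),
            "AGE": np.round(age, 2),
            "WT": np.round(wt, 1),
            "SEX": (rng.random(n) < design.male_p).astype(int),
            "ALB": np.round(alb, 1),
            "HCT": np.round(hct, 1),
            "COMBWZ": (rng.random(n) < design.comb_wz_p).astype(int),
        }
    )
    geno = sample_genotypes(n, design.snps, rng)
    return pd.concat([cov, geno], axis=1)


def _starting_dose(design: CohortDesign, wt: float) -> float:
    raw = design.dose_per_kg * wt
    dose = round(raw / design.dose_step) * design.dose_step
    return float(np.clip(dose, *design.dose_range))


def generate_cohort(design: CohortDesign, truth: ModelSpec | None = None,
                    rng=None):
    """Generate a virtual cohort: dosing + sampling-time design, no DV yet.

    Returns ``(table, etas)``.  ``table`` contains EVID=1 dose rows and
    EVID=0 observation rows with ``DV`` empty (``MDV=1``); pass both to
    :func:`simulate_observations` to fill in concentrations.  ``etas``
    are the per-subject random effects drawn here — dose titration reacts
    to each virtual patient's *true* (noise-free) trough under ``truth``,
    as a TDM clinic reacts to the real patient.
    """
    truth = truth if truth is not None else final_model_spec()
    rng = np.random.default_rng(design.seed if rng is None else rng)
    cov = _draw_covariates(design, rng)

    cov_ind = cov.copy()
    from .events import INDICATOR_CODING

    for name, (col, levels) in INDICATOR_CODING.items():
        if col in cov_ind.columns:
            cov_ind[name] = cov_ind[col].isin(levels).astype(int)
    fcl, fv = covariate_factors(truth, cov_ind)
    eta = rng.multivariate_normal(np.zeros(2), truth.omega, size=design.n_subjects)
    cl_i = truth.tv_cl * fcl * np.exp(eta[:, 0])
    v_i = truth.tv_v * fv * np.exp(eta[:, 1])

    visit_times = [24.0 * d for d in design.visit_days]
    rows = []
    for s in range(design.n_subjects):
        sid = int(cov.loc[s, "ID"])
        covariate_cells = cov.loc[s].drop("ID").to_dict()
        params = StructuralParams(ka=truth.ka, cl=cl_i[s], v=v_i[s])
        dose = _starting_dose(design, cov.loc[s, "WT"])
        dose_times, dose_amts = [], []
        obs_times, obs_kind = [], []
        t = 0.0
        for v_idx, tv in enumerate(visit_times):
            while t < tv - 1e-9:
                dose_times.append(t)
                dose_amts.append(dose)
                t += design.tau
            # true trough just before the visit's morning dose
            t_trough = tv - design.trough_offset
            true_trough = conc_profile(
                dose_amts, dose_times, [t_trough], params
            )[0]
            if rng.random() < design.trough_p:
                obs_times.append(t_trough)
                obs_kind.append("trough")
            # titrate: step the dose toward the target window
            lo, hi = design.target_range
            if true_trough < lo:
                dose = min(dose + design.dose_step, design.dose_range[1])
            elif true_trough > hi:
                dose = max(dose - design.dose_step, design.dose_range[0])
            # the visit's morning dose (possibly adjusted)
            dose_times.append(tv)
            dose_amts.append(dose)
            t = tv + design.tau
            if rng.random() < design.peak_p:
                obs_times.append(tv + rng.uniform(*design.peak_window))
                obs_kind.append("peak")
        if not obs_times:
            # a monitored patient always has at least one level drawn
            obs_times.append(visit_times[-1] - design.trough_offset)
            obs_kind.append("trough")
        for td, amt in zip(dose_times, dose_amts):
            rows.append(
                {"ID": sid, "TIME": td, "AMT": amt, "DV": np.nan, "EVID": 1,
                 "MDV": 1, **covariate_cells}
            )
        for to, kind in zip(obs_times, obs_kind):
            rows.append(
                {"ID": sid, "TIME": to, "AMT": np.nan, "DV": np.nan,
                 "EVID": 0, "MDV": 1, "SAMPLE": kind, **covariate_cells}
            )
    df = pd.DataFrame(rows).sort_values(["ID", "TIME"], kind="stable")
    df["SAMPLE"] = df.get("SAMPLE", pd.Series(index=df.index, dtype=object))
    table = EventTable(df.reset_index(drop=True))
    etas = pd.DataFrame(
        {"ID": cov["ID"], "eta_cl": eta[:, 0], "eta_v": eta[:, 1]}
    )
    return table, etas


def simulate_observations(table: EventTable, spec: ModelSpec, rng=None,
                          etas: pd.DataFrame | None = None,
                          lloq: float = 0.5) -> EventTable:
    """Fill the DV of every observation row by simulating from ``spec``.

    Per subject, random effects are drawn from N(0, Omega) unless ``etas``
    provides them (e.g. the draws stored by :func:`generate_cohort`, so
    that concentrations stay consistent with the titrated doses).
    Residual error follows the model's error form.  Concentrations below
    ``lloq`` are flagged (column ``BLQ``), not censored; the assay never
    reports non-positive values, so non-positive noisy draws are redrawn.
    """
    from .foce import PredictionEngine  # local import to avoid a cycle

    rng = np.random.default_rng(rng)
    table = table.with_indicators()
    engine = PredictionEngine(table, include_missing_dv=True)
    cov = table.covariates().set_index("ID").loc[engine.subject_ids].reset_index()
    fcl, fv = covariate_factors(spec, cov)
    if etas is None:
        eta = rng.multivariate_normal(
            np.zeros(2), spec.omega, size=engine.n_subjects
        )
    else:
        eta = (
            etas.set_index("ID")
            .loc[engine.subject_ids, ["eta_cl", "eta_v"]]
            .to_numpy()
        )
    cl = spec.tv_cl * fcl * np.exp(eta[:, 0])
    v = spec.tv_v * fv * np.exp(eta[:, 1])
    f = engine.predict(cl, v, spec.ka)

    y = np.empty_like(f)
    pending = np.ones(len(f), dtype=bool)
    for _ in range(100):
        n = int(pending.sum())
        if n == 0:
            break
        fp = f[pending]
        if spec.error_model == "additive":
            draw = fp + float(spec.sigma) * rng.standard_normal(n)
        elif spec.error_model == "proportional":
            draw = fp * (1.0 + float(spec.sigma) * rng.standard_normal(n))
        elif spec.error_model == "combined":
            s1, s2 = spec.sigma
            draw = fp * (1.0 + s1 * rng.standard_normal(n)) + s2 * rng.standard_normal(n)
        elif spec.error_model == "exponential":
            draw = fp * np.exp(float(spec.sigma) * rng.standard_normal(n))
        else:
            raise ValueError(f"unknown error model {spec.error_model!r}")
        y[pending] = draw
        pending[pending] = ~(draw > 0)
    y[pending] = np.maximum(f[pending], lloq)  # pathological fallback

    df = table.df.copy()
    df.loc[engine.obs_index, "DV"] = y
    df.loc[engine.obs_index, "MDV"] = 0
    df["BLQ"] = 0
    df.loc[engine.obs_index, "BLQ"] = (y < lloq).astype(int)
    return EventTable(df)
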