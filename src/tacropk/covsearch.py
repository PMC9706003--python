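"""Stepwise covariate model building on OFV chi-square thresholds.

Forward inclusion adds, one at a time, the candidate whose single addition
drops the objective the most, as long as the drop exceeds 3.84 (chi-square,
df=1, p<0.05); this repeats until no candidate qualifies.  Backward
elimination then removes, least significant first, any retained candidate
whose deletion raises the objective by no more than 6.63 (p<0.01), until
every remaining term is indispensable at that level.

Continuous covariates enter as power terms normalized to the cohort
median; categorical covariates as exp(theta * indicator) terms.  A
three-level genotype enters as a block of per-level indicators against
the major-homozygote reference; the block is added and removed jointly
but judged by the scalar df=1 thresholds.  CYP3A5 is the exception,
coded as the field-standard expresser / non-expresser binary (*3/*3
versus *1 carrier).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .events import EventTable, SNP_COLUMNS, INDICATOR_CODING
from .foce import FitResult, fit_nlme
from .model import CovariateTerm, ModelSpec

__all__ = [
    "Candidate",
    "build_candidates",
    "univariate_prescreen",
    "materialize_indicators",
    "forward_step",
    "backward_step",
    "stepwise_search",
]

FORWARD_THRESHOLD = 3.84
BACKWARD_THRESHOLD = 6.63

#: clinical covariates screened before the SNPs, in fixed order
CLINICAL_CANDIDATES = ("AGE", "WT", "SEX", "ALB", "HCT", "COMBWZ")
_CONTINUOUS = {"AGE", "WT", "ALB", "HCT"}


@dataclass(frozen=True)
class Candidate:
    """One tested covariate relation: a term (or indicator block) on CL or V."""

    name: str
    parameter: str
    terms: tuple  # CovariateTerm(s); >1 for multi-level genotype blocks

    @property
    def keys(self):
        return tuple(t.key for t in self.terms)


def _snp_candidate(table: EventTable, snp: str, parameter: str) -> Candidate | None:
    """Indicator-block candidate for one genotype column (None if monomorphic)."""
    calls = table.covariates()[snp]
    levels = calls.value_counts()
    if len(levels) < 2:
        return None
    if snp == "CYP3A5_rs776746":
        # expresser / non-expresser binary
        if (calls == "*3/*3").nunique() < 2:
            return None
        term = CovariateTerm(parameter, "CYP3A5_33", "indicator")
        return Candidate(f"{snp}[{parameter}]", parameter, (term,))
    if snp == "CTLA4_rs4553808":
        names = [n for n, (c, lv) in INDICATOR_CODING.items()
                 if c == snp and calls.isin(lv).any()]
        terms = tuple(CovariateTerm(parameter, n, "indicator") for n in names)
        return Candidate(f"{snp}[{parameter}]", parameter, terms)
    reference = levels.index[0]  # most frequent call
    terms = tuple(
        CovariateTerm(parameter, f"{snp}__{lv}", "indicator")
        for lv in levels.index[1:]
    )
    return Candidate(f"{snp}[{parameter}]", parameter, terms)


def build_candidates(table: EventTable, parameters=("cl",),
                     clinical=CLINICAL_CANDIDATES, snps=SNP_COLUMNS):
    """Ordered candidate set: clinical covariates first, then SNPs.

    Continuous clinical covariates become power terms referenced to the
    cohort median; binary ones become exp(theta*x) indicator terms.
    Monomorphic SNPs and absent columns are skipped.
    """
    cov = table.covariates()
    out = []
    for parameter in parameters:
        for name in clinical:
            if name not in cov.columns:
                continue
            if name in _CONTINUOUS:
                ref = float(cov[name].median())
                term = CovariateTerm(parameter, name, "power", reference=ref)
            else:
                if cov[name].nunique() < 2:
                    continue
                term = CovariateTerm(parameter, name, "indicator")
            out.append(Candidate(f"{name}[{parameter}]", parameter, (term,)))
        for snp in snps:
            if snp not in cov.columns:
                continue
            cand = _snp_candidate(table, snp, parameter)
            if cand is not None:
                out.append(cand)
    return out


def materialize_indicators(table: EventTable, candidates) -> EventTable:
    """Add the 0/1 indicator columns the candidates' terms refer to."""
    table = table.with_indicators()
    df = table.df
    new = {}
    for cand in candidates:
        for term in cand.terms:
            col = term.covariate
            if term.kind != "indicator" or col in df.columns or col in new:
                continue
            if "__" in col:
                src, level = col.rsplit("__", 1)
                new[col] = (df[src] == level).astype(int)
    if new:
        df = df.copy()
        for col, vals in new.items():
            df[col] = vals
        table = EventTable(df)
    return table


# ----------------------------------------------------------------------
# univariate SNP pre-screen
# ----------------------------------------------------------------------

def dose_normalized_troughs(table: EventTable) -> pd.DataFrame:
    """Per-subject mean trough concentration divided by the current dose.

    Troughs are identified by the ``SAMPLE`` column when present, else as
    observations drawn at least 8 h after the most recent dose.
    """
    rows = []
    for sid, grp in table.df.groupby("ID", sort=False):
        doses = grp[grp["EVID"] == 1]
        obs = grp[(grp["EVID"] == 0) & (grp["MDV"] == 0)]
        vals = []
        for _, r in obs.iterrows():
            prior = doses[doses["TIME"] <= r["TIME"]]
            if prior.empty:
                continue
            last = prior.iloc[-1]
            tad = r["TIME"] - last["TIME"]
            is_trough = (
                r.get("SAMPLE") == "trough"
                if "SAMPLE" in r and pd.notna(r.get("SAMPLE"))
                else tad >= 8.0
            )
            if is_trough:
                vals.append(r["DV"] / last["AMT"])
        if vals:
            rows.append({"ID": sid, "dn_trough": float(np.mean(vals))})
    return pd.DataFrame(rows)


def univariate_prescreen(table: EventTable, snps=SNP_COLUMNS, alpha=0.1,
                         parameters=("cl",)):
    """Rank-based SNP screen merged with the clinical candidates.

    Kruskal-Wallis test of per-subject dose-normalized trough means across
    genotype groups; SNPs with p < alpha survive.  Returns
    ``(candidates, screen_log)`` where candidates holds the clinical set
    followed by the surviving SNP blocks.
    """
    dnt = dose_normalized_troughs(table)
    cov = table.covariates().merge(dnt, on="ID")
    kept, log = [], []
    for snp in snps:
        if snp not in cov.columns:
            continue
        groups = [g["dn_trough"].to_numpy() for _, g in cov.groupby(snp)]
        if len(groups) < 2:
            log.append({"snp": snp, "p": np.nan, "kept": False,
                        "note": "monomorphic"})
            continue
        _, p = stats.kruskal(*groups)
        keep = bool(p < alpha)
        log.append({"snp": snp, "p": float(p), "kept": keep, "note": ""})
        if keep:
            kept.append(snp)
    candidates = build_candidates(table, parameters=parameters, snps=tuple(kept))
    return candidates, pd.DataFrame(log)


# ----------------------------------------------------------------------
# stepwise search
# ----------------------------------------------------------------------

def _model_key(spec: ModelSpec):
    return tuple(sorted(t.key for t in spec.covariate_terms))


def _try_fit(table, spec, cache=None, **fit_kw):
    """Fit a candidate model, consulting/storing a per-search cache.

    Caching by covariate-term set makes backward eliminations of recently
    added terms exact replays of the forward fits that produced them.
    """
    key = _model_key(spec)
    if cache is not None and key in cache:
        return cache[key]
    try:
        fit = fit_nlme(table, spec, uncertainty=False, **fit_kw)
    except Exception:
        fit = None
    if fit is not None and not np.isfinite(fit.ofv):
        fit = None
    if cache is not None:
        cache[key] = fit
    return fit


def forward_step(fit: FitResult, table: EventTable, candidates,
                 threshold=FORWARD_THRESHOLD, cache=None, **fit_kw):
    """Test each remaining candidate singly; accept the largest qualifying drop.

    Returns ``(new_fit_or_None, accepted_candidate_or_None, entries)``.
    Candidates whose fit fails count as no improvement.
    """
    in_model = {t.key for t in fit.spec.covariate_terms}
    entries, results = [], []
    for cand in candidates:
        if any(k in in_model for k in cand.keys):
            continue
        aug = fit.spec.add_terms(cand.terms)
        for t in cand.terms:
            aug.theta[t.key] = 0.0
        cand_fit = _try_fit(table, aug, cache=cache, **fit_kw)
        if cand_fit is None:
            entries.append({"phase": "forward", "candidate": cand.name,
                            "delta_ofv": np.nan, "decision": "failed"})
            continue
        d_ofv = fit.ofv - cand_fit.ofv
        entries.append({"phase": "forward", "candidate": cand.name,
                        "delta_ofv": d_ofv, "decision": "tested"})
        results.append((d_ofv, cand, cand_fit))
    best = max(results, key=lambda r: r[0], default=None)
    if best is None or best[0] <= threshold:
        return None, None, entries
    d_ofv, cand, cand_fit = best
    entries.append({"phase": "forward", "candidate": cand.name,
                    "delta_ofv": d_ofv, "decision": "accepted"})
    return cand_fit, cand, entries


def backward_step(fit: FitResult, table: EventTable, accepted,
                  threshold=BACKWARD_THRESHOLD, cache=None, **fit_kw):
    """Delete the least significant removable candidate, if any.

    Each accepted candidate is removed singly; the one whose removal
    raises the OFV the least is deleted when that rise is <= threshold.
    Returns ``(new_fit_or_None, removed_candidate_or_None, entries)``.
    """
    entries, results = [], []
    if not accepted:
        entries.append({"phase": "backward", "candidate": None,
                        "delta_ofv": np.nan, "decision": "no-terms"})
        return None, None, entries
    for cand in accepted:
        reduced = fit.spec.drop_terms(cand.keys)
        red_fit = _try_fit(table, reduced, cache=cache, **fit_kw)
        if red_fit is None:
            entries.append({"phase": "backward", "candidate": cand.name,
                            "delta_ofv": np.nan, "decision": "failed"})
            continue
        d_ofv = red_fit.ofv - fit.ofv
        entries.append({"phase": "backward", "candidate": cand.name,
                        "delta_ofv": d_ofv, "decision": "tested"})
        results.append((d_ofv, cand, red_fit))
    weakest = min(results, key=lambda r: r[0], default=None)
    if weakest is None or weakest[0] > threshold:
        return None, None, entries
    d_ofv, cand, red_fit = weakest
    entries.append({"phase": "backward", "candidate": cand.name,
                    "delta_ofv": d_ofv, "decision": "removed"})
    return red_fit, cand, entries


def stepwise_search(table: EventTable, base_spec: ModelSpec, candidates,
                    forward_threshold=FORWARD_THRESHOLD,
                    backward_threshold=BACKWARD_THRESHOLD, **fit_kw):
    """Forward inclusion to exhaustion, then backward elimination to stability.

    Deterministic given the data and candidate order.  Returns
    ``(final_fit, trace)`` where trace is a step-by-step DataFrame.
    """
    table = materialize_indicators(table, candidates)
    cache: dict = {}
    fit = fit_nlme(table, base_spec, uncertainty=False, **fit_kw)
    cache[_model_key(fit.spec)] = fit
    trace = []
    accepted: list[Candidate] = []
    while True:
        new_fit, cand, entries = forward_step(
            fit, table, candidates, forward_threshold, cache=cache, **fit_kw
        )
        trace.extend(entries)
        if new_fit is None:
            break
        fit, _ = new_fit, accepted.append(cand)
    while accepted:
        new_fit, removed, entries = backward_step(
            fit, table, accepted, backward_threshold, cache=cache, **fit_kw
        )
        trace.extend(entries)
        if new_fit is None:
            break
        fit = new_fit
        accepted.remove(removed)
    return fit, pd.DataFrame(trace)
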