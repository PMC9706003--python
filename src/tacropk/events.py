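"""NONMEM-style event tables for sparse therapeutic-drug-monitoring data.

The estimation dataset is a longitudinal event table in the NONMEM column
dialect: one row per dosing or observation event, identified by ``EVID``
(1 = dose, 0 = observation), with ``ID``, ``TIME`` (hours since the
subject's first dose), ``AMT`` (dose in ug) and ``DV`` (whole-blood
concentration in ug/L).  Subject-level covariates (demographics, labs,
co-medication, genotype calls) ride along as extra columns, constant
within subject.

Genotypes are stored as text calls (``"*1/*3"``, ``"GA"``); the coding
maps in this module translate them into the 0/1 indicator columns the
covariate models consume.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

#: Mandatory event columns, NONMEM convention.
CORE_COLUMNS = ("ID", "TIME", "AMT", "DV", "EVID")

#: SNP columns in the order they are screened (clinical covariates come first
#: in candidate lists; SNPs follow in this order).
SNP_COLUMNS = (
    "CYP3A5_rs776746",
    "MYH9_rs2239781",
    "LAMB2_rs62119873",
    "ACTN4_rs62121818",
    "ACTN4_rs3745859",
    "MAP3K11_rs7946115",
    "ACTN4_rs56113315",
    "MYH9_rs4821478",
    "INF2_rs1128880",
    "IL2RA_rs12722489",
    "NPHS2_rs2274622",
    "CTLA4_rs4553808",
)

CLINICAL_COLUMNS = ("AGE", "WT", "SEX", "ALB", "HCT", "COMBWZ")

#: Derived 0/1 indicators and the genotype calls that switch them on.
#: CYP3A5 is coded expresser / non-expresser: the *3/*3 indicator is 1 only
#: for homozygous non-expressers.  CTLA4 rs4553808 carries one indicator per
#: non-GG level (GA, AA), i.e. GG homozygotes are the reference class.
INDICATOR_CODING = {
    "CYP3A5_33": ("CYP3A5_rs776746", ("*3/*3",)),
    "CTLA4_GA": ("CTLA4_rs4553808", ("GA",)),
    "CTLA4_AA": ("CTLA4_rs4553808", ("AA",)),
}


class EventTableError(ValueError):
    """Malformed or invalid event-table input."""


@dataclass
class EventTable:
    """Validated per-subject dosing/observation records with covariates.

    Wraps a :class:`pandas.DataFrame` whose rows are events.  Within each
    subject, times are non-decreasing.  ``MDV=1`` marks observation rows
    whose ``DV`` has not been (or will not be) filled — simulation
    templates produced by the cohort generator use this.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.df = _validate(self.df)

    # -- basic accessors -------------------------------------------------
    @property
    def subject_ids(self) -> np.ndarray:
        return self.df["ID"].unique()

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def doses(self) -> pd.DataFrame:
        return self.df[self.df["EVID"] == 1]

    def observations(self, with_dv_only: bool = False) -> pd.DataFrame:
        obs = self.df[self.df["EVID"] == 0]
        if with_dv_only:
            obs = obs[obs["DV"].notna()]
        return obs

    @property
    def n_observations(self) -> int:
        return int((self.df["EVID"] == 0).sum())

    @property
    def n_doses(self) -> int:
        return int((self.df["EVID"] == 1).sum())

    def covariates(self) -> pd.DataFrame:
        """One row per subject with the non-core columns (first occurrence)."""
        extra = [c for c in self.df.columns if c not in CORE_COLUMNS + ("MDV",)]
        return (
            self.df.groupby("ID", sort=False)[extra].first().reset_index()
        )

    def with_indicators(self) -> "EventTable":
        """Return a copy with the derived genotype indicator columns added."""
        df = self.df.copy()
        for name, (col, levels) in INDICATOR_CODING.items():
            if col in df.columns and name not in df.columns:
                df[name] = df[col].isin(levels).astype(int)
        return EventTable(df)

    def subset(self, subject_ids, relabel: bool = False) -> "EventTable":
        """Rows of the given subjects, in the given order (with repeats).

        ``relabel=True`` assigns fresh sequential IDs, so a subject drawn
        twice by a bootstrap resample becomes two distinct subjects.
        """
        parts = []
        for new_id, sid in enumerate(subject_ids, start=1):
            block = self.df[self.df["ID"] == sid].copy()
            if relabel:
                block["ID"] = new_id
            parts.append(block)
        return EventTable(pd.concat(parts, ignore_index=True))


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CORE_COLUMNS if c not in df.columns]
    if missing:
        raise EventTableError(f"missing mandatory column(s): {missing}")
    df = df.copy()
    if "MDV" not in df.columns:
        df["MDV"] = np.where(df["EVID"] == 0, df["DV"].isna().astype(int), 1)
    bad_evid = ~df["EVID"].isin([0, 1])
    if bad_evid.any():
        raise EventTableError(
            f"EVID must be 0 or 1; offending rows {list(df.index[bad_evid][:5])}"
        )
    neg_t = df["TIME"] < 0
    if neg_t.any():
        raise EventTableError(
            f"negative TIME at rows {list(df.index[neg_t][:5])}"
        )
    doses = df["EVID"] == 1
    if df.loc[doses, "AMT"].isna().any() or (df.loc[doses, "AMT"] <= 0).any():
        raise EventTableError("dose rows (EVID=1) must carry positive AMT")
    obs = df["EVID"] == 0
    if df.loc[obs, "AMT"].notna().any():
        raise EventTableError("observation rows (EVID=0) must not carry AMT")
    measured = obs & (df["MDV"] == 0)
    nonpos = measured & ~(df["DV"] > 0)
    if nonpos.any():
        raise EventTableError(
            f"non-positive DV at observation rows {list(df.index[nonpos][:5])}"
        )
    # within-subject time monotonicity
    for sid, grp in df.groupby("ID", sort=False):
        t = grp["TIME"].to_numpy()
        if np.any(np.diff(t) < 0):
            raise EventTableError(f"times not non-decreasing for subject {sid!r}")
    return df.reset_index(drop=True)


def read_event_table(path_or_buf, coding=None) -> EventTable:
    """Read a NONMEM-style CSV (ID, TIME, AMT, DV, EVID, covariates).

    ``coding`` optionally maps column name -> {text: value} recodings applied
    before validation (e.g. ``{"SEX": {"M": 1, "F": 0}}``).
    """
    df = pd.read_csv(path_or_buf)
    if coding:
        for col, mapping in coding.items():
            if col in df.columns:
                df[col] = df[col].map(mapping).fillna(df[col])
    return EventTable(df)


def write_event_table(table: EventTable, path_or_buf) -> None:
    """Write a CSV readable by :func:`read_event_table`, full float precision."""
    table.df.to_csv(path_or_buf, index=False)


def round_trip(table: EventTable) -> EventTable:
    """write -> read in memory; used by property tests."""
    buf = io.StringIO()
    write_event_table(table, buf)
    buf.seek(0)
    return read_event_table(buf)


# -- run configuration ---------------------------------------------------

@dataclass
class RunConfig:
    """Structured run settings shared by the pipeline stages."""

    ka: float = 4.48              # 1/h, fixed absorption rate constant
    error_model: str = "proportional"
    seed: int = 20220711
    n_sim_vpc: int = 500
    n_sim_npde: int = 1000
    n_boot: int = 1000
    forward_threshold: float = 3.84   # chi-square df=1, p<0.05
    backward_threshold: float = 6.63  # chi-square df=1, p<0.01
    initial: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)
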