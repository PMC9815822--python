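"""Genotype-stratified Kaplan-Meier survival estimation.

Fits the product-limit estimator per patient group (curve fitting is
delegated to lifelines) and reports the median overall survival per group:
the smallest observed time at which the survival function falls to 0.5 or
below.  No between-group test is computed here — the deliverable is the
stratified curves and medians.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

logger = logging.getLogger(__name__)

#: tumor-genotype strata used in the prostate-cancer analysis
CANONICAL_GROUPS = ("PTEN_ATAD1_null", "PTEN_null", "unaltered")


@dataclass(frozen=True)
class SurvivalRecord:
    """One patient: follow-up time in months and death (1) / censoring (0)."""

    patient_id: str
    group: str
    time: float
    event: int

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError(f"patient {self.patient_id!r}: time must be positive")
        if self.event not in (0, 1):
            raise ValueError(f"patient {self.patient_id!r}: event must be 0 or 1")


@dataclass
class KMCurve:
    """Product-limit estimate evaluated at the distinct death times.

    ``survival[i]`` is S(times[i]) just after the deaths at times[i] are
    processed; ``at_risk[i]`` is the risk-set size just before.  Ties of
    death and censoring at the same time follow the standard convention:
    deaths are processed first, censored subjects leave afterwards.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(np.diff(self.survival) > 1e-12) or np.any(self.survival > 1):
            raise ValueError("survival must be non-increasing and <= 1")


def km_fit(records: Sequence[SurvivalRecord]) -> KMCurve:
    """Fit the Kaplan-Meier product-limit estimator to one group of patients."""
    if len(records) == 0:
        raise ValueError("no survival records")
    durations = np.array([r.time for r in records])
    events = np.array([r.event for r in records])
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=events)
    table = kmf.event_table
    death_rows = table[table["observed"] > 0]
    times = death_rows.index.to_numpy(float)
    at_risk = death_rows["at_risk"].to_numpy(float).astype(int)
    surv = kmf.survival_function_at_times(times).to_numpy(float)
    return KMCurve(times, surv, at_risk)


#: sentinel returned when the survival curve never falls to 0.5
MEDIAN_UNDEFINED = None


def median_survival(curve: KMCurve) -> float | None:
    """Median survival: the smallest time t with S(t) <= 0.5.

    Returns ``None`` when the curve never reaches 0.5 (the median is not
    estimable from the follow-up available).  The step function is not
    interpolated.  A relative tolerance of 1e-9 absorbs floating-point
    round-off when the curve hits one half exactly (e.g. an even number of
    uncensored subjects).
    """
    below = curve.survival <= 0.5 * (1 + 1e-9)
    if not below.any():
        return MEDIAN_UNDEFINED
    return float(curve.times[np.argmax(below)])


def stratify(
    records: Sequence[SurvivalRecord],
    groups: Sequence[str] | None = None,
) -> dict[str, tuple[KMCurve, float | None]]:
    """Independent Kaplan-Meier fit and median per patient group.

    With ``groups`` given, a record outside that set is an error and
    requested groups with zero records are omitted with a warning;
    otherwise the groups observed in the data are used.
    """
    if groups is not None:
        allowed = set(groups)
        for r in records:
            if r.group not in allowed:
                raise ValueError(f"unknown group label {r.group!r}")
    by_group: dict[str, list[SurvivalRecord]] = {}
    for r in records:
        by_group.setdefault(r.group, []).append(r)
    if groups is not None:
        for g in groups:
            if g not in by_group:
                logger.warning("group %r has no records; omitted", g)
    out = {}
    for g in sorted(by_group):
        curve = km_fit(by_group[g])
        out[g] = (curve, median_survival(curve))
    return out


def read_survival(
    path: str | Path,
    time_col: str = "time_months",
    event_col: str = "event",
    group_col: str = "group",
    id_col: str = "patient_id",
) -> list[SurvivalRecord]:
    """Read a survival table (TSV/CSV by extension) with configurable columns."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    for col in (id_col, group_col, time_col, event_col):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    records = [
        SurvivalRecord(str(r[id_col]), str(r[group_col]), float(r[time_col]), int(r[event_col]))
        for _, r in df.iterrows()
    ]
    ids = [r.patient_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate patient_id")
    return records


def write_survival(records: Sequence[SurvivalRecord], path: str | Path) -> None:
    """Write survival records to the TSV interchange form."""
    df = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "group": [r.group for r in records],
            "time_months": [r.time for r in records],
            "event": [r.event for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)
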