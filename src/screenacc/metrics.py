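"""Confusion tables and diagnostic metrics for a dichotomized biomarker.

A continuous biomarker (here FeNO in integer ppb) is turned into a binary
screening test by a strict-greater cutoff; against a binary disease flag
this yields a 2x2 table and the four classical screening metrics
(sensitivity, specificity, positive and negative predictive value).

Metrics are kept as proportions in [0, 1]; zero-denominator cases are an
explicit ``None`` ("undefined"), never silently coerced to 0 or 1.
Rendering to percent happens only in the report layer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("screenacc")

#: Canonical cohort CSV header. ``feno_ppb`` may be empty (missing
#: measurement); the seven indicators are strictly "0"/"1".
COHORT_COLUMNS = (
    "child_id",
    "feno_ppb",
    "asthma",
    "cough_night",
    "cough_day",
    "rhinitis",
    "dyspnoea_night",
    "dyspnoea_day",
    "wheeze",
)

#: Questionnaire indicator columns (the outcome panel).
INDICATOR_COLUMNS = COHORT_COLUMNS[2:]


@dataclass(frozen=True)
class Cutoff:
    """A strict-greater screening threshold on integer ppb values.

    ``Cutoff(19)`` calls a measurement positive iff ``value > 19``, i.e.
    >=20 on integer data; the ``>19/>24/>34`` and ``>=20/>=25/>=35``
    readings coincide for integer ppb.
    """

    threshold: int

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError(f"cutoff threshold must be positive, got {self.threshold}")

    def __str__(self) -> str:  # table row label, e.g. ">19"
        return f">{self.threshold}"


@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _ratio(num: int, den: int) -> Optional[float]:
    return None if den == 0 else num / den


@dataclass(frozen=True)
class DiagnosticMetrics:
    """SEN/SPE/PPV/NPV as proportions; ``None`` marks an undefined metric
    (zero denominator), which propagates rather than masquerading as 0."""

    sen: Optional[float]
    spe: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]

    def defined(self) -> bool:
        """True when sensitivity and specificity are both defined."""
        return self.sen is not None and self.spe is not None


def dichotomize(values: Sequence[float], cutoff: Cutoff) -> np.ndarray:
    """Apply the strict-greater rule: flag positive iff value > threshold.

    Raises ``ValueError`` on negative or missing values; records with a
    missing biomarker must be excluded upstream.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size and np.isnan(arr).any():
        raise ValueError("missing biomarker values must be excluded before dichotomizing")
    if arr.size and (arr < 0).any():
        raise ValueError("biomarker values must be non-negative ppb")
    return (arr > cutoff.threshold).astype(np.int8)


def confusion_table(test_flags: Sequence[int], disease_flags: Sequence[int]) -> ConfusionTable:
    """Tally the 2x2 table of binary test calls against binary disease flags."""
    t = np.asarray(test_flags, dtype=np.int8)
    d = np.asarray(disease_flags, dtype=np.int8)
    if t.shape != d.shape:
        raise ValueError(f"length mismatch: {t.shape} test flags vs {d.shape} disease flags")
    for name, a in (("test", t), ("disease", d)):
        if a.size and not np.isin(a, (0, 1)).all():
            raise ValueError(f"{name} flags must be exactly 0 or 1")
    return ConfusionTable(
        tp=int(np.sum((t == 1) & (d == 1))),
        fp=int(np.sum((t == 1) & (d == 0))),
        fn=int(np.sum((t == 0) & (d == 1))),
        tn=int(np.sum((t == 0) & (d == 0))),
    )


def diagnostic_metrics(ct: ConfusionTable) -> DiagnosticMetrics:
    """SEN = TP/(TP+FN), SPE = TN/(TN+FP), PPV = TP/(TP+FP), NPV = TN/(TN+FN)."""
    return DiagnosticMetrics(
        sen=_ratio(ct.tp, ct.tp + ct.fn),
        spe=_ratio(ct.tn, ct.tn + ct.fp),
        ppv=_ratio(ct.tp, ct.tp + ct.fp),
        npv=_ratio(ct.tn, ct.tn + ct.fn),
    )


def screen(values: Sequence[float], disease_flags: Sequence[int], cutoff: Cutoff) -> DiagnosticMetrics:
    """Dichotomize and evaluate in one step (convenience wrapper)."""
    return diagnostic_metrics(confusion_table(dichotomize(values, cutoff), disease_flags))


# ---------------------------------------------------------------------------
# Cohort CSV I/O

def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort table in the canonical dialect.

    Returns a DataFrame with ``feno_ppb`` as nullable float (NaN = missing
    measurement) and indicator columns as int8. Validates the header, the
    0/1 coding of indicators and non-negativity of the biomarker.
    """
    df = pd.read_csv(path, dtype={"child_id": str})
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV missing columns: {missing}")
    df = df.loc[:, list(COHORT_COLUMNS)]
    df["feno_ppb"] = pd.to_numeric(df["feno_ppb"], errors="raise")
    if (df["feno_ppb"].dropna() < 0).any():
        raise ValueError("feno_ppb contains negative values")
    for col in INDICATOR_COLUMNS:
        vals = pd.to_numeric(df[col], errors="raise")
        if not vals.isin([0, 1]).all():
            raise ValueError(f"indicator column {col!r} must be strictly 0/1")
        df[col] = vals.astype(np.int8)
    n_missing = int(df["feno_ppb"].isna().sum())
    if n_missing:
        logger.info("cohort: %d of %d records have a missing FeNO measurement", n_missing, len(df))
    return df


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    """Write a cohort table byte-reproducibly (LF line endings, no index)."""
    out = df.loc[:, list(COHORT_COLUMNS)].copy()
    # integer ppb rendered without a trailing ".0"; missing stays empty
    out["feno_ppb"] = out["feno_ppb"].map(
        lambda v: "" if pd.isna(v) else str(int(v))
    )
    out.to_csv(path, index=False, lineterminator="\n")
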