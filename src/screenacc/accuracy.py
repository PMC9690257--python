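"""Prevalence-weighted accuracy and the accuracy-by-prevalence grid.

The central statistic: for a screening test with sensitivity SEN and
specificity SPE applied in a population with disease prevalence p, the
overall fraction of correct classifications is

    Accuracy(p) = p * SEN + (1 - p) * SPE

Accuracy is affine in p, bounded by [min(SEN, SPE), max(SEN, SPE)], and
strictly decreasing in p exactly when SEN < SPE — the regime of FeNO and
most screening biomarkers, which is why screening accuracy erodes as the
condition becomes more common.

``build_accuracy_table`` assembles the study-style grid: one row per
(outcome, cutoff), one accuracy column per prevalence (the observed one
plus a simulated ladder), and the per-outcome AUC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .metrics import DiagnosticMetrics


def prevalence_weighted_accuracy(p: float, sen: Optional[float], spe: Optional[float]) -> Optional[float]:
    """p*SEN + (1-p)*SPE; undefined (None) inputs propagate to None."""
    if sen is None or spe is None:
        return None
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"prevalence must be in [0, 1], got {p}")
    for name, v in (("sen", sen), ("spe", spe)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be a proportion in [0, 1], got {v}")
    return p * sen + (1.0 - p) * spe


def accuracy_sweep(
    sen: float, spe: float, grid: Sequence[float]
) -> list[tuple[float, float]]:
    """Evaluate the accuracy line over an ordered prevalence grid."""
    if len(grid) == 0:
        raise ValueError("prevalence grid must be non-empty")
    out = []
    for p in grid:
        if not 0.0 < p < 1.0:
            raise ValueError(f"sweep prevalences must lie strictly in (0, 1), got {p}")
        out.append((p, prevalence_weighted_accuracy(p, sen, spe)))
    return out


def default_sweep_grid() -> np.ndarray:
    """Prevalence ladder 1%..50% in 1-point steps (covers both the low
    screening-prevalence range and the simulated grid)."""
    return np.round(np.arange(0.01, 0.501, 0.01), 2)


def observed_prevalence(disease_flags: Sequence[int]) -> float:
    """count(positive) / n, unrounded."""
    arr = np.asarray(disease_flags)
    if arr.size == 0:
        raise ValueError("cannot compute a prevalence from an empty sequence")
    return float(np.mean(arr))


def truncate_prevalence_percent(p: float) -> float:
    """Truncate a prevalence to a whole percent (0.0823 -> 0.08).

    The published accuracy grid's real-prevalence column is reproducible
    only under this convention; the package computes with exact
    prevalences by default and exposes this for reconciliation.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"prevalence must be in [0, 1], got {p}")
    return math.floor(p * 100.0) / 100.0


@dataclass(frozen=True)
class PrevalenceGrid:
    """Observed prevalence plus an ascending simulated ladder."""

    observed: Optional[float]
    simulated: tuple[float, ...] = (0.20, 0.30, 0.40, 0.50)

    def __post_init__(self) -> None:
        if self.observed is not None and not 0.0 < self.observed < 1.0:
            raise ValueError(f"observed prevalence must lie in (0, 1), got {self.observed}")
        sims = tuple(self.simulated)
        if any(not 0.0 < p < 1.0 for p in sims):
            raise ValueError("simulated prevalences must lie strictly in (0, 1)")
        if list(sims) != sorted(set(sims)):
            raise ValueError("simulated prevalences must be ascending without duplicates")


def build_accuracy_table(
    metrics: Mapping[tuple[str, int], DiagnosticMetrics],
    observed: Mapping[str, float],
    simulated: Sequence[float] = (0.20, 0.30, 0.40, 0.50),
    auc: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """Assemble the accuracy grid as a DataFrame.

    Rows: MultiIndex (outcome, cutoff), in input order. Columns: ``auc``
    (repeated down an outcome's rows; NaN when unknown), ``real``
    (accuracy at the exact observed prevalence; NaN when no observed
    prevalence is supplied for the outcome), then one column per
    simulated prevalence labelled e.g. ``s20``.

    Rows whose sensitivity or specificity is undefined are dropped rather
    than half-filled.
    """
    PrevalenceGrid(observed=None, simulated=tuple(simulated))  # validate ladder
    auc = auc or {}
    rows = []
    index = []
    for (outcome, cutoff), m in metrics.items():
        if not m.defined():
            continue
        row: dict[str, float] = {"auc": auc.get(outcome, np.nan)}
        p_obs = observed.get(outcome)
        row["real"] = (
            prevalence_weighted_accuracy(p_obs, m.sen, m.spe) if p_obs is not None else np.nan
        )
        for p in simulated:
            row[simulated_column_name(p)] = prevalence_weighted_accuracy(p, m.sen, m.spe)
        rows.append(row)
        index.append((outcome, cutoff))
    idx = pd.MultiIndex.from_tuples(index, names=["outcome", "cutoff"]) if index else (
        pd.MultiIndex.from_arrays([[], []], names=["outcome", "cutoff"])
    )
    cols = ["auc", "real"] + [simulated_column_name(p) for p in simulated]
    return pd.DataFrame(rows, index=idx, columns=cols)


def simulated_column_name(p: float) -> str:
    """Column label for a simulated prevalence, e.g. 0.20 -> 's20'."""
    pct = p * 100.0
    return f"s{pct:g}"


# ---------------------------------------------------------------------------
# Percent rendering (report layer)

def render_percent(proportion: float, decimals: int = 1) -> str:
    """Render a proportion as percent, round-half-away-from-zero.

    A pre-round at 1e-9 percent absorbs binary floating-point dust so
    that exact halves (57.55 -> "57.6") round deterministically.
    """
    pct = Decimal(repr(float(proportion) * 100.0))
    pct = pct.quantize(Decimal("1e-9"), rounding=ROUND_HALF_EVEN)
    q = Decimal(1).scaleb(-decimals)
    return str(pct.quantize(q, rounding=ROUND_HALF_UP))


def percent_value(proportion: float, decimals: int = 1) -> float:
    """Same rounding as :func:`render_percent`, returned as a float."""
    return float(render_percent(proportion, decimals))
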