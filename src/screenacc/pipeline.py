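"""End-to-end study pipeline: cohort in, screening tables and sweep out.

Reproduces the shape of the published analysis: for each questionnaire
outcome, the outcome-positive children are contrasted against a
comparator group, the biomarker is dichotomized at each cutoff, and the
report collects (i) the SEN/SPE/PPV/NPV table, (ii) the accuracy grid at
observed and simulated prevalences with the per-outcome AUC, and
(iii) a per-outcome accuracy-by-prevalence sweep.

The comparator is, by default, the symptom-free children (every panel
indicator 0) — the design stated in the published table captions. The
published predictive-value denominators are, however, only consistent
with the complement of the outcome group; ``comparator="outcome_complement"``
reproduces that reading. The choice changes PPV/NPV and the AUC subset,
not the accuracy formula.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _version
from .accuracy import (
    accuracy_sweep,
    build_accuracy_table,
    default_sweep_grid,
    observed_prevalence,
    render_percent,
)
from .metrics import (
    INDICATOR_COLUMNS,
    Cutoff,
    DiagnosticMetrics,
    confusion_table,
    diagnostic_metrics,
    dichotomize,
)
from .roc import auc_concordance, fit_logistic_univariate

logger = logging.getLogger("screenacc")

#: Analysis outcomes in report order. ``asthma_isolated`` is derived:
#: physician-diagnosed asthma with no coexisting wheeze, cough, dyspnoea
#: or allergic rhinitis.
OUTCOMES = (
    "asthma",
    "asthma_isolated",
    "cough_night",
    "cough_day",
    "rhinitis",
    "dyspnoea_night",
    "dyspnoea_day",
)

_COEXISTING = ("wheeze", "cough_night", "cough_day", "dyspnoea_night", "dyspnoea_day", "rhinitis")


class DegenerateAnalysisError(ValueError):
    """The cohort cannot support the two-group contrast (e.g. no
    symptom-free comparator exists)."""


def select_comparator(cohort: pd.DataFrame) -> pd.DataFrame:
    """Children with every panel indicator 0 (symptom-free comparator)."""
    if len(cohort) == 0:
        raise DegenerateAnalysisError("empty cohort")
    mask = (cohort.loc[:, list(INDICATOR_COLUMNS)] == 0).all(axis=1)
    sub = cohort.loc[mask]
    if len(sub) == 0:
        raise DegenerateAnalysisError(
            "no symptom-free children: the comparator rule (all panel "
            "indicators 0) selects an empty negative class"
        )
    return sub


def define_outcome_groups(cohort: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Positive subsets for the seven analysis outcomes."""
    groups: dict[str, pd.DataFrame] = {}
    isolated = (cohort["asthma"] == 1) & (cohort.loc[:, list(_COEXISTING)] == 0).all(axis=1)
    for outcome in OUTCOMES:
        if outcome == "asthma_isolated":
            mask = isolated
        else:
            mask = cohort[outcome] == 1
        groups[outcome] = cohort.loc[mask]
    return groups


@dataclass
class StudyReport:
    """All study artifacts plus run metadata.

    ``table1``: (outcome, cutoff)-indexed SEN/SPE/PPV/NPV proportions.
    ``table2``: accuracy grid (AUC, real-prevalence, simulated columns).
    ``sweeps``: per-outcome DataFrame of (prevalence, accuracy).
    """

    table1: pd.DataFrame
    table2: pd.DataFrame
    sweeps: dict[str, pd.DataFrame]
    metrics: dict[tuple[str, int], DiagnosticMetrics]
    metadata: dict = field(default_factory=dict)


def run_study(
    cohort: pd.DataFrame,
    cutoffs: Sequence[int] = (19, 24, 34),
    simulated_prevalences: Sequence[float] = (0.20, 0.30, 0.40, 0.50),
    sweep_grid: Optional[Sequence[float]] = None,
    comparator: str = "symptom_free",
) -> StudyReport:
    """Run the full screening-accuracy analysis on one cohort.

    Records with a missing biomarker are excluded from each contrast
    (and counted in the log); observed prevalence is computed on the full
    cohort from the questionnaire alone. Outcomes with no positive
    subject are skipped with a warning. Deterministic given the input.
    """
    if comparator not in ("symptom_free", "outcome_complement"):
        raise ValueError(f"unknown comparator rule {comparator!r}")
    cuts = [Cutoff(int(c)) for c in cutoffs]
    grid = default_sweep_grid() if sweep_grid is None else np.asarray(sweep_grid, float)

    groups = define_outcome_groups(cohort)
    comparator_df = select_comparator(cohort) if comparator == "symptom_free" else None

    metrics: dict[tuple[str, int], DiagnosticMetrics] = {}
    observed: dict[str, float] = {}
    aucs: dict[str, float] = {}
    fits: dict[str, object] = {}
    sweeps: dict[str, pd.DataFrame] = {}
    t1_rows = []
    t1_index = []

    for outcome in OUTCOMES:
        pos = groups[outcome]
        if len(pos) == 0:
            logger.warning("outcome %s: no positive subjects, skipped", outcome)
            continue
        if comparator_df is not None:
            neg = comparator_df
        else:
            neg = cohort.loc[~cohort.index.isin(pos.index)]
        two = pd.concat([pos, neg])
        disease = np.r_[np.ones(len(pos), dtype=np.int8), np.zeros(len(neg), dtype=np.int8)]
        keep = two["feno_ppb"].notna().to_numpy()
        n_excluded = int((~keep).sum())
        values = two.loc[keep, "feno_ppb"].to_numpy(dtype=float)
        disease = disease[keep]
        logger.info(
            "outcome %s: %d positives, %d comparator, %d excluded (missing FeNO)",
            outcome, len(pos), len(neg), n_excluded,
        )
        if disease.sum() == 0 or disease.sum() == disease.size:
            logger.warning("outcome %s: one class empty after exclusions, skipped", outcome)
            continue

        observed[outcome] = observed_prevalence(
            (cohort.index.isin(pos.index)).astype(int)
        )
        aucs[outcome] = auc_concordance(values, disease).auc
        fits[outcome] = fit_logistic_univariate(values, disease)

        for cut in cuts:
            m = diagnostic_metrics(confusion_table(dichotomize(values, cut), disease))
            metrics[(outcome, cut.threshold)] = m
            t1_rows.append({"sen": m.sen, "spe": m.spe, "ppv": m.ppv, "npv": m.npv})
            t1_index.append((outcome, cut.threshold))

        if cuts:
            # one sweep curve per cutoff, stacked in long format
            frames = []
            for cut in cuts:
                m = metrics[(outcome, cut.threshold)]
                if not m.defined():
                    continue
                pts = accuracy_sweep(m.sen, m.spe, grid)
                frames.append(
                    pd.DataFrame(pts, columns=["prevalence", "accuracy"]).assign(
                        cutoff=cut.threshold
                    )
                )
            if frames:
                sweeps[outcome] = pd.concat(frames, ignore_index=True).loc[
                    :, ["cutoff", "prevalence", "accuracy"]
                ]

    idx = (
        pd.MultiIndex.from_tuples(t1_index, names=["outcome", "cutoff"])
        if t1_index
        else pd.MultiIndex.from_arrays([[], []], names=["outcome", "cutoff"])
    )
    table1 = pd.DataFrame(t1_rows, index=idx, columns=["sen", "spe", "ppv", "npv"])
    table2 = build_accuracy_table(metrics, observed, simulated_prevalences, aucs)

    _lint_monotonicity(table1)

    meta = {
        "tool_version": _version,
        "n_cohort": int(len(cohort)),
        "cutoffs": [c.threshold for c in cuts],
        "simulated_prevalences": [float(p) for p in simulated_prevalences],
        "comparator": comparator,
        "input_hash": _cohort_hash(cohort),
        "logistic_fits": {
            o: {
                "intercept": f.intercept,
                "slope": f.slope,
                "converged": f.converged,
                "separated": f.separated,
            }
            for o, f in fits.items()
        },
    }
    return StudyReport(table1=table1, table2=table2, sweeps=sweeps, metrics=metrics, metadata=meta)


def _lint_monotonicity(table1: pd.DataFrame) -> None:
    """Structural lint: under a strict-greater rule on one dataset, SEN is
    non-increasing and SPE non-decreasing in the cutoff. A violation means
    the rows were not computed from a single dataset."""
    for outcome, sub in table1.groupby(level="outcome", sort=False):
        sub = sub.droplevel("outcome").sort_index()
        sen = sub["sen"].dropna()
        spe = sub["spe"].dropna()
        if not sen.is_monotonic_decreasing:
            logger.warning("outcome %s: sensitivity not non-increasing in cutoff", outcome)
        if not spe.is_monotonic_increasing:
            logger.warning("outcome %s: specificity not non-decreasing in cutoff", outcome)


def _cohort_hash(cohort: pd.DataFrame) -> str:
    payload = cohort.to_csv(index=False).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Rendering

def _fmt(v: Optional[float]) -> str:
    return "" if v is None or (isinstance(v, float) and np.isnan(v)) else render_percent(v)


def render_report(report: StudyReport, out_dir, formats: Sequence[str] = ("csv", "md")) -> list[Path]:
    """Write the report tables as CSV and/or Markdown, percentages to one
    decimal (round half away from zero); AUC stays on the [0, 1] scale."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    t1 = report.table1.copy()
    for col in t1.columns:
        t1[col] = t1[col].map(_fmt)
    t1 = t1.reset_index()

    t2 = report.table2.copy()
    auc_col = t2["auc"].map(lambda v: "" if np.isnan(v) else f"{v:.3f}")
    for col in t2.columns:
        if col != "auc":
            t2[col] = t2[col].map(_fmt)
    t2["auc"] = auc_col
    t2 = t2.reset_index()

    try:
        if "csv" in formats:
            for name, df in (("table1", t1), ("table2", t2)):
                p = out / f"{name}.csv"
                df.to_csv(p, index=False, lineterminator="\n")
                written.append(p)
            for outcome, sweep in report.sweeps.items():
                p = out / f"sweep_{outcome}.csv"
                sweep.to_csv(p, index=False, lineterminator="\n", float_format="%.6g")
                written.append(p)
        if "md" in formats:
            for name, df in (("table1", t1), ("table2", t2)):
                p = out / f"{name}.md"
                p.write_text(_markdown_table(df), encoding="utf-8")
                written.append(p)
        p = out / "metadata.json"
        p.write_text(json.dumps(report.metadata, indent=2, sort_keys=True) + "\n", encoding="utf-8")
        written.append(p)
    except OSError as exc:
        raise OSError(f"failed writing report under {out}: {exc}") from exc
    return written


def _markdown_table(df: pd.DataFrame) -> str:
    header = "| " + " | ".join(df.columns) + " |"
    rule = "|" + "|".join("---" for _ in df.columns) + "|"
    rows = ["| " + " | ".join(str(v) for v in rec) + " |" for rec in df.itertuples(index=False)]
    return "\n".join([header, rule, *rows]) + "\n"
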