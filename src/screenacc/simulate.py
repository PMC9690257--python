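"""Calibrated synthetic cohorts for the screening-accuracy pipeline.

The study's raw data are not deposited, so this module generates cohorts
with the statistical structure the analysis needs: questionnaire outcomes
with the published marginal counts and asthma co-occurrence, and
per-group FeNO distributions calibrated so that exceedance of the
screening cutoffs reproduces the published sensitivity/specificity.

FeNO is modelled as lognormal — the standard family for exhaled nitric
oxide, which is positive and right-skewed. A two-parameter lognormal is
pinned down exactly by two exceedance anchors:

    P(X > c_i) = p_i   =>   ln c_i = mu + sigma * Phi^{-1}(1 - p_i)

a 2x2 linear system in (mu, sigma). The two extreme cutoffs (>19, >34
ppb) are the anchors; the middle cutoff (>24) is an out-of-sample check.
Device behaviour is emulated by rounding to integer ppb and clamping at
a 5-ppb detection floor; rounding shifts exceedance from P(X > c) to
P(X > c + 0.5), and calibration can target the rounded variable through
that half-step correction (``rounded=True``).
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from . import reference
from .metrics import (
    COHORT_COLUMNS,
    Cutoff,
    DiagnosticMetrics,
    confusion_table,
    diagnostic_metrics,
    dichotomize,
)


class CalibrationError(ValueError):
    """No valid lognormal satisfies the requested exceedance anchors."""


@dataclass(frozen=True)
class LognormalParams:
    """Location/scale on the log-ppb axis."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")

    def survival(self, c: float) -> float:
        """P(X > c) for the continuous variable."""
        return float(1.0 - ndtr((math.log(c) - self.mu) / self.sigma))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.lognormal(mean=self.mu, sigma=self.sigma, size=n)


def calibrate_lognormal(
    c1: float,
    p1: float,
    c2: float,
    p2: float,
    rounded: bool = False,
    sigma_max: float = 20.0,
) -> LognormalParams:
    """Solve for the lognormal with P(X > c1) = p1 and P(X > c2) = p2.

    ``rounded=True`` targets the integer-rounded variable instead, via
    the half-step correction (anchors at c + 0.5). Requires c1 < c2 and
    1 > p1 > p2 > 0 (exceedance decreases in the cutoff); near-equal
    exceedances would need an absurd spread and trip the ``sigma_max``
    guard.
    """
    if not (0 < c1 < c2):
        raise CalibrationError(f"cutoffs must satisfy 0 < c1 < c2, got {c1}, {c2}")
    for p in (p1, p2):
        if not 0.0 < p < 1.0:
            raise CalibrationError(f"exceedance anchors must lie strictly in (0, 1), got {p}")
    if p2 >= p1:
        raise CalibrationError(
            f"exceedance must decrease in the cutoff (p1={p1} must exceed p2={p2})"
        )
    a1, a2 = (c1 + 0.5, c2 + 0.5) if rounded else (c1, c2)
    z1, z2 = ndtri(1.0 - p1), ndtri(1.0 - p2)
    sigma = (math.log(a2) - math.log(a1)) / (z2 - z1)
    if sigma > sigma_max:
        raise CalibrationError(
            f"anchors imply sigma = {sigma:.3g} log-ppb (> {sigma_max}); "
            "exceedances are too close for the cutoff spacing"
        )
    mu = math.log(a1) - sigma * z1
    return LognormalParams(mu=mu, sigma=sigma)


#: Non-asthma questionnaire indicators (generation order).
SYMPTOMS = ("cough_night", "cough_day", "rhinitis", "dyspnoea_night", "dyspnoea_day", "wheeze")

#: FeNO status groups, in assignment priority order.
FENO_GROUPS = ("asthma", "symptomatic", "healthy")


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters for one synthetic cohort.

    ``symptom_probs`` maps each non-asthma indicator to its Bernoulli
    probability conditional on asthma status (given-asthma,
    given-no-asthma); symptoms are independent given that status.
    ``group_distributions`` assigns a FeNO lognormal to each status:
    any-asthma children, symptomatic non-asthmatics, and symptom-free
    ("healthy") children.
    """

    n: int
    seed: int
    asthma_prevalence: float
    symptom_probs: Mapping[str, tuple[float, float]]
    group_distributions: Mapping[str, LognormalParams]
    feno_floor: int = 5

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"cohort size must be >= 1, got {self.n}")
        if self.feno_floor < 0:
            raise ValueError("feno_floor must be >= 0")
        if not 0.0 <= self.asthma_prevalence <= 1.0:
            raise ValueError("asthma_prevalence must be in [0, 1]")
        missing = set(SYMPTOMS) - set(self.symptom_probs)
        if missing:
            raise ValueError(f"symptom_probs missing indicators: {sorted(missing)}")
        for s, (pa, pn) in self.symptom_probs.items():
            for label, p in (("given asthma", pa), ("given no asthma", pn)):
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"P({s} | {label}) = {p} outside [0, 1]")
        missing_g = set(FENO_GROUPS) - set(self.group_distributions)
        if missing_g:
            raise ValueError(f"group_distributions missing groups: {sorted(missing_g)}")


def default_cohort_spec(seed: int = 0, n: int = reference.COHORT_SIZE) -> CohortSpec:
    """The published study's conditions as a generative spec.

    Marginal outcome counts match the printed per-outcome n; symptom
    rates given asthma are set so the expected isolated-asthma count is
    the printed 5 of 447; FeNO groups are calibrated to the printed
    SEN/SPE anchors at the >19 and >34 ppb cutoffs (any-asthma row for
    the asthma group and, via 1 - SPE, for the symptom-free comparator;
    cough-at-night row for the remaining symptomatic children).
    """
    n_cohort = reference.COHORT_SIZE
    n_asthma = reference.OUTCOME_COUNTS["asthma"]
    p_asthma = n_asthma / n_cohort

    # coughs and rhinitis at their marginal rates given asthma; dyspnoea
    # mildly enriched; wheeze (no printed count) solves the isolated-
    # asthma constraint: prod(1 - P(s | asthma)) = 5/37
    given_asthma = {
        "cough_night": reference.OUTCOME_COUNTS["cough_night"] / n_cohort,
        "cough_day": reference.OUTCOME_COUNTS["cough_day"] / n_cohort,
        "rhinitis": reference.OUTCOME_COUNTS["rhinitis"] / n_cohort,
        "dyspnoea_night": 0.08,
        "dyspnoea_day": 0.06,
    }
    p_isolated_given_asthma = reference.OUTCOME_COUNTS["asthma_isolated"] / n_asthma
    prod_compl = math.prod(1.0 - p for p in given_asthma.values())
    given_asthma["wheeze"] = 1.0 - p_isolated_given_asthma / prod_compl

    symptom_probs = {}
    for s in SYMPTOMS:
        pa = given_asthma[s]
        if s == "wheeze":
            pn = 0.10  # plausible childhood wheeze rate; count not published
        else:
            count = reference.OUTCOME_COUNTS[s]
            pn = (count - n_asthma * pa) / (n_cohort - n_asthma)
        symptom_probs[s] = (pa, pn)

    sen19, spe19 = reference.sen_spe("asthma", 19)
    sen34, spe34 = reference.sen_spe("asthma", 34)
    cn19, _ = reference.sen_spe("cough_night", 19)
    cn34, _ = reference.sen_spe("cough_night", 34)
    group_distributions = {
        "asthma": calibrate_lognormal(19, sen19, 34, sen34, rounded=True),
        "healthy": calibrate_lognormal(19, 1.0 - spe19, 34, 1.0 - spe34, rounded=True),
        "symptomatic": calibrate_lognormal(19, cn19, 34, cn34, rounded=True),
    }
    return CohortSpec(
        n=n,
        seed=seed,
        asthma_prevalence=p_asthma,
        symptom_probs=symptom_probs,
        group_distributions=group_distributions,
    )


def _round_and_floor(x: np.ndarray, floor: int) -> np.ndarray:
    return np.maximum(np.rint(x), floor).astype(int)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw one cohort; deterministic under (spec, seed).

    Disease statuses are drawn per child (asthma first, then each symptom
    conditional on asthma status, independently); FeNO comes from the
    status group's lognormal, rounded to integer ppb and clamped at the
    device floor. Derived groupings (isolated asthma, symptom-free) are
    consistent with the indicator panel by construction.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    asthma = (rng.random(n) < spec.asthma_prevalence).astype(np.int8)
    cols = {"asthma": asthma}
    for s in SYMPTOMS:
        pa, pn = spec.symptom_probs[s]
        p = np.where(asthma == 1, pa, pn)
        cols[s] = (rng.random(n) < p).astype(np.int8)
    any_symptom = np.zeros(n, dtype=bool)
    for s in SYMPTOMS:
        any_symptom |= cols[s] == 1

    group = np.where(asthma == 1, "asthma", np.where(any_symptom, "symptomatic", "healthy"))
    feno = np.empty(n, dtype=float)
    for g in FENO_GROUPS:
        mask = group == g
        if mask.any():
            feno[mask] = spec.group_distributions[g].sample(int(mask.sum()), rng)
    feno_i = _round_and_floor(feno, spec.feno_floor)

    width = max(4, len(str(n)))
    df = pd.DataFrame(
        {
            "child_id": [f"C{i:0{width}d}" for i in range(1, n + 1)],
            "feno_ppb": feno_i.astype(float),
            **{s: cols[s] for s in ("asthma",) + SYMPTOMS},
        }
    )
    return df.loc[:, list(COHORT_COLUMNS)]


def recover_metrics(
    spec: CohortSpec, n_large: int, cutoffs: Sequence[Cutoff | int]
) -> dict[int, DiagnosticMetrics]:
    """Monte-Carlo recovery of the calibrated SEN/SPE.

    Draws ``n_large`` subjects from the disease-positive ("asthma") FeNO
    distribution and ``n_large`` from the symptom-free comparator
    ("healthy"), applies the device rounding/floor, and runs the metrics
    pipeline at each cutoff. With anchors calibrated under
    ``rounded=True`` the empirical SEN/SPE converge to the targets.
    """
    if n_large < 1:
        raise ValueError(f"n_large must be >= 1, got {n_large}")
    rng = np.random.default_rng(spec.seed)
    pos = _round_and_floor(spec.group_distributions["asthma"].sample(n_large, rng), spec.feno_floor)
    neg = _round_and_floor(spec.group_distributions["healthy"].sample(n_large, rng), spec.feno_floor)
    values = np.r_[pos, neg]
    disease = np.r_[np.ones(n_large, dtype=np.int8), np.zeros(n_large, dtype=np.int8)]
    out: dict[int, DiagnosticMetrics] = {}
    for c in cutoffs:
        cut = c if isinstance(c, Cutoff) else Cutoff(int(c))
        out[cut.threshold] = diagnostic_metrics(
            confusion_table(dichotomize(values, cut), disease)
        )
    return out


# ---------------------------------------------------------------------------
# Spec files (TOML)

def load_cohort_spec(path) -> CohortSpec:
    """Load a cohort spec from TOML; ``seed`` is mandatory, everything
    else falls back to the published-study defaults.

    Layout::

        seed = 1
        n = 447
        feno_floor = 5
        asthma_prevalence = 0.0828
        [symptoms.given_asthma]
        cough_night = 0.52
        [symptoms.given_no_asthma]
        cough_night = 0.52
        [feno.asthma]
        mu = 2.6
        sigma = 1.0
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    if "seed" not in raw:
        raise ValueError(f"spec file {path} must set a seed")
    base = default_cohort_spec(seed=int(raw["seed"]))
    spec = replace(
        base,
        n=int(raw.get("n", base.n)),
        feno_floor=int(raw.get("feno_floor", base.feno_floor)),
        asthma_prevalence=float(raw.get("asthma_prevalence", base.asthma_prevalence)),
    )
    symptoms = raw.get("symptoms", {})
    if symptoms:
        probs = dict(spec.symptom_probs)
        for s in SYMPTOMS:
            pa = symptoms.get("given_asthma", {}).get(s, probs[s][0])
            pn = symptoms.get("given_no_asthma", {}).get(s, probs[s][1])
            probs[s] = (float(pa), float(pn))
        spec = replace(spec, symptom_probs=probs)
    feno = raw.get("feno", {})
    if feno:
        dists = dict(spec.group_distributions)
        for g in FENO_GROUPS:
            if g in feno:
                dists[g] = LognormalParams(mu=float(feno[g]["mu"]), sigma=float(feno[g]["sigma"]))
        spec = replace(spec, group_distributions=dists)
    return spec
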