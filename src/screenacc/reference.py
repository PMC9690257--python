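"""Published summary statistics of the FeNO school-children screening study.

The study cohort (447 Silesian schoolchildren aged 6-9, FeNO by
electrochemical analyser, respiratory status by ISAAC-style questionnaire)
is not publicly deposited; what is public is the per-outcome screening
table: sensitivity, specificity, PPV and NPV of FeNO dichotomized at
>19 / >24 / >34 ppb, for seven questionnaire outcomes contrasted against
symptom-free children.

These printed values are *inputs* to this package: they anchor the
synthetic-cohort calibration and they are the operands of the
prevalence-weighted accuracy grid. All values are stored exactly as
printed (percent, one decimal) and converted to proportions on access.
"""

from __future__ import annotations

COHORT_SIZE = 447

CUTOFFS_PPB = (19, 24, 34)

SIMULATED_PREVALENCES = (0.20, 0.30, 0.40, 0.50)

#: Questionnaire outcomes in the published row order, with the positive-group
#: size printed alongside each.
OUTCOME_COUNTS = {
    "asthma": 37,                 # physician-diagnosed, coexisting disorders allowed
    "asthma_isolated": 5,         # asthma with no coexisting wheeze/cough/dyspnoea/rhinitis
    "cough_night": 234,
    "cough_day": 210,
    "rhinitis": 106,
    "dyspnoea_night": 17,
    "dyspnoea_day": 12,
}

#: (outcome, cutoff ppb) -> (SEN %, SPE %, PPV %, NPV %), exactly as printed.
SCREENING_TABLE_PERCENT = {
    ("asthma", 19): (32.4, 82.6, 14.4, 93.1),
    ("asthma", 24): (27.0, 98.5, 18.8, 93.1),
    ("asthma", 34): (18.9, 94.6, 24.1, 93.1),
    ("asthma_isolated", 19): (40.0, 81.6, 2.4, 99.1),
    ("asthma_isolated", 24): (20.0, 88.2, 1.8, 99.1),
    ("asthma_isolated", 34): (20.0, 93.6, 3.4, 98.9),
    ("cough_night", 19): (19.2, 82.1, 54.2, 48.0),
    ("cough_night", 24): (13.6, 90.0, 60.3, 48.7),
    ("cough_night", 34): (8.5, 95.7, 68.9, 48.8),
    ("cough_day", 19): (19.5, 82.2, 49.4, 53.5),
    ("cough_day", 24): (14.2, 90.3, 56.6, 54.3),
    ("cough_day", 34): (7.1, 94.0, 51.7, 53.3),
    ("rhinitis", 19): (15.5, 71.7, 63.8, 20.8),
    ("rhinitis", 24): (8.8, 78.3, 56.6, 21.0),
    ("rhinitis", 34): (3.8, 84.9, 44.8, 21.5),
    ("dyspnoea_night", 19): (29.4, 81.8, 6.0, 96.7),
    ("dyspnoea_night", 24): (23.5, 88.6, 7.5, 96.7),
    ("dyspnoea_night", 34): (17.6, 93.9, 10.3, 96.6),
    ("dyspnoea_day", 19): (16.6, 81.3, 3.7, 97.2),
    ("dyspnoea_day", 24): (16.6, 88.2, 3.7, 97.4),
    ("dyspnoea_day", 34): (8.3, 93.5, 3.4, 97.3),
}

#: Published per-outcome AUC of FeNO as a continuous score (logistic model).
AUC_BY_OUTCOME = {
    "asthma": 0.628,
    "asthma_isolated": 0.757,
    "cough_night": 0.520,
    "cough_day": 0.521,
    "rhinitis": 0.570,
    "dyspnoea_night": 0.576,
    "dyspnoea_day": 0.511,
}


def sen_spe(outcome: str, cutoff: int) -> tuple[float, float]:
    """Printed sensitivity and specificity as proportions in [0, 1]."""
    sen, spe, _, _ = SCREENING_TABLE_PERCENT[(outcome, cutoff)]
    return sen / 100.0, spe / 100.0


def observed_prevalence_exact(outcome: str) -> float:
    """Observed outcome prevalence n_outcome / n_cohort, unrounded."""
    return OUTCOME_COUNTS[outcome] / COHORT_SIZE
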