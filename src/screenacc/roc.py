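"""Univariate logistic regression and ROC/AUC for a continuous score.

The AUC here is the rank-concordance (Mann-Whitney) statistic: the
probability that a randomly chosen diseased subject scores higher than a
randomly chosen comparator, with ties — frequent on integer ppb data —
getting half credit. This is numerically identical to the trapezoidal
area under the empirical ROC staircase, and it is invariant under any
strictly increasing transform of the score; in particular, the logistic
model's predicted probabilities give the same AUC as the raw biomarker
whenever the fitted slope is positive. The logistic fit is retained as
the named route; concordance is the reported estimator because it is
exact and tie-safe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit
from scipy.stats import rankdata

# absolute linear predictor beyond which fitted probabilities are 0/1 to
# machine precision; reaching it during IRLS signals (quasi-)separation
_ETA_DIVERGENCE = 30.0


@dataclass(frozen=True)
class LogisticFit:
    intercept: float
    slope: float
    converged: bool
    iterations: int
    log_likelihood: float
    separated: bool = False

    def predict_proba(self, x) -> np.ndarray:
        return expit(self.intercept + self.slope * np.asarray(x, dtype=float))


@dataclass(frozen=True)
class AucResult:
    auc: float
    n_pos: int
    n_neg: int
    tie_pairs: int


def _validate_two_class(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D sequences of equal length")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("labels must be exactly 0 or 1")
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    return s, y.astype(np.int8)


def _bernoulli_loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # log p = -log(1+e^-eta); log(1-p) = -log(1+e^eta); stable for large |eta|
    return float(-np.sum(np.logaddexp(0.0, np.where(y == 1, -eta, eta))))


def fit_logistic_univariate(
    x, y, tol: float = 1e-8, max_iter: int = 50
) -> LogisticFit:
    """Maximum-likelihood logit(P(y=1)) = a + b*x by IRLS (Newton-Raphson).

    Convergence: change in log-likelihood below ``tol``. Complete or
    quasi-complete separation (coefficients diverging, fitted
    probabilities saturating) is flagged via ``separated`` with
    ``converged=False`` rather than returning meaningless coefficients.
    """
    xv, yv = _validate_two_class(x, y)
    # centre/scale the covariate for a well-conditioned Hessian; the
    # coefficients are mapped back afterwards
    mu, sd = float(xv.mean()), float(xv.std())
    sd = sd if sd > 0 else 1.0
    z = (xv - mu) / sd
    X = np.column_stack([np.ones_like(z), z])

    ybar = float(yv.mean())
    beta = np.array([logit(ybar), 0.0])
    ll = _bernoulli_loglik(X @ beta, yv)
    converged = False
    separated = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = expit(eta)
        w = p * (1.0 - p)
        H = X.T @ (X * w[:, None])
        g = X.T @ (yv - p)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            separated = True
            break
        beta = beta + step
        ll_new = _bernoulli_loglik(X @ beta, yv)
        if np.max(np.abs(X @ beta)) > _ETA_DIVERGENCE:
            separated = True
            ll = ll_new
            break
        if abs(ll_new - ll) < tol:
            ll = ll_new
            converged = True
            break
        ll = ll_new

    intercept = float(beta[0] - beta[1] * mu / sd)
    slope = float(beta[1] / sd)
    return LogisticFit(
        intercept=intercept,
        slope=slope,
        converged=converged and not separated,
        iterations=it,
        log_likelihood=ll,
        separated=separated,
    )


def auc_concordance(scores, labels) -> AucResult:
    """Mann-Whitney AUC with half-credit ties over all pos-neg pairs."""
    s, y = _validate_two_class(scores, labels)
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    ranks = rankdata(s)  # midranks give ties half credit automatically
    u = float(ranks[y == 1].sum()) - n_pos * (n_pos + 1) / 2.0
    # tie-pair count: per tied score value, positives x negatives
    vals, inv = np.unique(s, return_inverse=True)
    pos_counts = np.bincount(inv[y == 1], minlength=vals.size)
    neg_counts = np.bincount(inv[y == 0], minlength=vals.size)
    tie_pairs = int(np.sum(pos_counts * neg_counts))
    return AucResult(auc=u / (n_pos * n_neg), n_pos=n_pos, n_neg=n_neg, tie_pairs=tie_pairs)


def roc_curve(scores, labels) -> np.ndarray:
    """Empirical ROC staircase at all distinct thresholds.

    Returns an array of (fpr, tpr) points from (0, 0) to (1, 1); tied
    scores move diagonally in one step, so the trapezoidal area equals
    the half-credit concordance AUC exactly.
    """
    s, y = _validate_two_class(scores, labels)
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    # indices where the threshold value changes
    distinct = np.flatnonzero(np.diff(s_sorted) != 0)
    cut_idx = np.r_[distinct, s_sorted.size - 1]
    tps = np.cumsum(y_sorted)[cut_idx]
    fps = np.cumsum(1 - y_sorted)[cut_idx]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    return np.column_stack([fpr, tpr])


def roc_area(points: np.ndarray) -> float:
    """Trapezoidal area under an ROC staircase."""
    return float(np.trapezoid(points[:, 1], points[:, 0]))
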