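"""Acute-rejection classification from the tCRM score.

ROC analysis of the score against biopsy-proven acute rejection (higher
score => AR), Youden-style threshold derivation on a discovery split,
frozen-threshold evaluation on a validation split, and a from-scratch
maximum-likelihood logistic regression (IRLS with step halving) for the
"independent correlate" analysis.

The published decision threshold (score > 2.24 => AR risk) ships as
:data:`DEFAULT_AR_THRESHOLD` for apply-only use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "DEFAULT_AR_THRESHOLD",
    "RocResult",
    "ThresholdDecision",
    "ConfusionMetrics",
    "LogisticFit",
    "roc_curve",
    "auc_ci",
    "select_threshold",
    "evaluate_threshold",
    "fit_logistic",
]

#: Published tCRM decision threshold: score strictly greater => call AR.
DEFAULT_AR_THRESHOLD = 2.24


@dataclass
class RocResult:
    thresholds: np.ndarray  # sorted ascending, with -inf/+inf sentinels
    sensitivity: np.ndarray  # P(score > thr | positive), per threshold
    specificity: np.ndarray  # P(score <= thr | negative), per threshold
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    n_pos: int
    n_neg: int


@dataclass
class ThresholdDecision:
    threshold: float
    sensitivity: float
    specificity: float
    youden_j: float


@dataclass
class ConfusionMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    ppv: float  # NaN when no positive calls were made
    npv: float
    accuracy: float


@dataclass
class LogisticFit:
    coefficients: np.ndarray
    standard_errors: np.ndarray
    z_values: np.ndarray
    p_values: np.ndarray
    converged: bool
    n_iterations: int
    separation: bool = False
    log_likelihood: float = np.nan
    loglik_history: list[float] = field(default_factory=list)


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    return labels


def roc_curve(scores, labels) -> RocResult:
    """Empirical ROC of ``scores`` against binary ``labels`` (1 = AR).

    Candidate thresholds are the midpoints between consecutive distinct
    sorted scores, bracketed by -inf/+inf sentinels; a sample is called
    positive when its score is strictly greater than the threshold.  The
    trapezoidal AUC equals the normalized Mann-Whitney U statistic.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    if np.isnan(scores).any():
        raise ValueError("scores must be finite")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate(([-np.inf], mids, [np.inf]))
    sens = np.array([(pos > t).mean() for t in thresholds])
    spec = np.array([(neg <= t).mean() for t in thresholds])
    # trapezoid over the (FPR, TPR) polyline from (0,0) to (1,1); vertical
    # jumps at tied FPR must be traversed in TPR order
    fpr = 1.0 - spec
    order = np.lexsort((sens, fpr))
    auc = float(np.trapezoid(sens[order], fpr[order]))
    low, high = auc_ci(auc, len(pos), len(neg))
    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        auc_ci_low=low,
        auc_ci_high=high,
        n_pos=len(pos),
        n_neg=len(neg),
    )


def auc_ci(auc: float, n_pos: int, n_neg: int) -> tuple[float, float]:
    """95% CI for the AUC by the Hanley-McNeil closed-form standard error.

    SE^2 = [A(1-A) + (n1-1)(Q1-A^2) + (n2-1)(Q2-A^2)] / (n1 n2)
    with Q1 = A/(2-A), Q2 = 2A^2/(1+A); the interval A +- 1.96 SE is
    clipped to [0, 1].
    """
    a = float(auc)
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (
        a * (1.0 - a)
        + (n_pos - 1) * (q1 - a * a)
        + (n_neg - 1) * (q2 - a * a)
    ) / (n_pos * n_neg)
    se = float(np.sqrt(max(var, 0.0)))
    return max(0.0, a - 1.96 * se), min(1.0, a + 1.96 * se)


def select_threshold(roc: RocResult) -> ThresholdDecision:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    Ties are broken toward higher specificity, then toward the lower
    threshold; the +-inf sentinels are excluded so the decision is always a
    usable finite midpoint cutpoint.
    """
    finite = np.isfinite(roc.thresholds)
    if not finite.any():
        raise ValueError("no finite candidate thresholds (constant scores)")
    thr = roc.thresholds[finite]
    sens = roc.sensitivity[finite]
    spec = roc.specificity[finite]
    j = sens + spec - 1.0
    # lexicographic argmax: J desc, specificity desc, threshold asc
    best = 0
    for k in range(1, len(thr)):
        if (j[k], spec[k], -thr[k]) > (j[best], spec[best], -thr[best]):
            best = k
    return ThresholdDecision(
        threshold=float(thr[best]),
        sensitivity=float(sens[best]),
        specificity=float(spec[best]),
        youden_j=float(j[best]),
    )


def evaluate_threshold(scores, labels, threshold: float) -> ConfusionMetrics:
    """2x2 confusion metrics for the rule "score > threshold => AR"."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pred = scores > threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    ppv = tp / (tp + fp) if tp + fp else float("nan")
    npv = tn / (tn + fn) if tn + fn else float("nan")
    acc = (tp + tn) / len(scores)
    return ConfusionMetrics(tp, fp, tn, fn, sens, spec, ppv, npv, acc)


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically stable Bernoulli log-likelihood with logit link
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(
    design: np.ndarray,
    outcome,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> LogisticFit:
    """Maximum-likelihood logistic regression via IRLS with step halving.

    ``design`` must include its own intercept column.  Convergence when the
    largest coefficient update falls below ``tol``.  Quasi-complete
    separation is detected (fitted probabilities saturating at 0/1 with
    diverging coefficients) and reported as a non-converged fit rather than
    silently returning huge coefficients.
    """
    x = np.asarray(design, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if x.ndim != 2 or x.shape[0] != y.shape[0]:
        raise ValueError("design must be (n, p) matching outcome length")
    n, p = x.shape
    beta = np.zeros(p)
    eta = x @ beta
    ll = _loglik(y, eta)
    history = [ll]
    converged = False
    separation = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-12)
        # Newton step via weighted least squares
        xtw = x.T * w
        try:
            step = np.linalg.solve(xtw @ x, x.T @ (y - mu))
        except np.linalg.LinAlgError:
            break
        # halve until the log-likelihood does not decrease
        scale = 1.0
        for _ in range(30):
            candidate = beta + scale * step
            ll_new = _loglik(y, x @ candidate)
            if ll_new >= ll - 1e-12:
                break
            scale /= 2.0
        beta = beta + scale * step
        eta = x @ beta
        ll = _loglik(y, eta)
        history.append(ll)
        if np.max(np.abs(scale * step)) < tol:
            converged = True
            break
        if np.max(np.abs(beta)) > 1e4 or np.max(np.abs(eta)) > 30.0:
            separation = True
            break
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(mu * (1.0 - mu), 1e-12)
    info = (x.T * w) @ x
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    if separation:
        converged = False
    return LogisticFit(
        coefficients=beta,
        standard_errors=se,
        z_values=z,
        p_values=pvals,
        converged=converged,
        n_iterations=it,
        separation=separation,
        log_likelihood=ll,
        loglik_history=history,
    )
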