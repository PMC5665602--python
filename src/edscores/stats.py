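"""From-scratch statistical machinery for mortality-prediction evaluation.

Implements, without delegating to scipy/statsmodels/sklearn, the full
analytic toolkit the pipeline needs: two-sided Mann-Whitney U tests
(exact enumeration or tie-corrected normal approximation), Fisher's
exact test for 2x2 tables, univariate logistic regression by
iteratively reweighted least squares with the logit probability of
death p = 1 / (1 + exp(-(b0 + b1*x))), ROC curves with trapezoidal
AUROC, Youden-J optimal cutoffs, and confusion-matrix test
characteristics.  The established library implementations serve as
independent oracles in the test suite only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GroupComparison",
    "LogisticFit",
    "RocCurve",
    "ClassifierMetrics",
    "SeparationError",
    "mann_whitney_u",
    "fisher_exact",
    "fit_univariate_logistic",
    "predict_probability",
    "roc_curve",
    "optimal_cutoff",
    "confusion_metrics",
]

_EXACT_LIMIT = 1_000_000  # max C(n, n_x) combinations for exact enumeration


@dataclass(frozen=True)
class GroupComparison:
    """A two-group test result: statistic, two-sided p, and the method used."""

    statistic: float
    p_value: float
    method: str  # mann_whitney_exact | mann_whitney_normal | fisher_exact

    def __post_init__(self):
        if not 0 <= self.p_value <= 1 + 1e-12:
            raise ValueError(f"p_value {self.p_value!r} outside [0, 1]")


@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood univariate logistic model score -> mortality."""

    beta0: float
    beta1: float
    converged: bool
    iterations: int
    log_likelihood: float
    beta0_se: float = math.nan
    beta1_se: float = math.nan


@dataclass(frozen=True)
class RocCurve:
    """An ROC curve over descending thresholds ('positive iff score >= t').

    The first point is the empty classifier (t = +inf, at (0, 0)); the
    last classifies everyone positive (t = min score, at (1, 1)).
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float

    def __post_init__(self):
        if np.any(np.diff(self.tpr) < 0) or np.any(np.diff(self.fpr) < 0):
            raise ValueError("tpr and fpr must be non-decreasing along the curve")
        if not (self.tpr[0] == 0 and self.fpr[0] == 0 and self.tpr[-1] == 1 and self.fpr[-1] == 1):
            raise ValueError("curve must start at (0,0) and end at (1,1)")
        if not 0 <= self.auc <= 1:
            raise ValueError(f"auc {self.auc!r} outside [0, 1]")


@dataclass(frozen=True)
class ClassifierMetrics:
    """Confusion counts and test characteristics at one cutoff.

    Convention: predicted positive (predicted death) iff score >= cutoff.
    Ratios with empty denominators are NaN.
    """

    cutoff: float
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float = field(init=False)
    specificity: float = field(init=False)
    ppv: float = field(init=False)
    npv: float = field(init=False)
    accuracy: float = field(init=False)

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

        def ratio(num, den):
            return num / den if den > 0 else math.nan

        object.__setattr__(self, "sensitivity", ratio(self.tp, self.tp + self.fn))
        object.__setattr__(self, "specificity", ratio(self.tn, self.tn + self.fp))
        object.__setattr__(self, "ppv", ratio(self.tp, self.tp + self.fp))
        object.__setattr__(self, "npv", ratio(self.tn, self.tn + self.fn))
        object.__setattr__(
            self, "accuracy", ratio(self.tp + self.tn, self.tp + self.tn + self.fp + self.fn)
        )


class SeparationError(ValueError):
    """Complete separation: a threshold on the score splits the classes perfectly."""


# ---------------------------------------------------------------------------
# Mann-Whitney U


def _midranks(pooled: np.ndarray) -> np.ndarray:
    """Ranks 1..N with tied values receiving their average rank."""
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1  # average of ranks i+1..j+1
        i = j + 1
    return ranks


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U of x over y via midranks (tied pairs count one half)."""
    nx = len(x)
    ranks = _midranks(np.concatenate([x, y]))
    return float(ranks[:nx].sum() - nx * (nx + 1) / 2)


def _exact_u_distribution_no_ties(nx: int, ny: int) -> np.ndarray:
    """Counts of rank-sum values for x over all C(nx+ny, nx) assignments.

    Dynamic programming over 'number of chosen ranks x rank sum'; entry
    s of the returned vector counts assignments with U = s.
    """
    n = nx + ny
    max_u = nx * ny
    # ways[k][u]: choose k ranks from 1..m with reduced sum u (u = ranksum - k(k+1)/2)
    ways = np.zeros((nx + 1, max_u + 1), dtype=float)
    ways[0, 0] = 1.0
    for m in range(1, n + 1):
        for k in range(min(nx, m), 0, -1):
            # adding rank m as the k-th (largest) chosen rank adds m - k to the reduced sum
            shift = m - k
            if shift <= max_u:
                ways[k, shift:] += ways[k - 1, : max_u + 1 - shift]
    return ways[nx]


def _two_sided_tail(counts: np.ndarray, u: float, n_total: float) -> float:
    """P(|U' - mean| >= |u - mean|) under the permutation distribution."""
    mean = (len(counts) - 1) / 2
    dev = abs(u - mean) - 1e-9
    idx = np.abs(np.arange(len(counts)) - mean) >= dev
    return float(counts[idx].sum() / n_total)


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], mode: str = "auto"
) -> GroupComparison:
    """Two-sided Mann-Whitney U test of two independent samples.

    The reported statistic is U of ``x`` (number of (x, y) pairs with
    x > y, tied pairs counting one half).  In ``auto`` mode the exact
    permutation p-value is computed whenever C(n_x+n_y, n_x) <= 1e6
    (by a rank-sum counting recursion without ties, by full enumeration
    of combinations with ties); otherwise the normal approximation with
    midrank tie correction and 0.5 continuity correction is used.
    ``mode='exact'`` forces enumeration where feasible and falls back
    with a logged note where not; ``mode='normal'`` forces the
    approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if mode not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown mode {mode!r}")
    nx, ny = len(x), len(y)
    u = _u_statistic(x, y)
    ties = len(np.unique(np.concatenate([x, y]))) < nx + ny
    feasible = math.comb(nx + ny, nx) <= _EXACT_LIMIT

    if mode != "normal" and feasible:
        if not ties:
            counts = _exact_u_distribution_no_ties(nx, ny)
            p = _two_sided_tail(counts, u, math.comb(nx + ny, nx))
        else:
            p = _exact_with_ties(x, y, u)
        return GroupComparison(u, min(p, 1.0), "mann_whitney_exact")
    if mode == "exact":
        logger.warning(
            "exact Mann-Whitney infeasible for n=(%d, %d)%s; falling back to normal approximation",
            nx,
            ny,
            " with ties" if ties else "",
        )
    return GroupComparison(u, _normal_p(x, y, u), "mann_whitney_normal")


def _exact_with_ties(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Exact permutation p by full enumeration of label assignments."""
    from itertools import combinations

    pooled = np.sort(np.concatenate([x, y]))
    nx = len(x)
    n = len(pooled)
    ranks = _midranks(pooled)
    mean = nx * (n - nx) / 2
    dev = abs(u_obs - mean) - 1e-9
    hits = total = 0
    offset = nx * (nx + 1) / 2
    for combo in combinations(range(n), nx):
        u = ranks[list(combo)].sum() - offset
        total += 1
        if abs(u - mean) >= dev:
            hits += 1
    return hits / total


def _normal_p(x: np.ndarray, y: np.ndarray, u: float) -> float:
    """Tie-corrected normal approximation with continuity correction."""
    nx, ny = len(x), len(y)
    n = nx + ny
    mean = nx * ny / 2
    _, tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = nx * ny / 12 * ((n + 1) - tie_term)
    if var <= 0:  # all observations identical
        return 1.0
    z = (abs(u - mean) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    return math.erfc(z / math.sqrt(2))


# ---------------------------------------------------------------------------
# Fisher's exact test


def _log_comb(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def fisher_exact(table: Sequence[Sequence[int]]) -> GroupComparison:
    """Two-sided Fisher's exact test on a 2x2 contingency table.

    With row and column margins fixed, the count in cell (0, 0) follows
    a hypergeometric distribution; the two-sided p-value sums the
    probabilities of all tables no more probable than the observed one
    (with a 1 + 1e-7 relative tolerance at ties).  The statistic is the
    sample odds ratio ad/bc.
    """
    (a, b), (c, d) = table
    cells = (a, b, c, d)
    if any(v < 0 or v != int(v) for v in cells):
        raise ValueError(f"table cells must be non-negative integers, got {cells}")
    a, b, c, d = (int(v) for v in cells)
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if n == 0:
        raise ValueError("table must have at least one non-zero margin")
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        odds = _odds_ratio(a, b, c, d)
        return GroupComparison(odds, 1.0, "fisher_exact")  # degenerate margin: single table
    denom = _log_comb(n, c1)
    k_lo, k_hi = max(0, c1 - r2), min(r1, c1)
    log_p = np.array([_log_comb(r1, k) + _log_comb(r2, c1 - k) - denom for k in range(k_lo, k_hi + 1)])
    p_obs = log_p[a - k_lo]
    keep = log_p <= p_obs + math.log1p(1e-7)
    p = float(np.exp(log_p[keep]).sum())
    return GroupComparison(_odds_ratio(a, b, c, d), min(p, 1.0), "fisher_exact")


def _odds_ratio(a, b, c, d) -> float:
    if b * c == 0:
        return math.inf if a * d > 0 else math.nan
    return (a * d) / (b * c)


# ---------------------------------------------------------------------------
# Univariate logistic regression (IRLS)


def fit_univariate_logistic(
    scores: Sequence[float],
    outcomes: Sequence[int],
    tol: float = 1e-8,
    max_iter: int = 50,
) -> LogisticFit:
    """Maximum-likelihood fit of P(death) = 1/(1 + exp(-(b0 + b1*score))).

    Newton/IRLS iterations from b = (log odds of the base rate, 0),
    declared converged when the gradient max-norm drops below ``tol``.
    Raises :class:`SeparationError` on completely separated data (no
    finite maximum exists) and ValueError when only one outcome class
    is present.
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("scores and outcomes must be equal-length 1-d sequences")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("outcomes must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    pos, neg = x[y == 1], x[y == 0]
    if pos.min() > neg.max():
        raise SeparationError(
            "complete separation: every non-survivor scores above every survivor"
        )
    if pos.max() < neg.min():
        raise SeparationError(
            "complete separation: every non-survivor scores below every survivor"
        )

    p_base = y.mean()
    beta = np.array([math.log(p_base / (1 - p_base)), 0.0])
    X = np.column_stack([np.ones_like(x), x])
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1 / (1 + np.exp(-np.clip(eta, -700, 700)))
        w = mu * (1 - mu)
        grad = X.T @ (y - mu)
        if np.abs(grad).max() < tol:
            converged = True
            break
        hess = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"singular weight matrix at iteration {it}: {exc}") from exc
        beta = beta + step
        if not np.all(np.isfinite(beta)):
            raise ValueError("logistic fit diverged (non-finite coefficients)")
    eta = X @ beta
    ll = float(np.sum(y * eta - np.logaddexp(0, eta)))
    mu = 1 / (1 + np.exp(-np.clip(eta, -700, 700)))
    w = mu * (1 - mu)
    se = (math.nan, math.nan)
    try:
        cov = np.linalg.inv((X * w[:, None]).T @ X)
        if np.all(np.diag(cov) > 0):
            se = tuple(np.sqrt(np.diag(cov)))
    except np.linalg.LinAlgError:
        pass
    return LogisticFit(
        beta0=float(beta[0]),
        beta1=float(beta[1]),
        converged=converged,
        iterations=it,
        log_likelihood=ll,
        beta0_se=float(se[0]),
        beta1_se=float(se[1]),
    )


def predict_probability(fit: LogisticFit, score):
    """Probability of death from the logit formula p = 1/(1+exp(-(b0 + b1*x)))."""
    eta = fit.beta0 + fit.beta1 * np.asarray(score, dtype=float)
    p = 1 / (1 + np.exp(-np.clip(eta, -700, 700)))
    return float(p) if np.isscalar(score) else p


# ---------------------------------------------------------------------------
# ROC analysis


def roc_curve(scores: Sequence[float], outcomes: Sequence[int]) -> RocCurve:
    """ROC curve over all distinct thresholds, ties grouped; AUROC by trapezoid.

    The trapezoidal area equals U/(n_pos * n_neg) with tied
    positive/negative pairs counted one half, i.e. the probability that
    a random non-survivor outscores a random survivor.
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("scores and outcomes must be equal-length 1-d sequences")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("outcomes must be binary 0/1")
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both outcome classes must be present")
    order = np.argsort(-x, kind="stable")
    xs, ys = x[order], y[order]
    last_of_group = np.nonzero(np.diff(xs, append=-np.inf) != 0)[0]
    cum_tp = np.cumsum(ys)[last_of_group]
    cum_fp = last_of_group + 1 - cum_tp
    thresholds = np.concatenate([[np.inf], xs[last_of_group]])
    tpr = np.concatenate([[0.0], cum_tp / n_pos])
    fpr = np.concatenate([[0.0], cum_fp / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc)


def optimal_cutoff(curve: RocCurve) -> float:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    Only data thresholds are candidates (the leading +inf sentinel is
    the empty classifier).  Ties in J are broken toward higher
    specificity, then toward the higher threshold.
    """
    j = curve.tpr - curve.fpr
    best = None
    for i in range(1, len(curve.thresholds)):
        key = (j[i], -curve.fpr[i], curve.thresholds[i])
        if best is None or key > (j[best], -curve.fpr[best], curve.thresholds[best]):
            best = i
    if best is None:
        raise ValueError("degenerate ROC curve with no data thresholds")
    return float(curve.thresholds[best])


def confusion_metrics(
    scores: Sequence[float], outcomes: Sequence[int], cutoff: float
) -> ClassifierMetrics:
    """Confusion counts and test characteristics at ``cutoff`` (positive iff score >= cutoff)."""
    x = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("outcomes must be binary 0/1")
    if not (y == 1).any() or not (y == 0).any():
        raise ValueError("both outcome classes must be present")
    pred = x >= cutoff
    return ClassifierMetrics(
        cutoff=float(cutoff),
        tp=int(np.sum(pred & (y == 1))),
        fp=int(np.sum(pred & (y == 0))),
        tn=int(np.sum(~pred & (y == 0))),
        fn=int(np.sum(~pred & (y == 1))),
    )
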