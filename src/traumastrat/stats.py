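"""From-scratch estimators for the validation analyses.

Everything here is implemented directly from the defining formulas:

* odds ratio on a 2x2 table with Woolf log-normal 95% CI and
  Haldane-Anscombe 0.5 correction when a cell is empty;
* Pearson chi-square with optional Yates continuity correction (2x2 only);
* Krippendorff's alpha for two ratings per unit via the coincidence
  matrix, with nominal, ordinal and interval distance metrics;
* binary logistic regression by iteratively reweighted least squares
  (internal standardisation, Wald standard errors, separation detection);
* ROC AUC as the tie-corrected Mann-Whitney probability with a DeLong
  variance for the 95% CI.

scipy supplies only distribution tails (chi2 / normal survival functions)
and mid-ranks; the estimators themselves are authored here.  All results
are small dataclasses serialisable to JSON via ``dataclasses.asdict``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm as norm_dist
from scipy.stats import rankdata

__all__ = [
    "ContingencyTable",
    "OREstimate",
    "ChiSquareResult",
    "AlphaEstimate",
    "LogisticModel",
    "AUCEstimate",
    "StatsUsageError",
    "odds_ratio",
    "chi_square",
    "krippendorff_alpha",
    "fit_logistic",
    "roc_auc",
    "holm_adjust",
]

Z_95 = norm_dist.ppf(0.975)


class StatsUsageError(ValueError):
    """An estimator was called on data outside its preconditions."""


@dataclass
class ContingencyTable:
    """An r x c count table with labelled axes."""

    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise StatsUsageError("counts shape does not match labels")
        if np.any(self.counts < 0):
            raise StatsUsageError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_dict(self) -> dict:
        return {
            "row_labels": self.row_labels,
            "col_labels": self.col_labels,
            "counts": self.counts.astype(int).tolist(),
        }


@dataclass
class OREstimate:
    or_value: float
    ci_low: float
    ci_high: float
    p_value: float
    reference_label: Optional[str] = None
    zero_cell_corrected: bool = False
    method: str = "woolf_log_normal_ci; haldane_anscombe_0.5_on_zero_cell"


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    yates_corrected: bool


@dataclass
class AlphaEstimate:
    alpha: float
    metric: str
    observed_disagreement: float
    expected_disagreement: float
    n_units: int


@dataclass
class LogisticModel:
    intercept: float
    coefficients: np.ndarray  # per-predictor log-odds weights, original scale
    standard_errors: np.ndarray  # Wald SEs (original scale), intercept first
    converged: bool
    n_iterations: int
    separation_suspected: bool = False
    predictor_names: Optional[list[str]] = None

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return expit(self.intercept + X @ self.coefficients)


@dataclass
class AUCEstimate:
    auc: float
    ci_low: float
    ci_high: float
    n_positive: int
    n_negative: int
    method: str = "mann_whitney_ties_half; delong_ci"


# ---------------------------------------------------------------------------
# contingency statistics


def odds_ratio(table: ContingencyTable) -> OREstimate:
    """Odds ratio (a*d)/(b*c) of a 2x2 table, row 2 being the reference.

    The 95% CI uses the Woolf log-OR normal approximation with standard
    error sqrt(1/a + 1/b + 1/c + 1/d); if any cell is zero, 0.5 is added to
    every cell first (Haldane-Anscombe) and the estimate is flagged.  The
    p-value is the two-sided Wald test of log OR = 0.
    """
    if table.counts.shape != (2, 2):
        raise StatsUsageError("odds_ratio requires a 2x2 table")
    counts = table.counts.astype(float)
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise StatsUsageError("odds ratio undefined: a table margin is zero")
    corrected = bool(np.any(counts == 0))
    if corrected:
        counts = counts + 0.5
    a, b = counts[0]
    c, d = counts[1]
    or_value = (a * d) / (b * c)
    se = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
    log_or = float(np.log(or_value))
    z = log_or / se
    return OREstimate(
        or_value=float(or_value),
        ci_low=float(np.exp(log_or - Z_95 * se)),
        ci_high=float(np.exp(log_or + Z_95 * se)),
        p_value=float(2 * norm_dist.sf(abs(z))),
        reference_label=table.row_labels[1],
        zero_cell_corrected=corrected,
    )


def chi_square(table: ContingencyTable, yates: bool = False) -> ChiSquareResult:
    """Pearson chi-square test of independence; Yates correction for 2x2."""
    counts = table.counts.astype(float)
    if counts.sum() <= 0:
        raise StatsUsageError("chi-square undefined on an empty table")
    if yates and counts.shape != (2, 2):
        raise StatsUsageError("Yates correction applies to 2x2 tables only")
    row = counts.sum(axis=1, keepdims=True)
    col = counts.sum(axis=0, keepdims=True)
    expected = row @ col / counts.sum()
    if np.any(expected == 0):
        zero = np.argwhere(expected == 0)[0]
        raise StatsUsageError(
            f"zero expected count at row {table.row_labels[zero[0]]!r}, "
            f"column {table.col_labels[zero[1]]!r}"
        )
    dev = np.abs(counts - expected)
    if yates:
        dev = np.maximum(dev - 0.5, 0.0)
    statistic = float(np.sum(dev**2 / expected))
    df = (counts.shape[0] - 1) * (counts.shape[1] - 1)
    return ChiSquareResult(
        statistic=statistic,
        df=df,
        p_value=float(chi2_dist.sf(statistic, df)),
        yates_corrected=yates,
    )


# ---------------------------------------------------------------------------
# Krippendorff's alpha (two ratings per unit)


def _delta_matrix(categories: Sequence, marginals: np.ndarray, metric: str) -> np.ndarray:
    k = len(categories)
    if metric == "nominal":
        return 1.0 - np.eye(k)
    if metric == "interval":
        try:
            values = np.asarray([float(c) for c in categories])
        except (TypeError, ValueError):
            values = np.arange(k, dtype=float)
        return (values[:, None] - values[None, :]) ** 2
    if metric == "ordinal":
        # delta_ck = (sum of marginals from c to k minus half the end
        # marginals)^2, the standard ordinal distance on coincidence counts
        delta = np.zeros((k, k))
        for c in range(k):
            for d in range(c + 1, k):
                span = marginals[c : d + 1].sum() - (marginals[c] + marginals[d]) / 2.0
                delta[c, d] = delta[d, c] = span**2
        return delta
    raise StatsUsageError(f"unknown alpha metric {metric!r}")


def krippendorff_alpha(
    pairs: Sequence[tuple], metric: str = "nominal", categories: Optional[Sequence] = None
) -> AlphaEstimate:
    """Krippendorff's alpha for units rated twice (two-score design).

    Each unit contributes both ordered pairs to the coincidence matrix
    o_ck; with category marginals n_c and N = sum(n_c):

        Do = sum_{c!=k} o_ck * delta_ck / N
        De = sum_{c!=k} n_c * n_k * delta_ck / (N * (N - 1))
        alpha = 1 - Do / De

    ``categories`` fixes the (ordered) category set; by default it is the
    sorted set of observed labels.  Perfect agreement yields alpha = 1
    exactly; all-identical single-category data make De = 0 and raise.
    """
    if len(pairs) < 2:
        raise StatsUsageError("alpha requires at least 2 units")
    if categories is None:
        categories = sorted({lab for pair in pairs for lab in pair})
    categories = list(categories)
    index = {c: i for i, c in enumerate(categories)}
    k = len(categories)
    o = np.zeros((k, k))
    for a, b in pairs:
        try:
            i, j = index[a], index[b]
        except KeyError as exc:
            raise StatsUsageError(f"label {exc.args[0]!r} not in category set") from exc
        o[i, j] += 1
        o[j, i] += 1
    marginals = o.sum(axis=1)
    n_total = marginals.sum()
    delta = _delta_matrix(categories, marginals, metric)
    do = float(np.sum(o * delta) / n_total)
    de = float(
        np.sum(np.outer(marginals, marginals) * delta) / (n_total * (n_total - 1.0))
    )
    if de == 0.0:
        raise StatsUsageError("expected disagreement is zero (single category observed)")
    alpha = 1.0 if do == 0.0 else 1.0 - do / de
    return AlphaEstimate(
        alpha=alpha,
        metric=metric,
        observed_disagreement=do,
        expected_disagreement=de,
        n_units=len(pairs),
    )


# ---------------------------------------------------------------------------
# logistic regression (IRLS)


def fit_logistic(
    X,
    y,
    predictor_names: Optional[list[str]] = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> LogisticModel:
    """Maximum-likelihood binary logistic fit by IRLS.

    Predictors are standardised internally (the coefficients returned are
    back-transformed to the original scale).  Convergence is declared when
    the maximum absolute score-equation residual max|X'(y - p)| on the
    standardised scale falls below ``tol * n``; complete separation is
    reported via ``separation_suspected`` with ``converged=False`` rather
    than silently diverging.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and np.ndim(y) == 1 and len(y) == X.shape[1]:
        X = X.T
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if p < 1:
        raise StatsUsageError("at least one predictor required")
    if y.shape[0] != n:
        raise StatsUsageError("X and y lengths differ")
    if np.all(y == y[0]):
        raise StatsUsageError("response is constant")

    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = np.column_stack([np.ones(n), (X - mean) / sd])

    beta = np.zeros(p + 1)
    beta[0] = np.log(y.mean() / (1 - y.mean()))
    converged = False
    separation = False
    it = 0
    score_tol = tol * n
    for it in range(1, max_iter + 1):
        eta = Xs @ beta
        mu = expit(eta)
        score = Xs.T @ (y - mu)
        if np.max(np.abs(score)) < score_tol:
            converged = True
            break
        w = mu * (1 - mu)
        if np.max(w) < 1e-12:
            separation = True
            break
        info = Xs.T @ (Xs * w[:, None])
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            # ridge fallback for ill-conditioned (e.g. collinear) designs
            step = np.linalg.solve(info + 1e-10 * np.eye(p + 1), score)
        # step-halving to keep the log-likelihood moving uphill
        ll_old = float(y @ eta - np.logaddexp(0.0, eta).sum())
        scale = 1.0
        for _ in range(30):
            candidate = beta + scale * step
            eta_new = Xs @ candidate
            ll_new = float(y @ eta_new - np.logaddexp(0.0, eta_new).sum())
            if ll_new >= ll_old:
                break
            scale /= 2.0
        beta = beta + scale * step
        if np.max(np.abs(beta[1:])) > 30.0:
            separation = True
            break

    if not converged and not separation:
        # ran out of iterations; flag separation if fit is saturating
        mu = expit(Xs @ beta)
        if np.min(np.abs(y - mu)) < 1e-6:
            separation = True

    eta = Xs @ beta
    w = np.clip(expit(eta) * (1 - expit(eta)), 1e-12, None)
    info = Xs.T @ (Xs * w[:, None])
    try:
        cov_s = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov_s = np.linalg.pinv(info)

    # back-transform: beta_j = beta_sj / sd_j; intercept absorbs the means
    coef = beta[1:] / sd
    intercept = float(beta[0] - np.sum(beta[1:] * mean / sd))
    grad = np.zeros((p + 1, p + 1))
    grad[0, 0] = 1.0
    grad[0, 1:] = -mean / sd
    grad[1:, 1:] = np.diag(1.0 / sd)
    cov = grad @ cov_s @ grad.T
    se = np.sqrt(np.clip(np.diag(cov), 0, None))

    return LogisticModel(
        intercept=intercept,
        coefficients=coef,
        standard_errors=se,
        converged=converged,
        n_iterations=it,
        separation_suspected=separation,
        predictor_names=predictor_names,
    )


# ---------------------------------------------------------------------------
# ROC / AUC


def roc_auc(scores, labels) -> AUCEstimate:
    """AUC as the Mann-Whitney probability (ties count one half).

    The 95% CI comes from the DeLong variance of the placement values; it
    collapses to a point at 0 or 1 for perfectly separated data.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    if len(pos) == 0 or len(neg) == 0:
        raise StatsUsageError("both classes must be present")

    ranks = rankdata(scores)  # mid-ranks handle ties as half-wins
    n_pos, n_neg = len(pos), len(neg)
    auc = float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))

    # DeLong: placement of each positive among negatives and vice versa
    ranks_pos_within = rankdata(pos)
    ranks_neg_within = rankdata(neg)
    v10 = (ranks[labels] - ranks_pos_within) / n_neg  # per-positive placements
    v01 = 1.0 - (ranks[~labels] - ranks_neg_within) / n_pos  # per-negative
    s10 = float(np.var(v10, ddof=1)) if n_pos > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n_neg > 1 else 0.0
    var = s10 / n_pos + s01 / n_neg
    se = float(np.sqrt(max(var, 0.0)))
    return AUCEstimate(
        auc=auc,
        ci_low=float(max(0.0, auc - Z_95 * se)),
        ci_high=float(min(1.0, auc + Z_95 * se)),
        n_positive=n_pos,
        n_negative=n_neg,
    )


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjustment over a declared family of tests."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted.tolist()
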