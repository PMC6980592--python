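"""Statistics core vs independent oracles (closed forms, brute force,
exhaustive enumeration, and established-library cross-checks)."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency
from sklearn.metrics import roc_auc_score
import statsmodels.api as sm

from traumastrat import (
    ContingencyTable,
    StatsUsageError,
    chi_square,
    fit_logistic,
    holm_adjust,
    krippendorff_alpha,
    odds_ratio,
    roc_auc,
)


def table2x2(a, b, c, d):
    return ContingencyTable(["exposed", "reference"], ["yes", "no"], np.array([[a, b], [c, d]]))


# ---------------------------------------------------------------------------
# odds ratio


def test_odds_ratio_exhaustive_small_tables():
    """Every 2x2 table with cells <= 5: estimate matches the closed form
    (with the 0.5 zero-cell correction), CI is ordered, flag set iff a
    cell is empty."""
    for a, b, c, d in itertools.product(range(6), repeat=4):
        table = table2x2(a, b, c, d)
        if min(a + b, c + d, a + c, b + d) == 0:
            with pytest.raises(StatsUsageError):
                odds_ratio(table)
            continue
        est = odds_ratio(table)
        corrected = 0 in (a, b, c, d)
        aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d)) if corrected else (a, b, c, d)
        assert est.zero_cell_corrected == corrected
        assert est.or_value == pytest.approx((aa * dd) / (bb * cc), rel=1e-12)
        assert est.ci_low <= est.or_value <= est.ci_high
        assert 0.0 <= est.p_value <= 1.0


def test_odds_ratio_symmetric_table_is_one():
    est = odds_ratio(table2x2(10, 10, 10, 10))
    assert est.or_value == 1.0
    assert est.ci_low < 1.0 < est.ci_high


def test_odds_ratio_reconstructed_published_counts():
    """Counts rebuilt from the published early-death rates (56.2% of 281
    high-risk vs 14.2% of 2745 low-risk) give an OR of about 7.76."""
    est = odds_ratio(table2x2(158, 123, 390, 2355))
    assert round(est.or_value, 2) == 7.76
    assert est.p_value < 1e-10


def test_odds_ratio_axis_flips():
    est = odds_ratio(table2x2(7, 3, 2, 9))
    # swapping both rows and both columns leaves the OR unchanged
    assert odds_ratio(table2x2(9, 2, 3, 7)).or_value == pytest.approx(est.or_value)
    # inverting one axis inverts the OR
    assert odds_ratio(table2x2(3, 7, 9, 2)).or_value == pytest.approx(1 / est.or_value)


def test_odds_ratio_ci_cross_check_statsmodels():
    sm_table = sm.stats.Table2x2(np.array([[158, 123], [390, 2355]]))
    est = odds_ratio(table2x2(158, 123, 390, 2355))
    lo, hi = sm_table.oddsratio_confint()
    assert est.or_value == pytest.approx(sm_table.oddsratio, rel=1e-12)
    assert est.ci_low == pytest.approx(lo, rel=1e-9)
    assert est.ci_high == pytest.approx(hi, rel=1e-9)


# ---------------------------------------------------------------------------
# chi-square


def _textbook_chi2(counts):
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    stat = 0.0
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            e = counts[i].sum() * counts[:, j].sum() / total
            stat += (counts[i, j] - e) ** 2 / e
    return stat


@pytest.mark.parametrize(
    "counts",
    [
        [[390, 2355], [158, 123]],
        [[10, 20, 30], [15, 12, 40]],
        [[5, 9], [12, 2], [7, 7]],
    ],
)
def test_chi_square_matches_textbook_formula_and_scipy(counts):
    table = ContingencyTable(
        [f"r{i}" for i in range(len(counts))],
        [f"c{j}" for j in range(len(counts[0]))],
        np.array(counts),
    )
    res = chi_square(table)
    assert res.statistic == pytest.approx(_textbook_chi2(counts), rel=1e-12)
    stat, p, df, _ = chi2_contingency(np.array(counts), correction=False)
    assert res.statistic == pytest.approx(stat, rel=1e-12)
    assert res.p_value == pytest.approx(p, rel=1e-9)
    assert res.df == df


def test_chi_square_yates_vs_scipy_2x2():
    for a, b, c, d in [(390, 2355, 158, 123), (12, 5, 7, 20), (30, 30, 31, 29)]:
        table = table2x2(a, b, c, d)
        res = chi_square(table, yates=True)
        stat, p, _, _ = chi2_contingency(np.array([[a, b], [c, d]]), correction=True)
        assert res.statistic == pytest.approx(stat, rel=1e-12)
        assert res.p_value == pytest.approx(p, rel=1e-9)


@settings(max_examples=200, deadline=None)
@given(st.tuples(*[st.integers(0, 30)] * 4))
def test_yates_never_exceeds_uncorrected(cells):
    a, b, c, d = cells
    table = table2x2(a, b, c, d)
    try:
        plain = chi_square(table, yates=False)
    except StatsUsageError:
        return  # degenerate margin
    assert chi_square(table, yates=True).statistic <= plain.statistic + 1e-12


def test_chi_square_degenerate_inputs():
    assert chi_square(table2x2(10, 10, 10, 10)).statistic == 0.0
    assert chi_square(table2x2(10, 10, 10, 10)).p_value == 1.0
    empty_col = ContingencyTable(["r0", "r1"], ["c0", "c1", "c2"],
                                 np.array([[3, 0, 2], [4, 0, 1]]))
    with pytest.raises(StatsUsageError, match="zero expected"):
        chi_square(empty_col)
    with pytest.raises(StatsUsageError, match="2x2"):
        chi_square(ContingencyTable(["r0", "r1"], ["a", "b", "c"],
                                    np.array([[1, 2, 3], [4, 5, 6]])), yates=True)


# ---------------------------------------------------------------------------
# Krippendorff's alpha


def brute_force_nominal_alpha(pairs):
    """Pair-enumeration oracle in exact rational arithmetic: Do from all
    ordered rating pairs within units, De from all ordered pairs of the
    pooled ratings across different slots."""
    ratings = [r for pair in pairs for r in pair]
    n = len(ratings)
    do_num = sum(1 for a, b in pairs for x, y in ((a, b), (b, a)) if x != y)
    do = Fraction(do_num, 2 * len(pairs))
    de_num = sum(
        1 for i in range(n) for j in range(n) if i != j and ratings[i] != ratings[j]
    )
    de = Fraction(de_num, n * (n - 1))
    if de == 0:
        return None
    return 1 - do / de


def test_alpha_perfect_agreement_is_exactly_one():
    est = krippendorff_alpha([("a", "a"), ("b", "b"), ("a", "a")])
    assert est.alpha == 1.0 and est.observed_disagreement == 0.0


def test_alpha_two_crossed_units_hand_value():
    # o = [[0,2],[2,0]], n_c = (2,2): Do = 1, De = 2/3, alpha = -1/2
    est = krippendorff_alpha([("a", "b"), ("b", "a")])
    assert est.alpha == pytest.approx(-0.5, abs=1e-15)


def test_alpha_exhaustive_small_designs_match_pair_enumeration():
    """All two-category rating patterns on 2-4 units agree exactly with
    the rational pair-enumeration oracle."""
    checked = 0
    for n_units in (2, 3, 4):
        for labels in itertools.product("ab", repeat=2 * n_units):
            pairs = [(labels[2 * i], labels[2 * i + 1]) for i in range(n_units)]
            expected = brute_force_nominal_alpha(pairs)
            if expected is None:
                with pytest.raises(StatsUsageError):
                    krippendorff_alpha(pairs, categories=["a", "b"])
                continue
            est = krippendorff_alpha(pairs, categories=["a", "b"])
            assert est.alpha == pytest.approx(float(expected), abs=1e-12)
            checked += 1
    assert checked > 200


def test_alpha_symmetry_and_permutation_invariance():
    pairs = [("a", "b"), ("b", "b"), ("c", "a"), ("a", "a"), ("b", "c")]
    base = krippendorff_alpha(pairs).alpha
    assert krippendorff_alpha([(b, a) for a, b in pairs]).alpha == pytest.approx(base)
    assert krippendorff_alpha(list(reversed(pairs))).alpha == pytest.approx(base)


def test_alpha_ordinal_and_interval_metrics():
    pairs = [("1", "2"), ("2", "2"), ("3", "3"), ("1", "3")]
    nominal = krippendorff_alpha(pairs, metric="nominal", categories=["1", "2", "3"])
    ordinal = krippendorff_alpha(pairs, metric="ordinal", categories=["1", "2", "3"])
    interval = krippendorff_alpha(pairs, metric="interval", categories=["1", "2", "3"])
    # adjacent-category confusions are punished less under ordered metrics
    assert ordinal.alpha != nominal.alpha
    assert interval.alpha != nominal.alpha
    for est in (nominal, ordinal, interval):
        assert -1.0 < est.alpha <= 1.0
    with pytest.raises(StatsUsageError, match="metric"):
        krippendorff_alpha(pairs, metric="ratio")


def test_alpha_degenerate_inputs():
    with pytest.raises(StatsUsageError, match="2 units"):
        krippendorff_alpha([("a", "a")])
    with pytest.raises(StatsUsageError, match="single category"):
        krippendorff_alpha([("a", "a"), ("a", "a")])


# ---------------------------------------------------------------------------
# ROC / AUC


def brute_force_auc(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def test_auc_worked_examples():
    assert roc_auc([1, 2, 3, 4], [0, 0, 1, 1]).auc == 1.0
    assert roc_auc([1, 2, 3, 4], [0, 1, 0, 1]).auc == 0.75
    assert roc_auc([0, 1, 0, 1, 1], [0, 1, 0, 1, 1]).auc == 1.0


def test_auc_matches_pair_counting_on_random_small_sets():
    rng = np.random.default_rng(2024)
    for trial in range(300):
        n = int(rng.integers(3, 51))
        scores = rng.integers(0, 6, size=n).astype(float)  # heavy ties
        labels = rng.integers(0, 2, size=n).astype(bool)
        if labels.all() or not labels.any():
            continue
        est = roc_auc(scores, labels)
        assert est.auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)
        assert est.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)
        assert 0.0 <= est.ci_low <= est.auc <= est.ci_high <= 1.0


def test_auc_null_scores_cover_half():
    rng = np.random.default_rng(7)
    scores = rng.normal(size=10_000)
    labels = rng.random(10_000) < 0.3
    est = roc_auc(scores, labels)
    assert est.ci_low < 0.5 < est.ci_high
    assert abs(est.auc - 0.5) < 0.02


def test_auc_single_class_rejected():
    with pytest.raises(StatsUsageError):
        roc_auc([1.0, 2.0], [True, True])


# ---------------------------------------------------------------------------
# logistic regression


def test_logistic_null_model():
    rng = np.random.default_rng(11)
    x = rng.normal(size=2000)
    y = rng.random(2000) < 0.35
    fit = fit_logistic(x[:, None], y.astype(float))
    assert fit.converged
    assert abs(fit.coefficients[0]) < 3 * fit.standard_errors[1]
    assert fit.intercept == pytest.approx(math.log(y.mean() / (1 - y.mean())), abs=0.15)


def test_logistic_parameter_recovery_and_score_equations():
    rng = np.random.default_rng(42)
    n = 20_000
    x = rng.normal(size=n)
    p = 1 / (1 + np.exp(-(-1.0 + 0.8 * x)))
    y = (rng.random(n) < p).astype(float)
    fit = fit_logistic(x[:, None], y)
    assert fit.converged and not fit.separation_suspected
    assert abs(fit.intercept - (-1.0)) < 3 * fit.standard_errors[0]
    assert abs(fit.coefficients[0] - 0.8) < 3 * fit.standard_errors[1]
    # score equations hold at the optimum
    resid = y - fit.predict_proba(x[:, None])
    assert abs(resid.sum()) < 1e-4 * n
    assert abs((x * resid).sum()) < 1e-4 * n


def test_logistic_cross_check_statsmodels():
    rng = np.random.default_rng(3)
    n = 5000
    X = rng.normal(size=(n, 2))
    eta = 0.3 - 0.6 * X[:, 0] + 1.1 * X[:, 1]
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    fit = fit_logistic(X, y)
    ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
    assert fit.intercept == pytest.approx(ref.params[0], abs=1e-6)
    assert fit.coefficients == pytest.approx(ref.params[1:], abs=1e-6)
    assert fit.standard_errors == pytest.approx(ref.bse, rel=1e-4)


def test_logistic_separation_flagged():
    x = np.array([-2.0, -1.0, -0.5, 0.5, 1.0, 2.0])
    y = np.array([0, 0, 0, 1, 1, 1], dtype=float)
    fit = fit_logistic(x[:, None], y)
    assert fit.separation_suspected and not fit.converged


def test_logistic_usage_errors():
    with pytest.raises(StatsUsageError, match="constant"):
        fit_logistic(np.array([[1.0], [2.0]]), np.array([1.0, 1.0]))


def test_duplicated_predictor_leaves_ranking_unchanged():
    rng = np.random.default_rng(8)
    x = rng.normal(size=500)
    y = (rng.random(500) < 1 / (1 + np.exp(-x))).astype(float)
    single = fit_logistic(x[:, None], y)
    doubled = fit_logistic(np.column_stack([x, x]), y)
    auc_single = roc_auc(single.predict_proba(x[:, None]), y.astype(bool)).auc
    auc_doubled = roc_auc(doubled.predict_proba(np.column_stack([x, x])), y.astype(bool)).auc
    assert auc_doubled == pytest.approx(auc_single, abs=1e-9)


# ---------------------------------------------------------------------------
# multiple testing


def test_holm_adjustment_known_example():
    adjusted = holm_adjust([0.01, 0.04, 0.03, 0.005])
    assert adjusted == pytest.approx([0.03, 0.06, 0.06, 0.02])
    assert holm_adjust([0.5]) == [0.5]
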