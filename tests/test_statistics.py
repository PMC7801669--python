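"""Statistics layer: exact enumeration oracles for the signed-rank test and
AUC, brute-force partial-correlation oracles, and composite-index
properties."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from muscleqmri.statistics import (
    classify_fibrosis,
    composed_index,
    delong_ci,
    incremental_panel,
    kruskal_wallis,
    paired_wilcoxon,
    partial_spearman,
    roc_auc,
    spearman,
)


# -------------------------------------------------------- paired Wilcoxon


def wilcoxon_exact_oracle(deltas):
    """Two-sided exact p by enumerating every sign pattern (no |d| ties)."""
    d = np.asarray(deltas, float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    total = ranks.sum()
    lo, hi = min(w_obs, total - w_obs), max(w_obs, total - w_obs)
    count = 0
    n = d.size
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if w <= lo or w >= hi:
            count += 1
    return count / 2**n


def test_wilcoxon_all_positive_n6_extreme_case():
    res = paired_wilcoxon([5, 6, 7, 8, 9, 10], [1, 2, 3, 4, 5, 6.5])
    assert res.p_value == pytest.approx(2 / 64)


def test_wilcoxon_matches_enumeration_oracle():
    # hand-crafted deltas without |d| ties (the exact null assumes none)
    inj = np.array([5.0, 3.2, 8.1, 2.0, 9.5, 4.4, 7.7, 1.1])
    ctl = np.array([4.1, 3.9, 6.0, 2.5, 5.0, 4.8, 5.5, 1.9])
    res = paired_wilcoxon(inj, ctl)
    assert res.p_value == pytest.approx(wilcoxon_exact_oracle(inj - ctl), abs=1e-12)


def test_wilcoxon_more_enumeration_cases():
    rng = np.random.default_rng(7)
    for n in (5, 9, 12):
        d = rng.normal(0.3, 1.0, n)
        d = np.where(d == 0, 0.1, d)
        res = paired_wilcoxon(d, np.zeros(n))
        assert res.p_value == pytest.approx(wilcoxon_exact_oracle(d), abs=1e-12), n


def test_wilcoxon_zero_deltas_degenerate():
    res = paired_wilcoxon([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
    assert np.isnan(res.p_value)
    assert res.n == 0
    assert res.effect["delta_median_iqr"] == (0.0, 0.0)


def test_wilcoxon_bonferroni_capped():
    res = paired_wilcoxon([5, 6, 7, 8, 9, 10], [1, 2, 3, 4, 5, 6.5], m_tests=100)
    assert res.p_adjusted == 1.0
    res2 = paired_wilcoxon([5, 6, 7, 8, 9, 10], [1, 2, 3, 4, 5, 6.5], m_tests=4)
    assert res2.p_adjusted == pytest.approx(4 * res2.p_value)
    assert res2.p_adjusted >= res2.p_value


# --------------------------------------------------------- Kruskal-Wallis


def test_kruskal_identical_groups():
    g = [1.0, 2.0, 3.0, 4.0]
    res = kruskal_wallis(g, g, g)
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value > 0.99


def test_kruskal_hand_ranked_three_groups():
    """H computed by hand for 3 small tie-free groups."""
    a, b, c = [1.0, 2.0], [3.0, 4.0], [5.0, 6.0]
    # ranks 1..6, rank sums 3, 7, 11; H = 12/(6*7) * sum(R^2/n) - 3*7
    h_manual = 12 / (6 * 7) * (9 / 2 + 49 / 2 + 121 / 2) - 21
    res = kruskal_wallis(a, b, c)
    assert res.statistic == pytest.approx(h_manual)


def test_kruskal_two_groups_consistent_with_ranksum():
    from scipy.stats import mannwhitneyu

    rng = np.random.default_rng(0)
    a = rng.normal(0, 1, 30)
    b = rng.normal(1.0, 1, 30)
    res = kruskal_wallis(a, b)
    p_mw = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
    assert (res.p_value < 0.05) == (p_mw < 0.05)


def test_kruskal_rejects_small_group():
    with pytest.raises(ValueError):
        kruskal_wallis([1.0, 2.0], [3.0])


# ------------------------------------------------------------- Spearman


def test_spearman_monotone_and_reverse():
    x = np.array([1.0, 2.0, 5.0, 7.0, 8.0, 11.0])
    assert spearman(x, np.exp(x)).r == pytest.approx(1.0)
    assert spearman(x, -(x**3)).r == pytest.approx(-1.0)


def test_spearman_hand_rank_formula():
    x = [3.0, 1.0, 4.0, 1.5, 5.0, 9.0]
    y = [2.0, 0.5, 7.0, 1.0, 3.0, 8.0]
    d = rankdata(x) - rankdata(y)
    r_hand = 1 - 6 * np.sum(d**2) / (6 * (36 - 1))  # no ties
    assert spearman(x, y).r == pytest.approx(r_hand)


def test_spearman_rejects_constant():
    with pytest.raises(ValueError):
        spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


def partial_rank_oracle(x, y, covs):
    """Partial correlation on mid-ranks via the precision matrix."""
    cols = [rankdata(x), rankdata(y)] + [rankdata(c) for c in covs]
    C = np.corrcoef(np.vstack(cols))
    P = np.linalg.inv(C)
    return -P[0, 1] / np.sqrt(P[0, 0] * P[1, 1])


def test_partial_spearman_brute_force_oracle():
    rng = np.random.default_rng(3)
    z = rng.normal(0, 1, 40)
    x = z + rng.normal(0, 1, 40)
    y = z + rng.normal(0, 1, 40)
    c1 = z + rng.normal(0, 0.5, 40)
    c2 = rng.normal(0, 1, 40)
    res = partial_spearman(x, y, [c1, c2])
    assert res.r == pytest.approx(partial_rank_oracle(x, y, [c1, c2]), abs=1e-10)
    assert res.n_covariates == 2


def test_partial_spearman_agrees_with_pingouin():
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(5)
    df = pd.DataFrame(
        {
            "x": rng.normal(0, 1, 60),
            "y": rng.normal(0, 1, 60),
            "c": rng.integers(0, 4, 60).astype(float),
        }
    )
    df["y"] += 0.5 * df["x"] + 0.3 * df["c"]
    ours = partial_spearman(df.x, df.y, [df.c.to_numpy()])
    ref = pingouin.partial_corr(df, x="x", y="y", covar="c", method="spearman")
    assert ours.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-6)


def test_partial_spearman_no_covariates_equals_spearman():
    rng = np.random.default_rng(1)
    x, y = rng.normal(0, 1, 25), rng.normal(0, 1, 25)
    a, b = partial_spearman(x, y), spearman(x, y)
    assert a.r == pytest.approx(b.r, abs=1e-14)
    assert a.p_value == pytest.approx(b.p_value, abs=1e-14)


def test_partial_spearman_independent_covariate_changes_little():
    rng = np.random.default_rng(2)
    z = rng.normal(0, 1, 400)
    x = z + rng.normal(0, 1, 400)
    y = z + rng.normal(0, 1, 400)
    c = rng.normal(0, 1, 400)  # independent of everything
    assert partial_spearman(x, y, [c]).r == pytest.approx(spearman(x, y).r, abs=0.05)


def test_partial_spearman_removes_covariate_driven_association():
    rng = np.random.default_rng(4)
    c = rng.normal(0, 1, 500)
    x = c + rng.normal(0, 0.2, 500)
    y = np.exp(c)  # monotone function of the covariate
    assert abs(spearman(x, y).r) > 0.9
    res = partial_spearman(x, y, [c])
    assert res.r == 0.0  # no rank variation left after adjustment
    y_noisy = np.exp(c) + rng.normal(0, 0.05, 500)
    assert abs(partial_spearman(x, y_noisy, [c]).r) < 0.15


def test_partial_spearman_rejects_collinear_covariates():
    rng = np.random.default_rng(6)
    x, y = rng.normal(0, 1, 30), rng.normal(0, 1, 30)
    c = rng.normal(0, 1, 30)
    with pytest.raises(ValueError, match="[Cc]ollinear"):
        partial_spearman(x, y, [c, 2 * c])


# ----------------------------------------------------------- classification


def test_classify_threshold_boundaries():
    assert classify_fibrosis(14.0) == "normal"
    assert classify_fibrosis(15.0) == "fibrotic"
    assert classify_fibrosis(0.0) == "normal"
    labels = classify_fibrosis(np.array([8.0, 14.0, 14.1, 25.0]))
    assert list(labels) == ["normal", "normal", "fibrotic", "fibrotic"]
    with pytest.raises(ValueError):
        classify_fibrosis(120.0)


# -------------------------------------------------------------------- AUC


def auc_pair_count_oracle(scores, labels):
    s = np.asarray(scores, float)
    y = np.asarray(labels, bool)
    pos, neg = s[y], s[~y]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (pos.size * neg.size)


def test_auc_perfect_separation():
    auc, ci = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
    assert auc == 1.0
    assert ci[1] <= 1.0


def test_auc_all_tied_scores():
    auc, _ = roc_auc(np.ones(10), [0] * 5 + [1] * 5)
    assert auc == 0.5


def test_auc_matches_pair_counting_oracle():
    rng = np.random.default_rng(0)
    scores = np.round(rng.normal(0, 1, 40), 1)  # rounding induces ties
    labels = rng.random(40) < 0.4
    if labels.sum() in (0, 40):
        labels[0] = ~labels[0]
    auc, _ = delong_ci(scores, labels)
    assert auc == pytest.approx(auc_pair_count_oracle(scores, labels), abs=1e-12)


def test_auc_matches_sklearn():
    sklearn_metrics = pytest.importorskip("sklearn.metrics")
    rng = np.random.default_rng(1)
    scores = rng.normal(0, 1, 60)
    labels = rng.random(60) < 0.5
    auc, _ = delong_ci(scores, labels)
    assert auc == pytest.approx(sklearn_metrics.roc_auc_score(labels, scores), abs=1e-12)


def test_auc_complement_identity():
    rng = np.random.default_rng(2)
    scores = rng.normal(0, 1, 50)
    labels = rng.random(50) < 0.5
    a1, _ = delong_ci(scores, labels)
    a2, _ = delong_ci(-scores, labels)
    assert a1 + a2 == pytest.approx(1.0, abs=1e-12)


def test_delong_ci_contains_auc_and_shrinks():
    rng = np.random.default_rng(3)
    for n in (30, 300):
        scores = np.concatenate([rng.normal(0, 1, n), rng.normal(1, 1, n)])
        labels = np.array([0] * n + [1] * n, bool)
        auc, (lo, hi) = delong_ci(scores, labels)
        assert lo <= auc <= hi
        if n == 30:
            width30 = hi - lo
        else:
            assert hi - lo < width30


def test_auc_requires_both_classes():
    with pytest.raises(ValueError):
        roc_auc([1.0, 2.0], [1, 1])


# --------------------------------------------------------- composite index


def _toy_table(n=200, seed=0):
    rng = np.random.default_rng(seed)
    y = rng.random(n) < 0.5
    df = pd.DataFrame(
        {
            "m1": y + rng.normal(0, 1.0, n),
            "m2": y + rng.normal(0, 1.0, n),
            "noise": rng.normal(0, 1, n),
            "flat": np.ones(n),
        }
    )
    return df, y


def test_single_metric_panel_equals_univariate_auc():
    df, y = _toy_table()
    res = composed_index(df, ["m1"], y)
    auc_uni, _ = delong_ci(df["m1"].to_numpy(), y)
    assert res.auc == pytest.approx(max(auc_uni, 1 - auc_uni), abs=1e-12)


def test_duplicated_metric_is_idempotent():
    df, y = _toy_table()
    a = composed_index(df, ["m1", "m2"], y)
    b = composed_index(df, ["m1", "m2", "m1"], y)
    assert a.auc == pytest.approx(b.auc, abs=1e-12)
    assert a.metrics == b.metrics


def test_composite_invariant_to_affine_rescaling():
    df, y = _toy_table()
    df2 = df.copy()
    df2["m1"] = 100.0 * df2["m1"] - 7.0
    a = composed_index(df, ["m1", "m2"], y)
    b = composed_index(df2, ["m1", "m2"], y)
    assert b.auc == pytest.approx(a.auc, abs=1e-12)


def test_negatively_oriented_metric_contributes_positively():
    df, y = _toy_table()
    df2 = df.copy()
    df2["m1"] = -df2["m1"]
    a = composed_index(df, ["m1", "m2"], y)
    b = composed_index(df2, ["m1", "m2"], y)
    assert b.auc == pytest.approx(a.auc, abs=1e-12)
    assert b.signs["m1"] == -a.signs["m1"]


def test_complementary_metrics_combine_better():
    """Two independent AUC~0.75 markers: the composite beats each alone."""
    rng = np.random.default_rng(11)
    n = 500
    y = np.arange(n) < n // 2
    df = pd.DataFrame(
        {
            "m1": y * 1.0 + rng.normal(0, 1.05, n),
            "m2": y * 1.0 + rng.normal(0, 1.05, n),
        }
    )
    a1, _ = delong_ci(df.m1.to_numpy(), y)
    a2, _ = delong_ci(df.m2.to_numpy(), y)
    combo = composed_index(df, ["m1", "m2"], y)
    assert combo.auc > max(a1, a2)


def test_zero_iqr_metric_excluded_with_warning():
    df, y = _toy_table()
    with pytest.warns(RuntimeWarning):
        res = composed_index(df, ["m1", "flat"], y)
    assert res.metrics == ("m1",)


def test_incremental_panel_prefixes():
    df, y = _toy_table()
    results = incremental_panel(df, ["m1", "m2", "noise"], y)
    assert len(results) == 3
    assert results[0].metrics == ("m1",)
    uni = composed_index(df, ["m1"], y)
    assert results[0].auc == pytest.approx(uni.auc, abs=1e-12)
    # a pure-noise metric should not catastrophically destroy the panel
    assert results[2].auc > 0.5
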