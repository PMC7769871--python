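"""Rank tests, regressions and diagnostics against independent oracles."""

import itertools

import numpy as np
import pytest
from scipy import stats

import pigamu as pg
from pigamu.inference import (
    REGRESSION_PAIRS,
    kruskal_wallis,
    pairwise_posthoc,
    regression_suite,
    residual_diagnostics,
    simple_regression,
)
from conftest import per_animal_wide

FIXTURE = [[1, 2, 3], [4, 5, 6], [7, 8, 9]]


def test_kruskal_wallis_hand_fixture():
    """Separated groups {1,2,3},{4,5,6},{7,8,9}: rank sums 6/15/24 give H = 7.2."""
    res = kruskal_wallis(FIXTURE)
    assert res.h_statistic == pytest.approx(7.2, rel=1e-12)
    assert res.df == 2
    assert res.p_value == pytest.approx(stats.chi2.sf(7.2, 2), rel=1e-12)


def test_kruskal_wallis_identical_groups():
    res = kruskal_wallis([[5, 5], [5, 5], [5, 5]])
    assert res.h_statistic == 0.0 and res.p_value == 1.0


def test_kruskal_wallis_matches_scipy_with_ties():
    rng = np.random.default_rng(3)
    for _ in range(20):
        groups = [rng.integers(0, 6, rng.integers(3, 12)).astype(float) for _ in range(3)]
        if np.unique(np.concatenate(groups)).size == 1:
            continue
        ours = kruskal_wallis(groups)
        ref = stats.kruskal(*groups)
        assert ours.h_statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-12)


def test_kruskal_wallis_monotone_transform_invariant():
    rng = np.random.default_rng(5)
    groups = [rng.normal(size=8), rng.normal(1, 1, 6), rng.normal(2, 1, 7)]
    base = kruskal_wallis(groups)
    for f in (np.exp, lambda x: x**3, lambda x: 5 * x - 2):
        trans = kruskal_wallis([f(np.asarray(g)) for g in groups])
        assert trans.h_statistic == pytest.approx(base.h_statistic, rel=1e-12)


def test_kruskal_wallis_exact_permutation_matches_enumeration_oracle():
    """Exact permutation p on a tiny dataset vs independent enumeration."""
    groups = [[1.0, 7.0], [2.0, 6.0], [9.0, 3.0]]
    res = kruskal_wallis(groups, p_method="permutation")
    pooled = np.array([v for g in groups for v in g])
    h_obs = stats.kruskal(*groups).statistic
    count = total = 0
    for perm in itertools.permutations(range(6)):
        total += 1
        g = [pooled[list(perm[:2])], pooled[list(perm[2:4])], pooled[list(perm[4:])]]
        if stats.kruskal(*g).statistic >= h_obs - 1e-12:
            count += 1
    assert res.p_value == pytest.approx(count / total, rel=1e-12)


def test_kruskal_wallis_chi2_close_to_permutation_for_moderate_n():
    rng = np.random.default_rng(11)
    groups = [rng.normal(size=6), rng.normal(0.5, 1, 5), rng.normal(size=6)]
    chi2_p = kruskal_wallis(groups).p_value
    perm_p = kruskal_wallis(
        groups, p_method="permutation", n_permutations=20_000, rng=1
    ).p_value
    assert abs(chi2_p - perm_p) < 0.02


def test_pairwise_bonferroni_multiplier_and_cap():
    rng = np.random.default_rng(2)
    groups = {k: rng.normal(i, 1, 12) for i, k in enumerate("abcd")}
    adjusted, raw = pairwise_posthoc(groups)
    assert len(adjusted) == 6  # 4 groups -> 6 pairs, multiplier 6
    for pair, p in raw.items():
        assert adjusted[pair] == pytest.approx(min(1.0, 6 * p), rel=1e-12)
        assert adjusted[pair] >= p
    # identical groups compare as p = 1
    adj2, _ = pairwise_posthoc({"x": [1, 2, 3], "y": [1, 2, 3]})
    assert adj2[("x", "y")] == 1.0


def test_pairwise_rank_sum_matches_exact_null_distribution():
    """Small tie-free samples: raw p equals scipy's exact Mann-Whitney p."""
    a, b = [1.0, 3.0, 5.0, 7.0], [2.0, 4.0, 6.0, 20.0]
    _, raw = pairwise_posthoc({"a": a, "b": b})
    expected = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
    assert raw[("a", "b")] == pytest.approx(expected, rel=1e-12)


def test_pairwise_signed_rank_requires_alignment():
    with pytest.raises(ValueError, match="equal-length"):
        pairwise_posthoc({"a": [1, 2, 3], "b": [1, 2]}, method="signed_rank")
    adj, _ = pairwise_posthoc(
        {"a": [1.0, 5.0, 3.0, 9.0, 2.0, 8.0], "b": [2.0, 1.0, 4.0, 3.0, 0.5, 6.0]},
        method="signed_rank",
    )
    assert 0 <= adj[("a", "b")] <= 1


def test_pairwise_familywise_error_under_global_null():
    """Bonferroni keeps the familywise type-I error at or below alpha."""
    rng = np.random.default_rng(17)
    alpha, n_sim, rejections = 0.05, 2000, 0
    for _ in range(n_sim):
        groups = {k: rng.normal(size=10) for k in "abcd"}
        adjusted, _ = pairwise_posthoc(groups)
        if any(p <= alpha for p in adjusted.values()):
            rejections += 1
    # binomial(2000, 0.05) 3-sigma upper bound ~ 0.065
    assert rejections / n_sim <= 0.065


def test_simple_regression_perfect_fit():
    x = np.arange(5.0)
    res = simple_regression(x, 2 * x + 1)
    assert res.slope == pytest.approx(2, rel=1e-12)
    assert res.intercept == pytest.approx(1, rel=1e-12)
    assert res.r2 == pytest.approx(1, abs=1e-12)
    assert res.adj_r2 == pytest.approx(1, abs=1e-12)


def test_adjusted_r2_formula():
    # n = 10, r2 = 0.5 -> adj r2 = 1 - 0.5 * 9/8 = 0.4375
    assert 1 - (1 - 0.5) * 9 / 8 == pytest.approx(0.4375)
    rng = np.random.default_rng(4)
    x = rng.normal(size=10)
    res = simple_regression(x, x + rng.normal(size=10))
    assert res.adj_r2 == pytest.approx(1 - (1 - res.r2) * 9 / 8, rel=1e-12)
    assert res.adj_r2 <= res.r2


def test_simple_regression_matches_normal_equations():
    x = np.array([1.0, 2.5, 3.1, 4.9, 6.0, 7.2])
    y = np.array([2.2, 4.1, 5.9, 9.0, 12.5, 13.1])
    res = simple_regression(x, y)
    # closed form: beta = Sxy/Sxx, alpha = ybar - beta xbar, SE from RSS
    sxx = np.sum((x - x.mean()) ** 2)
    beta = np.sum((x - x.mean()) * (y - y.mean())) / sxx
    alpha = y.mean() - beta * x.mean()
    resid = y - alpha - beta * x
    se = np.sqrt(np.sum(resid**2) / (len(x) - 2) / sxx)
    assert res.slope == pytest.approx(beta, rel=1e-10)
    assert res.intercept == pytest.approx(alpha, rel=1e-10)
    assert res.slope_se == pytest.approx(se, rel=1e-10)
    t = beta / se
    assert res.p_value == pytest.approx(2 * stats.t.sf(abs(t), len(x) - 2), rel=1e-10)


def test_simple_regression_degenerate_design():
    with pytest.raises(ValueError, match="constant"):
        simple_regression([3, 3, 3, 3], [1, 2, 3, 4])


def test_regression_suite_models_and_noiseless_recovery(small_cohort):
    _, amu = small_cohort
    wide = per_animal_wide(amu)
    results = regression_suite(wide)
    expected = {f"{p}->{r}" for p, r in REGRESSION_PAIRS} | {"herd_size->total"}
    assert set(results) == expected
    # noiseless link: response exactly 0.3 * predictor
    wide2 = wide.copy()
    wide2["piglet"] = 0.3 * wide2["sow"]
    res = regression_suite(wide2)["sow->piglet"]
    assert res.slope == pytest.approx(0.3, rel=1e-9)
    assert res.r2 == pytest.approx(1, abs=1e-9)
    # permuting farms changes nothing
    shuffled = wide.sample(frac=1, random_state=0)
    res_a = regression_suite(wide)["sow->piglet"]
    res_b = regression_suite(shuffled)["sow->piglet"]
    assert res_a.slope == pytest.approx(res_b.slope, rel=1e-12)


def test_diagnostics_normal_residuals_mostly_pass():
    ok = 0
    for seed in range(20):
        rng = np.random.default_rng(100 + seed)
        x = rng.uniform(0, 10, 200)
        e = rng.standard_normal(200)
        d = residual_diagnostics(x, e)
        if d.normality_p > 0.05 and d.het_p > 0.05:
            ok += 1
    assert ok >= 17  # >= ~90% of seeds


def test_diagnostics_flag_heteroscedasticity():
    flagged = 0
    for seed in range(20):
        rng = np.random.default_rng(200 + seed)
        x = rng.uniform(0.5, 10, 200)
        e = rng.standard_normal(200) * x  # residual variance proportional to x^2
        d = residual_diagnostics(x, e)
        if d.het_p <= 0.05:
            flagged += 1
    assert flagged >= 18


def test_diagnostics_zero_residuals_not_assessable():
    d = residual_diagnostics([1, 2, 3], [0.0, 0.0, 0.0])
    assert not d.assessable
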