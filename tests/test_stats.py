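"""Statistics layer against from-scratch oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from plaqueband.stats import (
    ContingencyTable,
    FactorialDesign,
    benjamini_hochberg,
    classify_response,
    correlation,
    ddct_fold_change,
    fisher_exact,
    kruskal_wallis,
    mann_whitney,
    proportion,
    round_half_up,
    two_way_anova,
)

# ---------------------------------------------------------------- ANOVA


def anova_ss_oracle(y, a, b):
    """Textbook sums-of-squares for a balanced two-way design."""
    y = np.asarray(y, float)
    a = np.asarray(a)
    b = np.asarray(b)
    grand = y.mean()
    ss_a = sum(
        (y[a == lv]).size * (y[a == lv].mean() - grand) ** 2 for lv in np.unique(a)
    )
    ss_b = sum(
        (y[b == lv]).size * (y[b == lv].mean() - grand) ** 2 for lv in np.unique(b)
    )
    ss_cells = 0.0
    ss_err = 0.0
    for la in np.unique(a):
        for lb in np.unique(b):
            cell = y[(a == la) & (b == lb)]
            ss_cells += cell.size * (cell.mean() - grand) ** 2
            ss_err += ((cell - cell.mean()) ** 2).sum()
    ss_ab = ss_cells - ss_a - ss_b
    return ss_a, ss_b, ss_ab, ss_err


def balanced_design(rng, n_per_cell=5):
    levels_a = np.repeat(["Aw", "A+"], 2 * n_per_cell)
    levels_b = np.tile(np.repeat(["STD", "TWD"], n_per_cell), 2)
    y = rng.normal(10, 2, size=4 * n_per_cell)
    y[(levels_a == "A+") & (levels_b == "TWD")] += 3.0
    return y, levels_a, levels_b


def test_anova_f_matches_sums_of_squares_oracle(rng):
    y, a, b = balanced_design(rng)
    res = two_way_anova(FactorialDesign(y, a, b))
    ss_a, ss_b, ss_ab, ss_err = anova_ss_oracle(y, a, b)
    df_err = len(y) - 4
    for key, ss, dfe in (("A", ss_a, 1), ("B", ss_b, 1), ("A:B", ss_ab, 1)):
        f_expect = (ss / dfe) / (ss_err / df_err)
        assert res[key].statistic == pytest.approx(f_expect, rel=1e-9)
        assert res[key].df == (dfe, df_err)


def test_anova_identical_cell_means_give_zero_f(rng):
    n = 6
    a = np.repeat(["x", "y"], 2 * n)
    b = np.tile(np.repeat(["u", "v"], n), 2)
    noise = rng.normal(0, 1, n)
    y = np.concatenate([noise] * 4)  # every cell has the same values
    res = two_way_anova(FactorialDesign(y, a, b))
    for key in ("A", "B", "A:B"):
        assert res[key].statistic == pytest.approx(0.0, abs=1e-9)


def test_anova_decomposition_on_balanced_design(rng):
    y, a, b = balanced_design(rng, n_per_cell=4)
    ss_a, ss_b, ss_ab, ss_err = anova_ss_oracle(y, a, b)
    ss_total = ((y - y.mean()) ** 2).sum()
    assert ss_a + ss_b + ss_ab + ss_err == pytest.approx(ss_total, rel=1e-9)


def test_anova_one_observation_per_cell_rejected():
    y = [1.0, 2.0, 3.0, 4.0]
    a = ["x", "x", "y", "y"]
    b = ["u", "v", "u", "v"]
    with pytest.raises(ValueError, match="degrees of freedom"):
        two_way_anova(FactorialDesign(y, a, b))


def test_anova_empty_cell_rejected():
    y = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
    a = ["x", "x", "x", "x", "y", "y"]
    b = ["u", "u", "v", "v", "u", "u"]  # cell (y, v) empty
    with pytest.raises(ValueError, match="cell"):
        two_way_anova(FactorialDesign(y, a, b))


# ---------------------------------------------------------- Mann-Whitney


def mw_enumeration_oracle(x, y):
    """Exact Mann-Whitney two-sided p by full enumeration (tie-free)."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        us.append(sum(1 for xi in xs for yj in ys if xi > yj))
    us = np.array(us)
    p_low = (us <= u_obs).mean()
    p_high = (us >= u_obs).mean()
    return min(1.0, 2 * min(p_low, p_high))


def test_mw_identical_samples_give_half_u():
    x = [1.0, 2.0, 3.0, 4.0]
    res = mann_whitney(x, x)
    assert res.statistic == len(x) ** 2 / 2


def test_mw_complete_separation_n3_exact_p():
    """All x below all y with n1=n2=3: exact two-sided p = 2/20 = 0.1."""
    res = mann_whitney([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
    assert res.extras["method"] == "exact"
    assert res.p_value == pytest.approx(0.1)


def test_mw_exact_p_matches_enumeration(rng):
    for _ in range(10):
        x = rng.normal(0, 1, 5)
        y = rng.normal(0.5, 1, 5)
        res = mann_whitney(x, y)
        assert res.extras["method"] == "exact"
        assert res.p_value == pytest.approx(mw_enumeration_oracle(x, y), abs=1e-12)


def test_mw_u_plus_u_prime_is_n1_n2(rng):
    x = rng.normal(size=8)
    y = rng.normal(size=11)
    u = mann_whitney(x, y).statistic
    u_prime = mann_whitney(y, x).statistic
    assert u + u_prime == pytest.approx(len(x) * len(y))


def test_mw_large_or_tied_samples_use_normal_approximation():
    x = [1.0, 2.0, 2.0, 3.0]
    y = [2.0, 4.0, 5.0, 6.0]
    assert mann_whitney(x, y).extras["method"] == "normal_approx"


def test_mw_empty_sample_rejected():
    with pytest.raises(ValueError):
        mann_whitney([], [1.0])


# -------------------------------------------------------- Kruskal-Wallis


def test_kw_identical_groups_h_zero_p_one():
    res = kruskal_wallis([3.0, 3.0], [3.0, 3.0, 3.0])
    assert res.statistic == 0.0
    assert res.p_value == 1.0


def test_kw_two_groups_consistent_with_mw_z_squared(rng):
    """Tie-free two-group H equals the square of the MW normal z."""
    x = rng.normal(0, 1, 12)
    y = rng.normal(1, 1, 15)
    h = kruskal_wallis(x, y).statistic
    n1, n2 = len(x), len(y)
    u = mann_whitney(x, y).statistic
    mu = n1 * n2 / 2
    sigma = math.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    z = (u - mu) / sigma
    assert h == pytest.approx(z**2, rel=1e-9)


def test_kw_matches_brute_force_rank_computation(rng):
    groups = [rng.normal(i, 1, 7) for i in range(3)]
    pooled = np.concatenate(groups)
    # mid-ranks by explicit comparison counting
    ranks = np.array(
        [1 + (pooled < v).sum() + (pooled == v).sum() / 2 - 0.5 for v in pooled]
    )
    n = len(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += len(g) * (r.mean() - (n + 1) / 2) ** 2
        start += len(g)
    h *= 12.0 / (n * (n + 1))
    assert kruskal_wallis(*groups).statistic == pytest.approx(h, rel=1e-9)


# ----------------------------------------------------------- correlation


def test_correlation_perfect_linear():
    x = np.arange(10.0)
    res_r = correlation(x, 2 * x + 1, "pearson")
    res_rho = correlation(x, 2 * x + 1, "spearman")
    assert res_r.statistic == pytest.approx(1.0)
    assert res_rho.statistic == pytest.approx(1.0)


def test_correlation_monotone_decreasing_with_curvature():
    x = np.arange(1.0, 11.0)
    y = 1.0 / x
    assert correlation(x, y, "spearman").statistic == pytest.approx(-1.0)
    assert abs(correlation(x, y, "pearson").statistic) < 1.0


def test_pearson_matches_product_moment_formula(rng):
    x = rng.normal(size=20)
    y = 0.4 * x + rng.normal(size=20)
    r = correlation(x, y, "pearson").statistic
    expect = ((x - x.mean()) * (y - y.mean())).sum() / math.sqrt(
        ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
    )
    assert r == pytest.approx(expect, abs=1e-12)


def test_spearman_invariant_under_monotone_transform(rng):
    x = rng.uniform(1, 10, 25)
    y = rng.uniform(1, 10, 25)
    rho = correlation(x, y, "spearman").statistic
    rho_t = correlation(np.exp(x), y**3, "spearman").statistic
    assert rho_t == pytest.approx(rho, abs=1e-12)


def test_zero_variance_yields_nan_with_warning():
    with pytest.warns(UserWarning, match="zero variance"):
        res = correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    assert math.isnan(res.statistic)


# --------------------------------------------------------- Fisher exact


def fisher_enumeration_oracle(table, alternative):
    """Hypergeometric enumeration over all tables with fixed margins."""
    a, b = table[0]
    c, d = table[1]
    r1, r2, c1, n = a + b, c + d, a + c, a + b + c + d
    lo, hi = max(0, c1 - r2), min(r1, c1)

    def prob(k):
        return (
            math.comb(r1, k) * math.comb(r2, c1 - k) / math.comb(n, c1)
        )

    p_obs = prob(a)
    if alternative == "greater":
        return sum(prob(k) for k in range(a, hi + 1))
    if alternative == "less":
        return sum(prob(k) for k in range(lo, a + 1))
    return sum(prob(k) for k in range(lo, hi + 1) if prob(k) <= p_obs * (1 + 1e-9))


def test_fisher_no_association():
    res = fisher_exact(np.array([[5, 5], [5, 5]]))
    assert res.statistic == pytest.approx(1.0)
    assert res.p_value == pytest.approx(1.0)


def test_fisher_fatty_liver_table_matches_enumeration():
    """The diet-by-fatty-liver-evidence table [[20,4],[5,17]]."""
    table = np.array([[20, 4], [5, 17]])
    for alt in ("two-sided", "greater", "less"):
        res = fisher_exact(table, alt)
        assert res.p_value == pytest.approx(fisher_enumeration_oracle(table, alt), abs=1e-12)
    assert fisher_exact(table).statistic == pytest.approx(20 * 17 / (4 * 5))


def test_fisher_zero_cell_infinite_odds_ratio():
    table = np.array([[3, 0], [0, 3]])
    res = fisher_exact(table)
    assert math.isinf(res.statistic)
    assert res.p_value == pytest.approx(fisher_enumeration_oracle(table, "two-sided"), abs=1e-12)


def test_fisher_one_sided_tails_overlap(rng):
    """The two one-sided p-values sum to >= 1 (observed table in both)."""
    for _ in range(20):
        table = rng.integers(0, 12, size=(2, 2))
        p_hi = fisher_exact(table, "greater").p_value
        p_lo = fisher_exact(table, "less").p_value
        assert p_hi + p_lo >= 1.0 - 1e-12


def test_fisher_negative_counts_rejected():
    with pytest.raises(ValueError):
        ContingencyTable(np.array([[1, -2], [3, 4]]))


# -------------------------------------------------- proportions / ddCt


@pytest.mark.parametrize(
    "k,n,digits,expected",
    [(12, 24, 0, 50.0), (5, 22, 0, 23.0), (0, 7, 0, 0.0), (1, 3, 1, 33.3)],
)
def test_printed_proportions(k, n, digits, expected):
    assert proportion(k, n, digits) == expected


def test_proportion_rounds_half_up():
    assert proportion(1, 8, 0) == 13.0  # 12.5 -> 13 under half-up
    assert round_half_up(31.25, 1) == 31.3


def test_proportion_invalid_inputs():
    with pytest.raises(ValueError):
        proportion(1, 0)
    with pytest.raises(ValueError):
        proportion(5, 4)


@pytest.mark.parametrize(
    "cts,expected",
    [
        ((20, 20, 20, 20), 1.0),
        ((19, 20, 20, 20), 2.0),  # ddCt = -1
        ((25, 20, 22, 20), 0.125),  # ddCt = 3
    ],
)
def test_ddct_fold_change(cts, expected):
    assert ddct_fold_change(*cts) == pytest.approx(expected)


# ------------------------------------------------ response concordance


@pytest.mark.parametrize(
    "z1,z2,expected",
    [
        (3.0, 3.0, "concordant"),
        (-3.0, -4.0, "concordant"),
        (3.0, 0.0, "discordant"),
        (-3.0, 1.0, "discordant"),
        (1.0, 1.0, "neither"),
        (0.0, 3.0, "enhanced"),
        (3.0, -3.0, "neither"),  # both beyond cutoff, opposite signs
        (2.5, 2.5, "neither"),  # cutoff is strict
    ],
)
def test_classification_rule(z1, z2, expected):
    classified, _ = classify_response([("g", z1, z2)])
    assert classified[0].category == expected


def test_identical_contrasts_fully_concordant_or_neither():
    rng = np.random.default_rng(0)
    z = rng.normal(0, 2, 500)
    classified, corr_res = classify_response(list(zip(map(str, range(500)), z, z)))
    assert corr_res.statistic == pytest.approx(1.0)
    assert all(r.category in ("concordant", "neither") for r in classified)
    assert sum(r.category == "discordant" for r in classified) == 0


@settings(deadline=None, max_examples=50)
@given(
    hst.lists(
        hst.tuples(
            hst.floats(-10, 10, allow_nan=False), hst.floats(-10, 10, allow_nan=False)
        ),
        min_size=1,
        max_size=30,
    )
)
def test_classification_partitions_exhaustively(pairs):
    records = [(str(i), z1, z2) for i, (z1, z2) in enumerate(pairs)]
    if len(records) < 3:
        records = records + [("pad1", 0.1, 0.1), ("pad2", 0.2, 0.3), ("pad3", 0.0, 0.0)]
    classified, _ = classify_response(records)
    cats = {"concordant", "discordant", "enhanced", "neither"}
    assert all(r.category in cats for r in classified)
    assert len(classified) == len(records)


def test_planted_discordant_genes_recovered_exactly(rng):
    """50 planted discordant genes (|z1|=4, z2=0) among 5000 concordant-by-
    construction nulls are recovered exactly, with no false hits."""
    n_null = 5000
    z1 = rng.normal(0, 2, n_null)
    records = [(f"null{i}", z1[i], z1[i]) for i in range(n_null)]
    planted = [(f"planted{i}", 4.0 if i % 2 else -4.0, 0.0) for i in range(50)]
    classified, _ = classify_response(records + planted)
    discordant = {r.gene for r in classified if r.category == "discordant"}
    assert discordant == {name for name, _, _ in planted}


def test_benjamini_hochberg_monotone_and_bounded(rng):
    p = rng.uniform(size=40)
    adj = benjamini_hochberg(p)
    assert np.all(adj >= p - 1e-12)
    assert np.all(adj <= 1.0)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-12)
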