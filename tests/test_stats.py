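import itertools
import math

import numpy as np
import pytest
from scipy import optimize, stats as sps

from mtlnova.stats import (
    binary_logistic,
    chi_square_independence,
    kruskal_wallis,
    linear_score_model,
    mann_whitney,
    median_iqr,
    median_split_logistic,
    odds_ratio_2x2,
    proportional_odds,
)


# ---------------------------------------------------------------- 2x2 Woolf

def test_woolf_reproduces_published_any_red_contrast():
    """UPF 795/1650 vs MPF 166/986 with at least one red light."""
    res = odds_ratio_2x2(795, 855, 166, 820)
    assert res.estimate == pytest.approx(4.59, abs=0.005)
    assert res.ci_low == pytest.approx(3.79, abs=0.005)
    assert res.ci_high == pytest.approx(5.57, abs=0.005)
    assert res.method == "woolf_2x2" and not res.corrected


def test_woolf_unit_table_symmetric():
    res = odds_ratio_2x2(1, 1, 1, 1)
    assert res.estimate == 1.0
    assert math.log(res.ci_high) == pytest.approx(-math.log(res.ci_low))


def test_zero_cell_haldane_anscombe():
    res = odds_ratio_2x2(0, 10, 5, 5)
    assert res.corrected
    a, b, c, d = 0.5, 10.5, 5.5, 5.5
    assert res.estimate == pytest.approx((a * d) / (b * c))
    assert res.log_se == pytest.approx(
        math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    )


def test_zero_margin_rejected():
    with pytest.raises(ValueError, match="margin"):
        odds_ratio_2x2(0, 0, 5, 5)


def test_woolf_ci_widens_as_cells_shrink():
    widths = []
    for a in (200, 50, 10, 2):
        r = odds_ratio_2x2(a, 100, 100, 100)
        widths.append(math.log(r.ci_high) - math.log(r.ci_low))
    assert widths == sorted(widths)


# ------------------------------------------------------- binary logistic

def _expand(counts):
    """counts: {group: (n_event, n_nonevent)} -> (group, outcome) arrays."""
    groups, outcome = [], []
    for g, (a, b) in counts.items():
        groups += [g] * (a + b)
        outcome += [1] * a + [0] * b
    return np.array(groups), np.array(outcome, dtype=float)


def test_logistic_equals_woolf_on_saturated_two_group_design():
    group, outcome = _expand({"exp": (30, 70), "ref": (12, 88)})
    (fit,) = binary_logistic(group, outcome, reference="ref")
    oracle = odds_ratio_2x2(30, 70, 12, 88)
    assert fit.estimate == pytest.approx(oracle.estimate, rel=1e-6)
    assert fit.log_se == pytest.approx(oracle.log_se, rel=1e-6)
    assert fit.ci_low == pytest.approx(oracle.ci_low, rel=1e-6)


def test_logistic_identical_event_rates_gives_unit_or():
    group, outcome = _expand({"a": (20, 80), "b": (10, 40), "ref": (30, 120)})
    for fit in binary_logistic(group, outcome, reference="ref"):
        assert fit.estimate == pytest.approx(1.0, abs=1e-8)


def test_logistic_four_group_published_counts():
    """Saturated four-group fit reproduces the published any-red ORs."""
    group, outcome = _expand({
        "UPF": (795, 855), "PF": (121, 162), "PCI": (52, 9),
        "MPF": (166, 820),
    })
    fits = {f.contrast.split(" ")[0]: f
            for f in binary_logistic(group, outcome, reference="MPF")}
    assert fits["UPF"].estimate == pytest.approx(4.59, abs=0.005)
    assert fits["PF"].estimate == pytest.approx(3.69, abs=0.005)
    assert fits["PCI"].estimate == pytest.approx(28.54, abs=0.01)
    assert fits["PCI"].ci_low == pytest.approx(13.80, abs=0.01)
    assert fits["PCI"].ci_high == pytest.approx(59.05, abs=0.01)


def test_logistic_separation_falls_back_to_corrected_2x2():
    group, outcome = _expand({"sep": (15, 0), "ok": (10, 10),
                              "ref": (5, 15)})
    fits = {f.contrast.split(" ")[0]: f
            for f in binary_logistic(group, outcome, reference="ref")}
    assert fits["sep"].corrected and fits["sep"].method == "woolf_2x2"
    assert not fits["ok"].corrected
    oracle = odds_ratio_2x2(15, 0, 5, 15)
    assert fits["sep"].estimate == pytest.approx(oracle.estimate)


def test_logistic_constant_outcome_rejected():
    group, outcome = _expand({"a": (5, 0), "ref": (5, 0)})
    with pytest.raises(ValueError, match="constant"):
        binary_logistic(group, outcome, reference="ref")


# ---------------------------------------------------- proportional odds

def _ordinal_toy():
    group = np.array(["A"] * 15 + ["B"] * 15)
    outcome = np.array([0] * 6 + [1] * 5 + [2] * 4
                       + [0] * 3 + [1] * 5 + [2] * 7)
    return group, outcome


def _cumulative_logit_mle(group, outcome, exposed):
    """Independent maximization of the cumulative-logit likelihood."""
    x = (group == exposed).astype(float)
    levels = np.unique(outcome)
    k = len(levels)
    y = np.searchsorted(levels, outcome)

    def nll(params):
        # thresholds via first value + positive gaps; last param is beta
        alphas = np.cumsum([params[0], *np.exp(params[1:k - 1])])
        beta = params[-1]
        eta = np.subtract.outer(alphas, beta * x)  # (k-1, n)
        cdf = 1 / (1 + np.exp(-eta))
        upper = np.vstack([cdf, np.ones_like(x)])
        lower = np.vstack([np.zeros_like(x), cdf])
        probs = (upper - lower)[y, np.arange(len(x))]
        return -np.sum(np.log(np.clip(probs, 1e-300, None)))

    start = np.zeros(k)
    res = optimize.minimize(nll, start, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12,
                                     "maxiter": 20000, "maxfev": 20000})
    assert res.success
    return math.exp(res.x[-1])


def test_proportional_odds_matches_independent_mle():
    group, outcome = _ordinal_toy()
    (fit,) = proportional_odds(group, outcome, reference="A")
    oracle = _cumulative_logit_mle(group, outcome, exposed="B")
    assert fit.estimate == pytest.approx(oracle, abs=1e-4)


def test_proportional_odds_identical_distributions_unit_or():
    group = np.array(["A"] * 12 + ["B"] * 12)
    outcome = np.array([0, 0, 1, 1, 1, 2, 0, 0, 1, 1, 2, 2] * 2)
    (fit,) = proportional_odds(group, outcome, reference="A")
    assert fit.estimate == pytest.approx(1.0, abs=1e-4)


def test_proportional_odds_two_levels_reduces_to_binary_logistic():
    group, outcome = _expand({"exp": (30, 70), "ref": (12, 88)})
    (po,) = proportional_odds(group, outcome.astype(int), reference="ref")
    (bl,) = binary_logistic(group, outcome, reference="ref")
    assert po.estimate == pytest.approx(bl.estimate, abs=1e-4)
    assert po.log_se == pytest.approx(bl.log_se, abs=1e-4)


def test_proportional_odds_direction_flip_inverts_or():
    group, outcome = _ordinal_toy()
    (up,) = proportional_odds(group, outcome, reference="A")
    (down,) = proportional_odds(group, outcome, reference="A",
                                direction="lower_is_event")
    assert up.estimate == pytest.approx(1 / down.estimate, rel=1e-9)


# -------------------------------------------------------- rank tests

def test_kruskal_hand_rank_formula():
    """No ties: H = 12/(N(N+1)) * sum R_g^2/n_g - 3(N+1) = 7.2 for the
    rank-separated triples {1,2,3},{4,5,6},{7,8,9}."""
    res = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
    assert res.statistic == pytest.approx(7.2)
    assert res.df == 2
    assert res.p_value == pytest.approx(1 - sps.chi2.cdf(7.2, 2))


def test_kruskal_all_identical_guarded():
    res = kruskal_wallis([[5, 5, 5], [5, 5]])
    assert res.statistic == 0.0 and res.p_value == 1.0
    assert all(p == 1.0 for _, _, p in res.pairwise)


def test_kruskal_two_groups_matches_squared_rank_z():
    rng = np.random.default_rng(7)
    x = rng.normal(size=12)
    y = rng.normal(0.8, size=9)
    res = kruskal_wallis([x, y])
    m, n = len(x), len(y)
    u = sps.mannwhitneyu(x, y, alternative="two-sided").statistic
    z = (u - m * n / 2) / math.sqrt(m * n * (m + n + 1) / 12)
    assert res.statistic == pytest.approx(z**2, rel=1e-9)


def test_dunn_pairwise_bonferroni_properties():
    rng = np.random.default_rng(3)
    groups = [rng.normal(loc, size=20) for loc in (0, 0.1, 2.0)]
    res = kruskal_wallis(groups, labels=["a", "b", "c"])
    assert len(res.pairwise) == 3
    assert all(0 <= p <= 1 for _, _, p in res.pairwise)
    pmap = {(a, b): p for a, b, p in res.pairwise}
    # the well-separated pair is far smaller than the null pair
    assert pmap[("a", "c")] < 0.01 < pmap[("a", "b")]


def _mann_whitney_exact_p(x, y):
    """Exhaustive permutation distribution of U (tie-aware)."""
    pooled = np.concatenate([x, y])
    m = len(x)
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:m].sum() - m * (m + 1) / 2
    centre = m * len(y) / 2
    dev = abs(u_obs - centre)
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), m):
        u = ranks[list(idx)].sum() - m * (m + 1) / 2
        hits += abs(u - centre) >= dev - 1e-12
        total += 1
    return hits / total


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_mann_whitney_close_to_exact_enumeration(seed):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 10, size=7).astype(float)
    y = (rng.integers(0, 10, size=8) + 2).astype(float)
    _, p = mann_whitney(x, y)
    assert p == pytest.approx(_mann_whitney_exact_p(x, y), abs=0.01)


def test_mann_whitney_identical_samples():
    x = [1.0, 2.0, 3.0, 4.0]
    _, p = mann_whitney(x, x)
    assert p > 0.95


def test_mann_whitney_disjoint_ranges():
    u, p = mann_whitney(np.arange(20) + 100.0, np.arange(20.0))
    assert p < 0.001


# ------------------------------------------------------------ chi-square

def test_chi_square_proportional_rows_null():
    res = chi_square_independence([[10, 20, 30], [20, 40, 60]])
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)


def test_chi_square_hand_formula_2x2():
    res = chi_square_independence([[10, 20], [20, 10]])
    # all expected counts are 15: sum (O-E)^2/E = 4 * 25/15
    assert res.statistic == pytest.approx(100 / 15)
    assert res.df == 1


def test_chi_square_zero_margin_named():
    with pytest.raises(ValueError, match="column 1"):
        chi_square_independence([[10, 0], [20, 0]])


# ---------------------------------------------------------- descriptives

def test_median_iqr_weighted_average_convention():
    assert median_iqr([1, 2, 3, 4, 5]) == pytest.approx((3.0, 1.5, 4.5))
    assert median_iqr([7.0]) == (7.0, 7.0, 7.0)
    assert median_iqr([2.0, 2.0, 2.0]) == (2.0, 2.0, 2.0)


# --------------------------------------------------------- median split

def test_median_split_constant_values_rejected():
    group = np.array(["a"] * 5 + ["b"] * 5)
    with pytest.raises(ValueError, match="median"):
        median_split_logistic(group, np.ones(10), reference="a")


def test_median_split_separated_group_flagged():
    group = np.array(["hi"] * 10 + ["ref"] * 10)
    values = np.concatenate([np.arange(10) + 100.0, np.arange(10.0)])
    (fit,) = median_split_logistic(group, values, reference="ref")
    assert fit.corrected and fit.estimate > 1


def test_median_split_recovers_shift_direction():
    """Lognormal groups with a known upward shift give OR > 1 in at least
    95 % of seeded replicates."""
    rng = np.random.default_rng(11)
    agree = 0
    reps = 200
    for _ in range(reps):
        base = rng.lognormal(0.0, 0.8, size=60)
        shifted = rng.lognormal(0.5, 0.8, size=60)
        group = np.array(["ref"] * 60 + ["up"] * 60)
        (fit,) = median_split_logistic(
            group, np.concatenate([base, shifted]), reference="ref"
        )
        agree += fit.estimate > 1
    assert agree / reps >= 0.95


# ------------------------------------------------------------------ OLS

def test_linear_model_equal_means_zero_coefficient():
    group = np.array(["a"] * 4 + ["b"] * 4)
    score = np.array([1, 2, 3, 4, 4, 3, 2, 1], dtype=float)
    (fit,) = linear_score_model(group, score, reference="a")
    assert fit.estimate == pytest.approx(0.0, abs=1e-12)


def test_linear_model_coefficients_equal_mean_differences():
    rng = np.random.default_rng(5)
    group = np.repeat(["a", "b", "c"], 30)
    score = rng.normal(size=90) + np.repeat([0.0, 1.0, -0.5], 30)
    fits = {f.contrast.split(" ")[0]: f
            for f in linear_score_model(group, score, reference="a")}
    ref_mean = score[:30].mean()
    assert fits["b"].estimate == pytest.approx(score[30:60].mean() - ref_mean)
    assert fits["c"].estimate == pytest.approx(score[60:].mean() - ref_mean)
    assert fits["b"].ci_low < fits["b"].estimate < fits["b"].ci_high


def test_linear_model_tiny_group_dropped_with_warning():
    group = np.array(["a"] * 5 + ["b"] * 5 + ["tiny"])
    score = np.arange(11, dtype=float)
    with pytest.warns(UserWarning, match="tiny"):
        fits = linear_score_model(group, score, reference="a")
    assert [f.contrast for f in fits] == ["b vs a"]
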