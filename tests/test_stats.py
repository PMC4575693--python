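"""Ordinal statistics against exhaustive-permutation oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from connectopred.stats import (
    bonferroni_adjust,
    cumulative_percentages,
    frequency_table,
    jonckheere_terpstra,
    kruskal_wallis,
    relative_frequencies,
    spearman,
    wilcoxon_rank_sum,
)

# ---------------------------------------------------------------------------
# independent oracles (deliberately re-derived from first principles)


def manual_ranks(values):
    """Average ranks computed by explicit sorting, no scipy."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def pearson(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


def spearman_oracle(x, y):
    """rho by the rank formula; exact two-tailed permutation p."""
    rx, ry = manual_ranks(x), manual_ranks(y)
    rho = pearson(rx, ry)
    count = total = 0
    for perm in itertools.permutations(ry):
        if abs(pearson(rx, list(perm))) >= abs(rho) - 1e-12:
            count += 1
        total += 1
    return rho, count / total


def rank_sum_oracle(g1, g2):
    """W of group1 plus the exact permutation p of the rank sum."""
    pooled = list(g1) + list(g2)
    ranks = manual_ranks(pooled)
    n1 = len(g1)
    w_obs = sum(ranks[:n1])
    mean_w = n1 * (len(pooled) + 1) / 2
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        w = sum(ranks[i] for i in idx)
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12:
            count += 1
        total += 1
    return w_obs, count / total


def kruskal_oracle(groups):
    """H by the explicit rank formula with tie correction."""
    pooled = [v for g in groups for v in g]
    n = len(pooled)
    ranks = manual_ranks(pooled)
    h = 0.0
    start = 0
    for g in groups:
        rsum = sum(ranks[start : start + len(g)])
        h += rsum**2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    ties = {}
    for v in pooled:
        ties[v] = ties.get(v, 0) + 1
    correction = 1 - sum(t**3 - t for t in ties.values()) / (n**3 - n)
    return h / correction if correction > 0 else 0.0


def jt_oracle(groups):
    """Raw JT count plus the exact permutation p (two-tailed around the mean)."""

    def raw(gs):
        total = 0.0
        for i in range(len(gs)):
            for j in range(i + 1, len(gs)):
                for u in gs[i]:
                    for v in gs[j]:
                        total += 1.0 if u < v else (0.5 if u == v else 0.0)
        return total

    jt_obs = raw(groups)
    sizes = [len(g) for g in groups]
    pooled = [v for g in groups for v in g]
    n = len(pooled)
    mean = (n**2 - sum(s**2 for s in sizes)) / 4
    count = total = 0
    for perm in itertools.permutations(pooled):
        gs, start = [], 0
        for s in sizes:
            gs.append(perm[start : start + s])
            start += s
        if abs(raw(gs) - mean) >= abs(jt_obs - mean) - 1e-12:
            count += 1
        total += 1
    return jt_obs, count / total


# ---------------------------------------------------------------------------
# frequency tables


def _frame(present, absent, unknown):
    """Build an analysis-like frame from per-value counts."""
    rows = []
    for counts, status in ((present, "present"), (absent, "absent"), (unknown, "unknown")):
        for value, k in counts.items():
            rows.extend({"v": value, "status": status} for _ in range(k))
    return pd.DataFrame(rows)


class TestFrequencyTables:
    def test_cumulative_percentages(self):
        df = _frame({1: 10, 2: 5, 3: 5}, {1: 2}, {})
        ft = cumulative_percentages(df, "v")
        assert list(ft["cum_pct"]) == [50.0, 75.0, 100.0]

    def test_single_value_class(self):
        ft = cumulative_percentages(_frame({2: 7}, {}, {}), "v")
        assert list(ft["cum_pct"]) == [100.0]

    def test_relative_frequency_excludes_unknown(self):
        df = _frame({1: 3}, {1: 1}, {1: 2})
        ft = relative_frequencies(df, "v")
        assert ft.iloc[0]["rel_freq"] == 0.75
        assert ft.iloc[0]["n_examined"] == 4

    def test_all_examined_present(self):
        ft = relative_frequencies(_frame({1: 4}, {}, {}), "v")
        assert ft.iloc[0]["rel_freq"] == 1.0

    def test_zero_present_raises(self):
        with pytest.raises(ValueError, match="percentages undefined"):
            frequency_table(_frame({}, {1: 3}, {}), "v")

    def test_unknown_only_class_omitted_with_warning(self):
        df = _frame({1: 2}, {}, {2: 5})
        with pytest.warns(UserWarning, match="no examined"):
            ft = frequency_table(df, "v")
        assert list(ft["value"]) == [1]

    def test_cum_pct_monotone_ends_at_100(self, bundle):
        from connectopred.variables import analysis_frame, pair_variables

        fr = analysis_frame(bundle.table, pair_variables(bundle.parcellation))
        ft = frequency_table(fr, "delta_dist")
        assert (ft["cum_pct"].diff().dropna() >= 0).all()
        assert ft["cum_pct"].iloc[-1] == pytest.approx(100.0)


# ---------------------------------------------------------------------------
# rank tests


class TestSpearman:
    def test_perfect_anticorrelation(self):
        res = spearman([1, 2, 3, 4], [8, 6, 4, 2])
        assert res.statistic == pytest.approx(-1.0)

    def test_self_correlation_and_negation(self):
        x = [3, 1, 4, 1, 5, 9]
        assert spearman(x, x).statistic == pytest.approx(1.0)
        assert spearman(x, [-v for v in x]).statistic == pytest.approx(-1.0)

    def test_monotone_transform_invariance(self):
        x = [1, 2, 3, 4, 5, 6]
        y = [2, 1, 5, 3, 4, 6]
        base = spearman(x, y).statistic
        assert spearman([v**3 for v in x], y).statistic == pytest.approx(base)
        assert spearman(x, [math.exp(v) for v in y]).statistic == pytest.approx(base)

    @pytest.mark.parametrize(
        "x,y",
        [
            ([1, 2, 3, 4], [2, 2, 1, 1]),
            ([1, 2, 3, 4, 5], [3, 1, 4, 1, 5]),
            ([1, 1, 2, 3], [4, 2, 2, 1]),
        ],
    )
    def test_matches_exact_oracle(self, x, y):
        rho, p = spearman_oracle(x, y)
        res = spearman(x, y)
        assert res.statistic == pytest.approx(rho)
        assert res.p_value == pytest.approx(p)
        assert res.method == "spearman[exact-permutation]"

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            spearman([1, 1, 1], [1, 2, 3])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 8), st.integers(0, 8)), min_size=3, max_size=10))
    def test_invariance_under_strictly_monotone_maps(self, pairs):
        x = [float(a) for a, _ in pairs]
        y = [float(b) for _, b in pairs]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        rho = spearman(x, y).statistic
        assert spearman([3 * v + 2 for v in x], y).statistic == pytest.approx(rho)
        assert spearman(x, [v**3 + v for v in y]).statistic == pytest.approx(rho)
        assert spearman([-v for v in x], y).statistic == pytest.approx(-rho)


class TestWilcoxonRankSum:
    def test_identical_groups_z_near_zero(self):
        res = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert abs(res.z) < 1e-12
        assert res.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "g1,g2",
        [
            ([1, 5, 9], [2, 3, 4]),
            ([1, 2], [3, 4, 5, 6]),
            ([2, 2, 3], [1, 4, 4]),  # with ties
        ],
    )
    def test_matches_exact_oracle(self, g1, g2):
        w, p_exact = rank_sum_oracle(g1, g2)
        res = wilcoxon_rank_sum(g1, g2)
        assert res.statistic == pytest.approx(w)
        assert res.p_value == pytest.approx(p_exact)
        # z from the tie-corrected normal approximation carries the sign
        assert (res.z <= 0) == (w <= len(g1) * (len(g1) + len(g2) + 1) / 2)

    def test_all_identical_values_warns(self):
        with pytest.warns(UserWarning):
            res = wilcoxon_rank_sum([2, 2], [2, 2, 2])
        assert res.p_value == 1.0


class TestKruskalWallis:
    def test_identical_groups_h_zero(self):
        res = kruskal_wallis([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert res.statistic == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize(
        "groups",
        [
            [[1, 3], [2, 5], [4, 6]],
            [[1, 1, 2], [3, 4], [2, 5, 6]],
            [[7], [1, 2], [3, 3, 3]],
        ],
    )
    def test_matches_rank_formula_oracle(self, groups):
        res = kruskal_wallis(groups)
        assert res.statistic == pytest.approx(kruskal_oracle(groups))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2], []])

    def test_bonferroni_divides_alpha(self):
        r = wilcoxon_rank_sum([1, 2, 3, 4], [5, 6, 7, 8])
        out = bonferroni_adjust([r] * 6, alpha=0.05)
        assert out[0]["alpha_corrected"] == pytest.approx(0.05 / 6)
        out2 = bonferroni_adjust([r], alpha=0.05, n_comparisons=60)
        assert out2[0]["alpha_corrected"] == pytest.approx(0.05 / 60)


class TestJonckheereTerpstra:
    def test_perfect_trend_is_maximal(self):
        res = jonckheere_terpstra([[1, 1], [2, 2], [3, 3]])
        assert res.statistic == 12  # every cross-group pair is concordant
        assert res.z > 0

    def test_reversed_trend_negative_z(self):
        res = jonckheere_terpstra([[3, 3], [2, 2], [1, 1]], alternative="decreasing")
        assert res.statistic == 0
        assert res.z < 0

    @pytest.mark.parametrize(
        "groups",
        [
            [[1, 2], [2, 3], [3, 4]],
            [[1, 5], [2, 2], [3]],
            [[2, 2], [2], [1, 3]],
        ],
    )
    def test_matches_exhaustive_oracle(self, groups):
        jt, p_exact = jt_oracle(groups)
        res = jonckheere_terpstra(groups)
        assert res.statistic == pytest.approx(jt)
        assert res.p_value == pytest.approx(p_exact)

    def test_sums_pairwise_mann_whitney_counts(self):
        """The raw JT is the sum of pairwise Mann-Whitney U counts."""
        rng = np.random.default_rng(3)
        groups = [rng.integers(0, 5, size=4) for _ in range(3)]
        res = jonckheere_terpstra(groups)
        u_sum = 0.0
        for i in range(3):
            for j in range(i + 1, 3):
                u_sum += sps.mannwhitneyu(groups[j], groups[i], alternative="two-sided").statistic
        assert res.statistic == pytest.approx(u_sum)

    def test_two_groups_rejected(self):
        with pytest.raises(ValueError, match="wilcoxon"):
            jonckheere_terpstra([[1, 2], [3, 4]])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        st.lists(st.lists(st.integers(0, 5), min_size=1, max_size=4), min_size=3, max_size=4)
    )
    def test_reversing_group_order_mirrors_statistic(self, groups):
        fwd = jonckheere_terpstra(groups)
        rev = jonckheere_terpstra(groups[::-1])
        sizes = [len(g) for g in groups]
        n = sum(sizes)
        n_cross_pairs = (n**2 - sum(s**2 for s in sizes)) / 2
        # concordant pairs in one order are discordant in the other; ties
        # contribute one half to each, so the two statistics sum to the
        # number of cross-group pairs
        assert fwd.statistic + rev.statistic == pytest.approx(n_cross_pairs)
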