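"""Ordinal statistics for existence and topology analyses.

All variables here are ordinal (border distance, structural type and its
differences, hierarchy levels, projection densities, direction codes), so
the toolbox is rank-based throughout: Spearman's rho, the Wilcoxon rank-sum
test (W with a standardized z), the Kruskal-Wallis H test with Bonferroni
post hocs, and the Jonckheere-Terpstra trend test for ordered group
alternatives.  Ties take average ranks everywhere; W and H use the
tie-corrected variance; JT uses the half-tie counting convention with the
no-tie variance (documented limitation).  Significance is two-tailed at
alpha = 0.05 unless stated otherwise.

P-values for very short inputs (total n <= 8, e.g. the per-value
relative-frequency profiles with 5 or 6 entries) come from exact
permutation enumeration for all four tests, because the t / normal /
chi-square approximations are invalid there; larger samples use the
usual asymptotics.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RankTestResult",
    "frequency_table",
    "cumulative_percentages",
    "relative_frequencies",
    "spearman",
    "wilcoxon_rank_sum",
    "kruskal_wallis",
    "bonferroni_adjust",
    "jonckheere_terpstra",
]


@dataclass
class RankTestResult:
    """Outcome of a rank test: statistic, standardized z, p, sample sizes."""

    statistic: float
    p_value: float
    n: tuple[int, ...]
    method: str
    z: float | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "statistic": float(self.statistic),
            "z": None if self.z is None else float(self.z),
            "p_value": float(self.p_value),
            "n": list(self.n),
            **{k: v for k, v in self.extra.items()},
        }


# ---------------------------------------------------------------------------
# frequency tables


def frequency_table(df: pd.DataFrame, variable: str) -> pd.DataFrame:
    """Per-value presence counts for one anatomical variable.

    ``df`` must carry ``status`` in {present, absent, unknown} and the
    variable column.  Unknown pairs are excluded entirely (no assumption
    is made about unexamined projections).  Value classes with zero
    examined projections are omitted with a warning.

    Returns a frame with columns value, n_present, n_absent, n_examined,
    rel_freq, cum_pct; rel_freq = n_present / n_examined within the value
    class, cum_pct = cumulative percentage of all present projections
    found up to that value.
    """
    sub = df[(df["status"] != "unknown") & df[variable].notna()]
    values = sorted(df.loc[df[variable].notna(), variable].unique())
    rows = []
    for v in values:
        cls = sub[sub[variable] == v]
        n_p = int((cls["status"] == "present").sum())
        n_a = int((cls["status"] == "absent").sum())
        if n_p + n_a == 0:
            warnings.warn(f"value class {variable}={v} has no examined projections; omitted")
            continue
        rows.append((v, n_p, n_a, n_p + n_a))
    out = pd.DataFrame(rows, columns=["value", "n_present", "n_absent", "n_examined"])
    total_present = out["n_present"].sum()
    if total_present == 0:
        raise ValueError(f"no present projections with {variable} defined; percentages undefined")
    out["rel_freq"] = out["n_present"] / out["n_examined"]
    out["cum_pct"] = 100.0 * out["n_present"].cumsum() / total_present
    return out


def cumulative_percentages(df: pd.DataFrame, variable: str) -> pd.DataFrame:
    """Cumulative percentage of present projections up to each value."""
    return frequency_table(df, variable)[["value", "n_present", "cum_pct"]]


def relative_frequencies(df: pd.DataFrame, variable: str) -> pd.DataFrame:
    """Fraction of examined pairs found connected, per variable value."""
    return frequency_table(df, variable)[
        ["value", "n_present", "n_absent", "n_examined", "rel_freq"]
    ]


# ---------------------------------------------------------------------------
# rank tests


def _check_vector(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"{name} must be 1-D")
    return x


def spearman(x, y, exact_max_n: int = 8) -> RankTestResult:
    """Spearman rank correlation with tie handling by average ranks.

    Two-tailed p-value: exact permutation enumeration when n <= 8 (the t
    approximation is unreliable for the short frequency profiles this
    package correlates), t approximation otherwise.
    """
    x = _check_vector(x, "x")
    y = _check_vector(y, "y")
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("spearman requires n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("spearman undefined for zero-variance input")
    rho = float(sps.spearmanr(x, y).statistic)
    if n <= exact_max_n:
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = np.corrcoef(rx, perm)[0, 1]
            if abs(r) >= obs - 1e-12:
                count += 1
            total += 1
        p = count / total
        method = "spearman[exact-permutation]"
    else:
        p = float(sps.spearmanr(x, y).pvalue)
        method = "spearman[t-approx]"
    return RankTestResult(statistic=rho, p_value=p, n=(n,), method=method)


def wilcoxon_rank_sum(group1, group2, exact_max_n: int = 8) -> RankTestResult:
    """Wilcoxon rank-sum test for equality of two medians.

    The statistic W is the rank sum of ``group1`` in the pooled ranking
    (average ranks for ties); z uses the normal approximation with the
    tie-corrected variance and no continuity correction.  The two-tailed
    p-value comes from exhaustive label enumeration when the pooled
    sample has at most ``exact_max_n`` observations, from the normal
    approximation otherwise.
    """
    g1 = _check_vector(group1, "group1")
    g2 = _check_vector(group2, "group2")
    if len(g1) == 0 or len(g2) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([g1, g2])
    n1, n2 = len(g1), len(g2)
    n = n1 + n2
    ranks = sps.rankdata(pooled)
    w = float(ranks[:n1].sum())
    mean_w = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))) if n > 1 else 0.0
    var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_w <= 0:
        warnings.warn("all values identical across both groups; p = 1")
        return RankTestResult(statistic=w, z=0.0, p_value=1.0, n=(n1, n2), method="wilcoxon_rank_sum")
    z = (w - mean_w) / math.sqrt(var_w)
    if n <= exact_max_n:
        count = total = 0
        for idx in itertools.combinations(range(n), n1):
            w_perm = float(ranks[list(idx)].sum())
            if abs(w_perm - mean_w) >= abs(w - mean_w) - 1e-12:
                count += 1
            total += 1
        p = count / total
        method = "wilcoxon_rank_sum[exact-permutation]"
    else:
        p = 2.0 * sps.norm.sf(abs(z))
        method = "wilcoxon_rank_sum"
    return RankTestResult(statistic=w, z=float(z), p_value=float(p), n=(n1, n2), method=method)


def kruskal_wallis(groups, exact_max_n: int = 8) -> RankTestResult:
    """Kruskal-Wallis H test (tie-corrected).

    The p-value is upper-tail: exhaustive permutation enumeration for
    pooled samples of at most ``exact_max_n`` observations, chi-square
    with k-1 df otherwise.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("kruskal_wallis requires >= 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("kruskal_wallis requires non-empty groups")
    sizes = tuple(len(g) for g in groups)
    if np.ptp(np.concatenate(groups)) == 0:
        # identical data in every group: H is defined and equals 0
        return RankTestResult(statistic=0.0, p_value=1.0, n=sizes, method="kruskal_wallis")
    h, p = sps.kruskal(*groups)
    n = sum(sizes)
    method = "kruskal_wallis"
    if n <= exact_max_n:
        # permuting the data is equivalent to permuting the pooled ranks,
        # and the tie correction is permutation-invariant, so H can be
        # recomputed from group rank sums alone
        ranks = sps.rankdata(np.concatenate(groups))
        _, tie_counts = np.unique(np.concatenate(groups), return_counts=True)
        correction = 1.0 - float((tie_counts**3 - tie_counts).sum()) / (n**3 - n)
        count = total = 0
        for perm in itertools.permutations(ranks):
            h_perm, start = 0.0, 0
            for s in sizes:
                h_perm += sum(perm[start : start + s]) ** 2 / s
                start += s
            h_perm = (12.0 / (n * (n + 1)) * h_perm - 3 * (n + 1)) / correction
            if h_perm >= h - 1e-12:
                count += 1
            total += 1
        p = count / total
        method = "kruskal_wallis[exact-permutation]"
    return RankTestResult(statistic=float(h), p_value=float(p), n=sizes, method=method)


def bonferroni_adjust(
    results: list[RankTestResult],
    alpha: float = 0.05,
    n_comparisons: int | None = None,
) -> list[dict]:
    """Bonferroni decisions for post hoc pairwise tests.

    ``alpha`` is divided by ``n_comparisons`` (defaults to the number of
    results).  The correction denominator is an explicit parameter
    because conventions differ on whether it counts the pairwise
    comparisons alone or a larger test family.
    """
    m = n_comparisons if n_comparisons is not None else len(results)
    if m < 1:
        raise ValueError("n_comparisons must be >= 1")
    alpha_corr = alpha / m
    return [
        {"result": r, "alpha_corrected": alpha_corr, "significant": bool(r.p_value < alpha_corr)}
        for r in results
    ]


def jonckheere_terpstra(
    groups, alternative: str = "increasing", exact_max_n: int = 8
) -> RankTestResult:
    """Jonckheere-Terpstra test for a monotone trend across ordered groups.

    The raw statistic is the sum over ordered group pairs (i < j) of the
    Mann-Whitney counts #{u < v} + 0.5 * #{u == v} for u in group i, v in
    group j.  Reported alongside is the standardized z under the null
    mean (N^2 - sum n_i^2)/4 and the no-tie variance
    (N^2 (2N+3) - sum n_i^2 (2 n_i + 3)) / 72; p is two-tailed (exact
    permutation enumeration when the pooled sample has at most
    ``exact_max_n`` observations).  The sign of z follows the observed
    direction of trend in the given group order; ``alternative`` records
    the direction being tested.
    """
    if alternative not in ("increasing", "decreasing"):
        raise ValueError("alternative must be 'increasing' or 'decreasing'")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError(
            "jonckheere_terpstra requires >= 3 ordered groups; use wilcoxon_rank_sum for 2"
        )
    if any(len(g) == 0 for g in groups):
        raise ValueError("groups must be non-empty")
    jt = 0.0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            gi = groups[i][:, None]
            gj = groups[j][None, :]
            jt += float((gi < gj).sum()) + 0.5 * float((gi == gj).sum())
    ns = np.array([len(g) for g in groups], dtype=float)
    n = ns.sum()
    mean_jt = (n**2 - (ns**2).sum()) / 4.0
    var_jt = (n**2 * (2 * n + 3) - (ns**2 * (2 * ns + 3)).sum()) / 72.0
    z = (jt - mean_jt) / math.sqrt(var_jt)
    if n <= exact_max_n:
        pooled = np.concatenate(groups)
        sizes = [len(g) for g in groups]

        def _raw(gs) -> float:
            total = 0.0
            for i in range(len(gs)):
                for j in range(i + 1, len(gs)):
                    gi = np.asarray(gs[i])[:, None]
                    gj = np.asarray(gs[j])[None, :]
                    total += float((gi < gj).sum()) + 0.5 * float((gi == gj).sum())
            return total

        count = total = 0
        for perm in itertools.permutations(pooled):
            gs, start = [], 0
            for s in sizes:
                gs.append(perm[start : start + s])
                start += s
            if abs(_raw(gs) - mean_jt) >= abs(jt - mean_jt) - 1e-12:
                count += 1
            total += 1
        p = count / total
        method_suffix = ",exact-permutation"
    else:
        p = 2.0 * sps.norm.sf(abs(z))
        method_suffix = ""
    return RankTestResult(
        statistic=jt,
        z=float(z),
        p_value=float(p),
        n=tuple(int(x) for x in ns),
        method=f"jonckheere_terpstra[{alternative}{method_suffix}]",
    )
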