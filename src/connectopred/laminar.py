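"""Laminar projection directions versus type and level differences.

Tract-tracing studies classify a projection's laminar origin/termination
pattern as ascending (toward a putatively higher station: supragranular
or bilaminar origin, layer-IV termination), lateral (columnar), or
descending (infragranular-weighted origin, termination avoiding layer
IV).  Coded ordinally as ascending=1, lateral=2, descending=3, the code
correlates positively with the hierarchy level difference (descending
projections run down the hierarchy) and negatively with the structural
type difference.  Reversing the coding exactly negates every rho.

Directions marked unreliable (insufficient or contradictory data) are
included by default and can be excluded by flag; exclusion changes n but
should not flip any sign.
"""

from __future__ import annotations

import logging

import pandas as pd

from .stats import RankTestResult, spearman

__all__ = ["DIRECTION_CODES", "direction_correlations"]

logger = logging.getLogger(__name__)

DIRECTION_CODES = {"A": 1, "ascending": 1, "L": 2, "lateral": 2, "D": 3, "descending": 3}


def direction_correlations(
    projections: pd.DataFrame,
    variables: pd.DataFrame,
    include_unreliable: bool = True,
) -> dict[str, RankTestResult]:
    """Spearman of direction code against delta_type and delta_level.

    ``projections`` columns: source, target, direction (A/L/D or full
    words), reliable (0/1).  ``variables`` is the pair-variables table.
    Projections lacking the respective variable are skipped per-analysis,
    with counts logged.
    """
    df = projections.copy()
    df["direction_code"] = df["direction"].map(DIRECTION_CODES)
    if df["direction_code"].isna().any():
        bad = df.loc[df["direction_code"].isna(), "direction"].unique()
        raise ValueError(f"unknown direction labels: {sorted(map(str, bad))}")
    if not include_unreliable and "reliable" in df:
        df = df[df["reliable"].astype(bool)]
    merged = df.merge(variables, on=["source", "target"], how="left")
    out: dict[str, RankTestResult] = {}
    for var in ("delta_type", "delta_level"):
        sub = merged[merged[var].notna()]
        skipped = len(merged) - len(sub)
        if skipped:
            logger.info("direction vs %s: %d projections without %s skipped", var, skipped, var)
        if len(sub) < 3:
            logger.info("direction vs %s: only %d projections with %s; skipped", var, len(sub), var)
            continue
        out[var] = spearman(
            sub["direction_code"].to_numpy(dtype=float), sub[var].to_numpy(dtype=float)
        )
    if not out:
        raise ValueError("no variable has >= 3 projections with defined values")
    return out
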