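"""Pairwise anatomical variables over a parcellation.

Three variables are attached to every ordered pair of distinct areas:

* ``delta_dist`` — border distance: the minimum number of area borders
  separating the two areas, i.e. the unweighted shortest-path length in
  the symmetric border-adjacency graph.  A pragmatic stand-in for
  physical separation when reliable 3-D coordinates are unavailable.
* ``delta_type`` — structural (cytoarchitectonic) type difference,
  ``type(source) - type(target)``; antisymmetric in the pair.
* ``delta_level`` — hierarchy level difference in a named processing
  hierarchy, ``level(source) - level(target)``; antisymmetric.

Because connection existence and border distance are undirected while the
two difference variables are directed, analyses of existence use the
absolute values ``abs_type`` and ``abs_level``.

Pairs lacking a required attribute get a missing value and are excluded
per-analysis (not globally), so nested data subsets fall out naturally.
"""

from __future__ import annotations

import logging
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .data import Area, Parcellation, ProjectionTable, binarize

__all__ = [
    "border_distances",
    "type_difference",
    "level_difference",
    "pair_variables",
    "analysis_frame",
]

logger = logging.getLogger(__name__)


def border_distances(parcellation: Parcellation) -> pd.DataFrame:
    """All-pairs border distance (symmetric, zero diagonal).

    Computed by breadth-first search on the undirected adjacency graph.
    Pairs in different connected components get NaN, with a warning
    listing the components.
    """
    g = parcellation.adjacency
    names = parcellation.names
    dist = pd.DataFrame(np.nan, index=names, columns=names)
    for src, lengths in nx.all_pairs_shortest_path_length(g):
        for tgt, d in lengths.items():
            dist.loc[src, tgt] = d
    if dist.isna().to_numpy().any():
        comps = [sorted(c) for c in nx.connected_components(g)]
        logger.warning(
            "adjacency graph is disconnected; distances across components are "
            "missing. Components: %s",
            comps,
        )
    return dist


def type_difference(source: Area, target: Area) -> int | None:
    """Signed structural type difference type(source) - type(target)."""
    if source.structural_type is None or target.structural_type is None:
        return None
    return source.structural_type - target.structural_type


def level_difference(source: str, target: str, hierarchy: Mapping[str, int]) -> int | None:
    """Signed hierarchy level difference level(source) - level(target)."""
    if source not in hierarchy or target not in hierarchy:
        return None
    return hierarchy[source] - hierarchy[target]


def pair_variables(
    parcellation: Parcellation,
    hierarchy: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Long table of the anatomical variables for all ordered pairs.

    Columns: source, target, delta_dist, delta_type, abs_type,
    delta_level, abs_level.  Missing attributes yield NaN.
    """
    dist = border_distances(parcellation)
    types = parcellation.structural_types
    hierarchy = hierarchy or {}
    rows = []
    names = parcellation.names
    for s in names:
        for t in names:
            if s == t:
                continue
            d = dist.loc[s, t]
            dt = types[s] - types[t] if s in types and t in types else np.nan
            dl = hierarchy[s] - hierarchy[t] if s in hierarchy and t in hierarchy else np.nan
            rows.append((s, t, d, dt, abs(dt), dl, abs(dl)))
    df = pd.DataFrame(
        rows,
        columns=["source", "target", "delta_dist", "delta_type", "abs_type", "delta_level", "abs_level"],
    )
    return df


def analysis_frame(
    table: ProjectionTable,
    variables: pd.DataFrame,
) -> pd.DataFrame:
    """Join pair variables with binarized statuses.

    Adds a ``status`` column with values ``present`` / ``absent`` /
    ``unknown``; the existence analyses filter on it.
    """
    b = binarize(table)
    status = {(s, t): st.value for (s, t), st in b.records.items()}
    df = variables.copy()
    df["status"] = [
        status.get((s, t), "unknown") for s, t in zip(df["source"], df["target"])
    ]
    return df
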