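"""Seeded generator of synthetic parcellations and projection tables.

The generator emulates the statistical structure the analyses assume,
so every stage of the pipeline can run and be tested without any
external data:

* a connected, planar-like parcellation graph (square lattice or random
  geometric graph in the unit square), whose shortest-path structure
  plays the role of border distance;
* structural types 1..5 quantized by quintiles from a spatially smooth
  Gaussian random field, with a *short* correlation length so the
  cytoarchitectonic gradient repeats across the sheet and the resulting
  |type difference| stays approximately independent of distance;
* projection existence drawn per ordered pair from
  Bernoulli(logistic(beta0 - beta_dist * d - beta_type * |dt|)),
  i.e. probability decreasing monotonically in both border distance and
  absolute type difference;
* an ordinal density (sparse/intermediate/dense) for present
  projections, with dense projections favored at short distances;
* an independent unknown mask hiding a proportion ``unknown_rate`` of
  ordered pairs (missing completely at random);
* hierarchy levels anti-correlated with type, on a designated
  module-like subset, and projection directions derived from the level
  difference with flip noise, so direction correlates positively with
  level difference and (indirectly) negatively with type difference.

Everything is driven by one ``numpy`` generator seeded from the config;
equal seeds give byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import expit

from .data import Area, Parcellation, ProjectionTable, Status

__all__ = ["GeneratorConfig", "SyntheticConnectome", "generate_parcellation", "generate_projections", "generate", "synthetic_collation"]

MODULE_NAMES = ("visual", "auditory", "somatosensory-motor", "fronto-limbic")


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic connectome, with study-scale defaults.

    ``n_areas``/``unknown_rate`` mirror the scale of whole-cortex tracing
    collations (dozens of areas, roughly two thirds of ordered pairs
    never examined).  ``radius`` (random-geometric model) is set so the
    parcellation graph diameter lands near 5, matching border distances
    that span about 1-6.  ``type_field_smoothness`` is the Gaussian
    correlation length of the type field in the unit square; the small
    default makes the differentiation gradient repeat several times
    across the sheet.  The betas define the logistic existence model.
    """

    n_areas: int = 64
    adjacency_model: str = "random-geometric"  # or "grid"
    radius: float = 0.30
    type_field_smoothness: float = 0.18
    n_untyped: int = 0
    beta0: float = 2.0
    beta_dist: float = 0.6
    beta_type: float = 0.8
    unknown_rate: float = 0.67
    strength_decay: float = 0.5
    hierarchy_noise: float = 0.5
    direction_flip_rate: float = 0.10
    unreliable_rate: float = 0.20
    seed: int = 20140726

    def __post_init__(self) -> None:
        if self.n_areas < 9:
            raise ValueError("n_areas must be >= 9")
        for name in ("unknown_rate", "direction_flip_rate", "unreliable_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.adjacency_model not in ("grid", "random-geometric"):
            raise ValueError(f"unknown adjacency_model {self.adjacency_model!r}")


@dataclass
class SyntheticConnectome:
    """Bundle of one generated connectome and its ground truth."""

    parcellation: Parcellation
    table: ProjectionTable
    hierarchies: dict[str, dict[str, int]]
    directions: pd.DataFrame
    positions: dict[str, tuple[float, float]]
    config: GeneratorConfig


def _grid_layout(n: int) -> tuple[nx.Graph, dict[str, tuple[float, float]]]:
    side = math.ceil(math.sqrt(n))
    g = nx.Graph()
    pos = {}
    coords = [(i, j) for i in range(side) for j in range(side)][:n]
    names = [f"A{k:02d}" for k in range(n)]
    for name, (i, j) in zip(names, coords):
        g.add_node(name)
        pos[name] = (i / max(side - 1, 1), j / max(side - 1, 1))
    index = {c: nm for nm, c in zip(names, coords)}
    for (i, j), nm in index.items():
        for di, dj in ((1, 0), (0, 1)):
            nb = index.get((i + di, j + dj))
            if nb is not None:
                g.add_edge(nm, nb)
    return g, pos


def _geometric_layout(
    n: int, radius: float, rng: np.random.Generator, max_attempts: int = 100
) -> tuple[nx.Graph, dict[str, tuple[float, float]]]:
    names = [f"A{k:02d}" for k in range(n)]
    for _ in range(max_attempts):
        pts = rng.random((n, 2))
        g = nx.Graph()
        g.add_nodes_from(names)
        for i in range(n):
            for j in range(i + 1, n):
                if np.hypot(*(pts[i] - pts[j])) <= radius:
                    g.add_edge(names[i], names[j])
        if nx.is_connected(g):
            return g, {nm: (float(x), float(y)) for nm, (x, y) in zip(names, pts)}
    raise RuntimeError(f"no connected geometric graph in {max_attempts} attempts (radius={radius})")


def generate_parcellation(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> tuple[Parcellation, dict[str, tuple[float, float]]]:
    """Generate a connected parcellation with spatially structured types."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if config.adjacency_model == "grid":
        g, pos = _grid_layout(config.n_areas)
    else:
        g, pos = _geometric_layout(config.n_areas, config.radius, rng)
    names = sorted(g.nodes)
    pts = np.array([pos[nm] for nm in names])
    # smooth random field: Gaussian-kernel mixture of iid normal amplitudes
    amp = rng.normal(size=len(names))
    ell = config.type_field_smoothness
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    field = (np.exp(-d2 / (2 * ell**2)) * amp[None, :]).sum(axis=1)
    # Quantile quantization into types 1..5 keeps every type populated.
    # The cut points are skewed so lower (less differentiated) types
    # predominate, as they do across real cortex outside the primary
    # sensory cores; this skew is what couples node degree to type under
    # the |type difference| existence model (low-type areas sit close in
    # type to most of the sheet and hence connect more).
    edges = np.quantile(field, [0.40, 0.65, 0.82, 0.93])
    types = 1 + np.searchsorted(edges, field)
    untyped = set(rng.choice(len(names), size=config.n_untyped, replace=False)) if config.n_untyped else set()
    areas = []
    for k, nm in enumerate(names):
        x, y = pos[nm]
        module = MODULE_NAMES[(x >= 0.5) * 2 + (y >= 0.5)]
        areas.append(
            Area(
                name=nm,
                structural_type=None if k in untyped else int(types[k]),
                module=module,
            )
        )
    return Parcellation(areas=areas, adjacency=g), pos


def generate_projections(
    parcellation: Parcellation,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> tuple[ProjectionTable, dict[str, dict[str, int]], pd.DataFrame]:
    """Draw statuses, hierarchy levels and directions for a parcellation.

    Returns the projection table (with the unknown mask applied), the
    named hierarchies for the designated subset, and the direction table
    for present projections within that subset.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    names = parcellation.names
    types = parcellation.structural_types
    dist = dict(nx.all_pairs_shortest_path_length(parcellation.adjacency))
    typed_abs = [
        abs(types[a] - types[b]) for a in types for b in types if a != b
    ]
    mean_abs_type = float(np.mean(typed_abs)) if typed_abs else 0.0

    records: dict[tuple[str, str], Status] = {}
    truth: dict[tuple[str, str], Status] = {}
    for s in names:
        for t in names:
            if s == t:
                continue
            d = dist[s][t]
            a = abs(types[s] - types[t]) if s in types and t in types else mean_abs_type
            p = expit(config.beta0 - config.beta_dist * d - config.beta_type * a)
            if rng.random() < p:
                # ordinal density: dense disfavored with distance
                w = np.array(
                    [1.0]
                    + [math.exp(-config.strength_decay * (d - 1) * k) for k in (1, 2)]
                )
                k = rng.choice(3, p=w / w.sum())
                st = (Status.SPARSE, Status.INTERMEDIATE, Status.DENSE)[k]
            else:
                st = Status.ABSENT
            truth[(s, t)] = st
            if rng.random() >= config.unknown_rate:
                records[(s, t)] = st
    table = ProjectionTable(areas=list(names), records=records)

    # hierarchy on the module-like subset with the most typed areas
    module_of = parcellation.modules
    counts = {m: sum(1 for a in types if module_of.get(a) == m) for m in MODULE_NAMES}
    subset_module = max(counts, key=counts.get)
    subset = [a for a in types if module_of.get(a) == subset_module]
    hierarchies: dict[str, dict[str, int]] = {}
    for hname in ("synthetic", "synthetic-alt"):
        levels = {}
        for a in subset:
            base = 2 * (6 - types[a]) - 1  # anti-correlated with type, span ~1..9
            lvl = base + int(round(rng.normal(0.0, config.hierarchy_noise)))
            levels[a] = max(1, lvl)
        hierarchies[hname] = levels

    primary = hierarchies["synthetic"]
    dir_rows = []
    for (s, t), st in truth.items():
        if st is Status.ABSENT or s not in primary or t not in primary:
            continue
        dl = primary[s] - primary[t]
        code = 3 if dl > 0 else (1 if dl < 0 else 2)  # descending runs down the hierarchy
        if rng.random() < config.direction_flip_rate:
            code = int(rng.integers(1, 4))
        dir_rows.append(
            {
                "source": s,
                "target": t,
                "direction": {1: "A", 2: "L", 3: "D"}[code],
                "reliable": int(rng.random() >= config.unreliable_rate),
            }
        )
    directions = pd.DataFrame(dir_rows, columns=["source", "target", "direction", "reliable"])

    # rich-club style hub flags: top-degree typed areas (11 of 64 scale)
    deg = {a: 0 for a in names}
    for (s, t), st in records.items():
        if st.is_present:
            deg[s] += 1
            deg[t] += 1
    n_hubs = max(1, round(len(names) * 11 / 64))
    ranked = sorted((a for a in names if a in types), key=lambda a: (-deg[a], a))
    hub_set = set(ranked[:n_hubs])
    for area in parcellation.areas:
        area.hub = area.name in hub_set
        if area.name in primary:
            area.hierarchy_level = primary[area.name]
    return table, hierarchies, directions


def generate(config: GeneratorConfig) -> SyntheticConnectome:
    """Generate a full synthetic connectome from one seed."""
    rng = np.random.default_rng(config.seed)
    parcellation, positions = generate_parcellation(config, rng)
    table, hierarchies, directions = generate_projections(parcellation, config, rng)
    return SyntheticConnectome(
        parcellation=parcellation,
        table=table,
        hierarchies=hierarchies,
        directions=directions,
        positions=positions,
        config=config,
    )


def synthetic_collation(seed: int = 20140726) -> SyntheticConnectome:
    """Synthetic stand-in for a whole-cortex tracing collation.

    A deterministic synthetic dataset at the scale of the cat
    corticocortical collation: 65 areas of which 49 carry a structural
    type, and roughly two thirds of ordered pairs masked unknown.  The
    intercept is raised (beta0 = 3.9 = logit(0.77) + beta_dist * E[d] +
    beta_type * E[a]) so that, as in whole-cortex tracing collations,
    roughly three quarters of *examined* pairs are found connected.  It
    is *synthetic*: statuses come from the generator's logistic model,
    not from any tracing experiment, and per-pair values match no
    published collation.
    """
    cfg = GeneratorConfig(n_areas=65, n_untyped=16, beta0=3.9, seed=seed)
    return generate(cfg)
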