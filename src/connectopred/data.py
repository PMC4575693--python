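"""Data model and I/O for inter-areal cortical connectivity collations.

A collation records the outcome of tract-tracing experiments for ordered
pairs of cortical areas.  Three situations must be kept apart:

* the pair was examined and a projection was found (with an ordinal
  density rating: sparse, intermediate, or dense),
* the pair was examined and the projection was explicitly reported
  absent,
* the pair was never examined (*unknown*).

Unknown is a first-class status here: a pair with no record was never
examined, which is categorically different from a pair examined and
found unconnected.  Conflating the two is the classic pitfall of
connectome collations and the reason this module refuses to default
missing cells to "absent".

Connectivity matrices are stored as TSV with a header row and a first
column of area names, rows = projection sources, columns = targets, and
cells in ``{NA, 0, 1, 2, 3}`` (``P`` marks a binarized "present").  The
spatial adjacency of the parcellation (shared area borders) is a
symmetric 0/1 TSV matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "Status",
    "Area",
    "Parcellation",
    "ProjectionTable",
    "load_connectivity",
    "save_connectivity",
    "load_adjacency",
    "save_adjacency",
    "load_areas",
    "save_areas",
    "load_hierarchies",
    "save_hierarchies",
    "apply_adjacency_edits",
    "binarize",
    "CAT_ADJACENCY_EDITS",
    "STRENGTH_WEIGHTS",
]


class Status(Enum):
    """Projection status for one ordered (source, target) area pair."""

    UNKNOWN = "unknown"
    ABSENT = "absent"
    SPARSE = "sparse"
    INTERMEDIATE = "intermediate"
    DENSE = "dense"
    #: binarized "present" (density information discarded)
    PRESENT = "present"

    @property
    def is_present(self) -> bool:
        return self in _PRESENT_STATUSES

    @property
    def is_examined(self) -> bool:
        return self is not Status.UNKNOWN

    @property
    def ordinal(self) -> int | None:
        """Ordinal code: absent=0, sparse=1, intermediate=2, dense=3."""
        return _ORDINAL.get(self)


_PRESENT_STATUSES = {Status.SPARSE, Status.INTERMEDIATE, Status.DENSE, Status.PRESENT}
_ORDINAL = {Status.ABSENT: 0, Status.SPARSE: 1, Status.INTERMEDIATE: 2, Status.DENSE: 3}

#: cell token <-> status for the TSV matrix dialect
_TOKEN_TO_STATUS = {
    "NA": Status.UNKNOWN,
    "0": Status.ABSENT,
    "1": Status.SPARSE,
    "2": Status.INTERMEDIATE,
    "3": Status.DENSE,
    "P": Status.PRESENT,
}
_STATUS_TO_TOKEN = {v: k for k, v in _TOKEN_TO_STATUS.items()}

#: metric weights for the ordinal density ratings: projection strengths span
#: orders of magnitude, so sparse/intermediate/dense are weighted 10^0/10^1/10^2.
STRENGTH_WEIGHTS = {Status.SPARSE: 1, Status.INTERMEDIATE: 10, Status.DENSE: 100}

#: Published corrections reconciling the Scannell et al. (1995) cat spatial
#: adjacency matrix with the printed parcellation map: adjacencies to remove
#: and to add (applied symmetrically).
CAT_ADJACENCY_EDITS: list[tuple[str, str, str]] = [
    ("remove", "17", "CGp"),
    ("remove", "17", "RS"),
    ("add", "18", "20a"),
    ("add", "18", "20b"),
    ("add", "CGa", "17"),
    ("add", "CGa", "4"),
    ("add", "CGa", "6m"),
    ("add", "SVA", "18"),
    ("add", "SVA", "20b"),
    ("add", "SVA", "RS"),
    ("add", "SIV", "Ig"),
    ("add", "4g", "6m"),
]


@dataclass
class Area:
    """A named cortical area with optional anatomical annotations.

    ``structural_type`` is the ordinal cytoarchitectonic type 1 (least
    differentiated, e.g. limbic cortex) to 5 (most differentiated, e.g.
    primary sensory koniocortex).  ``hierarchy_level`` is a level in a
    published processing hierarchy (visual areas only, typically).
    ``module`` is the functional community label, ``hub`` flags rich-club
    membership.
    """

    name: str
    structural_type: int | None = None
    hierarchy_level: int | None = None
    module: str | None = None
    hub: bool | None = None

    def __post_init__(self) -> None:
        if self.structural_type is not None and self.structural_type not in (1, 2, 3, 4, 5):
            raise ValueError(
                f"area {self.name!r}: structural_type must be in 1..5, got {self.structural_type}"
            )


@dataclass
class Parcellation:
    """An ordered set of areas plus their symmetric border-adjacency graph."""

    areas: list[Area]
    adjacency: nx.Graph = field(default_factory=nx.Graph)

    def __post_init__(self) -> None:
        names = [a.name for a in self.areas]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate area names: {sorted(dupes)}")
        unknown_nodes = set(self.adjacency.nodes) - set(names)
        if unknown_nodes:
            raise ValueError(f"adjacency references unlisted areas: {sorted(unknown_nodes)}")
        if any(u == v for u, v in self.adjacency.edges):
            raise ValueError("self-adjacency is not allowed")
        # make sure every area is a node so isolated areas are representable
        self.adjacency.add_nodes_from(names)

    @property
    def names(self) -> list[str]:
        return [a.name for a in self.areas]

    def area(self, name: str) -> Area:
        for a in self.areas:
            if a.name == name:
                return a
        raise KeyError(name)

    @property
    def structural_types(self) -> dict[str, int]:
        """Name -> type, over areas that carry a type."""
        return {a.name: a.structural_type for a in self.areas if a.structural_type is not None}

    @property
    def modules(self) -> dict[str, str]:
        return {a.name: a.module for a in self.areas if a.module is not None}

    @property
    def hubs(self) -> dict[str, bool]:
        return {a.name: a.hub for a in self.areas if a.hub is not None}

    def copy(self) -> "Parcellation":
        return Parcellation(
            [Area(a.name, a.structural_type, a.hierarchy_level, a.module, a.hub) for a in self.areas],
            self.adjacency.copy(),
        )


@dataclass
class ProjectionTable:
    """Directed projection statuses keyed by ordered (source, target) pair.

    Pairs of distinct areas with no record are implicitly ``unknown``.
    Self-projections are outside the data model (never stored).
    """

    areas: list[str]
    records: dict[tuple[str, str], Status] = field(default_factory=dict)

    def __post_init__(self) -> None:
        area_set = set(self.areas)
        if len(area_set) != len(self.areas):
            raise ValueError("duplicate area names in projection table")
        for (s, t), st in self.records.items():
            if s == t:
                raise ValueError(f"self-projection {s}->{t} is not allowed")
            if s not in area_set or t not in area_set:
                raise ValueError(f"record {s}->{t} references unlisted area")
            if st is Status.UNKNOWN:
                raise ValueError("unknown pairs must be absent from records, not stored")

    def status(self, source: str, target: str) -> Status:
        return self.records.get((source, target), Status.UNKNOWN)

    def pairs(self) -> Iterable[tuple[str, str]]:
        """All ordered pairs of distinct areas."""
        for s in self.areas:
            for t in self.areas:
                if s != t:
                    yield (s, t)

    def counts(self) -> dict[Status, int]:
        n_pairs = len(self.areas) * (len(self.areas) - 1)
        out = {st: 0 for st in Status}
        for st in self.records.values():
            out[st] += 1
        out[Status.UNKNOWN] = n_pairs - len(self.records)
        return out

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame over all ordered pairs, unknown included."""
        rows = [(s, t, self.status(s, t).value) for s, t in self.pairs()]
        return pd.DataFrame(rows, columns=["source", "target", "status"])

    def to_matrix(self) -> pd.DataFrame:
        """Square token matrix (rows = sources, columns = targets)."""
        mat = pd.DataFrame("NA", index=self.areas, columns=self.areas)
        for (s, t), st in self.records.items():
            mat.loc[s, t] = _STATUS_TO_TOKEN[st]
        for a in self.areas:
            mat.loc[a, a] = "NA"  # diagonal is out of the data model
        return mat


def load_connectivity(matrix_file: str | Path) -> ProjectionTable:
    """Read a TSV connectivity matrix into a :class:`ProjectionTable`.

    Cells in ``{NA, 0, 1, 2, 3, P}``; the diagonal is ignored; every
    non-``NA`` off-diagonal cell becomes one record.
    """
    df = pd.read_csv(
        matrix_file, sep="\t", index_col=0, dtype=str, comment="#", keep_default_na=False
    )
    df.index = df.index.astype(str).str.strip()
    df.columns = [str(c).strip() for c in df.columns]
    if df.index.duplicated().any():
        raise ValueError(
            f"{matrix_file}: duplicate row area names: "
            f"{sorted(df.index[df.index.duplicated()])}"
        )
    if len(set(df.columns)) != len(df.columns):
        raise ValueError(f"{matrix_file}: duplicate column area names")
    if set(df.index) != set(df.columns):
        raise ValueError(f"{matrix_file}: row and column area sets differ")
    areas = list(df.index)
    records: dict[tuple[str, str], Status] = {}
    for s in areas:
        for t in areas:
            if s == t:
                continue
            token = str(df.loc[s, t]).strip()
            if token not in _TOKEN_TO_STATUS:
                raise ValueError(
                    f"{matrix_file}: unknown cell token {token!r} at row {s!r}, column {t!r}"
                )
            st = _TOKEN_TO_STATUS[token]
            if st is not Status.UNKNOWN:
                records[(s, t)] = st
    return ProjectionTable(areas=areas, records=records)


def save_connectivity(table: ProjectionTable, path: str | Path) -> None:
    table.to_matrix().to_csv(path, sep="\t", index_label="area")


def load_adjacency(path: str | Path) -> nx.Graph:
    """Read a symmetric 0/1 TSV matrix into an undirected graph."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str).str.strip()
    df.columns = [str(c).strip() for c in df.columns]
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: adjacency matrix rows and columns must match")
    vals = df.to_numpy()
    if not (vals == vals.T).all():
        raise ValueError(f"{path}: adjacency matrix is not symmetric")
    if vals.diagonal().any():
        raise ValueError(f"{path}: adjacency matrix has self-adjacencies")
    g = nx.Graph()
    g.add_nodes_from(df.index)
    for i, a in enumerate(df.index):
        for j, b in enumerate(df.columns):
            if j > i and vals[i, j]:
                g.add_edge(a, b)
    return g


def save_adjacency(graph: nx.Graph, path: str | Path, order: Sequence[str] | None = None) -> None:
    order = list(order) if order is not None else sorted(graph.nodes)
    mat = pd.DataFrame(0, index=order, columns=order, dtype=int)
    for a, b in graph.edges:
        mat.loc[a, b] = 1
        mat.loc[b, a] = 1
    mat.to_csv(path, sep="\t", index_label="area")


def load_areas(path: str | Path) -> list[Area]:
    """Read an area-attribute TSV (area, structural_type, module, hub)."""
    df = pd.read_csv(path, sep="\t", dtype={"area": str}, comment="#")
    areas = []
    for _, row in df.iterrows():
        st = row.get("structural_type")
        module = row.get("module")
        hub = row.get("hub")
        areas.append(
            Area(
                name=str(row["area"]),
                structural_type=None if pd.isna(st) else int(st),
                module=None if pd.isna(module) else str(module),
                hub=None if pd.isna(hub) else bool(int(hub)),
            )
        )
    return areas


def save_areas(areas: Sequence[Area], path: str | Path) -> None:
    rows = []
    for a in areas:
        rows.append(
            {
                "area": a.name,
                "structural_type": a.structural_type,
                "module": a.module,
                "hub": None if a.hub is None else int(a.hub),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_hierarchies(path: str | Path) -> dict[str, dict[str, int]]:
    """Read named hierarchies from a long TSV (area, hierarchy, level)."""
    df = pd.read_csv(path, sep="\t", dtype={"area": str, "hierarchy": str}, comment="#")
    out: dict[str, dict[str, int]] = {}
    for name, grp in df.groupby("hierarchy"):
        out[str(name)] = dict(zip(grp["area"], grp["level"].astype(int)))
    return out


def save_hierarchies(hierarchies: Mapping[str, Mapping[str, int]], path: str | Path) -> None:
    rows = [
        {"area": a, "hierarchy": h, "level": lvl}
        for h, levels in hierarchies.items()
        for a, lvl in levels.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def apply_adjacency_edits(
    parcellation: Parcellation,
    edits: Iterable[tuple[str, str, str]],
) -> Parcellation:
    """Apply symmetric add/remove edits to the border-adjacency graph.

    Each edit is ``(op, area_a, area_b)`` with ``op`` in ``{add, remove}``.
    Removing a non-existent adjacency or adding an existing one warns but
    does not fail (the operation is idempotent).
    """
    out = parcellation.copy()
    names = set(out.names)
    g = out.adjacency
    for op, a, b in edits:
        if a not in names or b not in names:
            raise ValueError(f"adjacency edit {op} ({a}, {b}) references unknown area")
        if op == "add":
            if g.has_edge(a, b):
                warnings.warn(f"adjacency ({a}, {b}) already present; add is a no-op")
            g.add_edge(a, b)
        elif op == "remove":
            if not g.has_edge(a, b):
                warnings.warn(f"adjacency ({a}, {b}) not present; remove is a no-op")
            else:
                g.remove_edge(a, b)
        else:
            raise ValueError(f"unknown adjacency edit op {op!r}")
    return out


def binarize(table: ProjectionTable) -> ProjectionTable:
    """Collapse sparse/intermediate/dense to a single ``present`` status.

    Absent and unknown are preserved exactly; density information is
    discarded so that projection frequencies can be normalized across
    variables without per-density stratification.
    """
    records = {
        pair: (Status.PRESENT if st.is_present else st) for pair, st in table.records.items()
    }
    return ProjectionTable(areas=list(table.areas), records=records)
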