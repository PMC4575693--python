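from pathlib import Path

import networkx as nx
import pytest

from connectopred.data import Area, Parcellation, ProjectionTable, Status
from connectopred.pipeline import load_inputs
from connectopred.synth import GeneratorConfig, generate

REPO_ROOT = Path(__file__).resolve().parents[1]
COLLATION_DIR = REPO_ROOT / "data" / "synthetic_collation"


@pytest.fixture
def toy_parcellation() -> Parcellation:
    """Five areas on a path graph A-B-C-D-E with types 1..5."""
    areas = [Area(name=n, structural_type=t) for n, t in zip("ABCDE", (1, 2, 3, 4, 5))]
    g = nx.path_graph(list("ABCDE"))
    return Parcellation(areas=areas, adjacency=g)


@pytest.fixture
def toy_table(toy_parcellation) -> ProjectionTable:
    return ProjectionTable(
        areas=list("ABCDE"),
        records={
            ("A", "B"): Status.DENSE,
            ("B", "A"): Status.SPARSE,
            ("A", "C"): Status.ABSENT,
            ("C", "D"): Status.INTERMEDIATE,
            ("E", "A"): Status.ABSENT,
        },
    )


@pytest.fixture(scope="session")
def collation():
    """The shipped synthetic stand-in collation (65 areas, 49 typed)."""
    return load_inputs(COLLATION_DIR)


@pytest.fixture(scope="session")
def bundle():
    """One default-parameter synthetic connectome, fixed seed."""
    return generate(GeneratorConfig(seed=11))
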