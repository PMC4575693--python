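"""Build the synthetic stand-in collation shipped under data/.

Generates, from a fixed seed, a deterministic synthetic whole-cortex
connectome at collation scale (65 areas, 49 typed, ~67% of ordered pairs
unknown, ~77% of examined pairs present) and writes it in the TSV
formats the readers consume.  Every file name carries ``_synthetic`` —
these are generator output, not tracing data.

Run from the repository root:  python analysis/01_build_synthetic_collation.py
"""

from pathlib import Path

from connectopred.data import save_adjacency, save_areas, save_connectivity, save_hierarchies
from connectopred.synth import synthetic_collation

OUT = Path("data/synthetic_collation")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    bundle = synthetic_collation(seed=20140726)
    parc, table = bundle.parcellation, bundle.table
    save_connectivity(table, OUT / "connectivity_synthetic.tsv")
    save_adjacency(parc.adjacency, OUT / "adjacency_synthetic.tsv", order=parc.names)
    save_areas(parc.areas, OUT / "areas_synthetic.tsv")
    save_hierarchies(bundle.hierarchies, OUT / "hierarchies_synthetic.tsv")
    bundle.directions.to_csv(OUT / "directions_synthetic.tsv", sep="\t", index=False)
    counts = {k.value: v for k, v in table.counts().items()}
    n_pairs = len(parc.names) * (len(parc.names) - 1)
    print(f"wrote {OUT}/: {len(parc.names)} areas, "
          f"{len(bundle.parcellation.structural_types)} typed")
    print(f"ordered pairs {n_pairs}, statuses {counts}")
    print(f"unknown fraction {counts['unknown'] / n_pairs:.3f}")


if __name__ == "__main__":
    main()
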