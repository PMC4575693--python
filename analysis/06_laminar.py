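"""Laminar projection directions versus type and level differences.

Correlates the ordinal direction code (ascending=1, lateral=2,
descending=3) of the hierarchy-subset projections with the signed type
and level differences, with and without the directions flagged
unreliable.  In the generator, directions derive from level differences
(descending = down the hierarchy) and levels are anti-correlated with
type, so direction should correlate positively with the level
difference and negatively with the type difference.

Run from the repository root:  python analysis/06_laminar.py
"""

import json
from pathlib import Path

import pandas as pd

from connectopred.laminar import direction_correlations
from connectopred.pipeline import load_inputs
from connectopred.variables import pair_variables

DATA = Path("data/synthetic_collation")
OUT = Path("results")


def main() -> None:
    OUT.mkdir(exist_ok=True)
    parcellation, _, hierarchies, directions = load_inputs(DATA)
    variables = pair_variables(parcellation, hierarchies["synthetic"])
    print(f"{len(directions)} directed projections in the hierarchy subset "
          f"({int(directions['reliable'].sum())} marked reliable)")
    report = {}
    for label, include in (("all", True), ("reliable_only", False)):
        res = direction_correlations(directions, variables, include_unreliable=include)
        report[label] = {k: v.to_dict() for k, v in res.items()}
        print(f"[{label}] direction vs type diff: rho={res['delta_type'].statistic:+.2f} "
              f"(p={res['delta_type'].p_value:.3g}, n={res['delta_type'].n[0]}); "
              f"vs level diff: rho={res['delta_level'].statistic:+.2f} "
              f"(p={res['delta_level'].p_value:.3g})")
    with open(OUT / "laminar.json", "w") as fh:
        json.dump(report, fh, indent=1)
        fh.write("\n")


if __name__ == "__main__":
    main()
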