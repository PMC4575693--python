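"""End-to-end orchestration: variables -> existence stats -> discriminant
model -> predictions -> topology -> laminar, with reproducible outputs.

``run_all`` executes every stage on either loaded inputs or a generated
synthetic connectome and writes machine-readable TSV/JSON reports into
an output directory.  Every JSON report carries provenance (seed, input
digests, package version); runs with equal seeds and inputs are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data import (
    Parcellation,
    ProjectionTable,
    load_adjacency,
    load_areas,
    load_connectivity,
    load_hierarchies,
)
from .laminar import direction_correlations
from .lda import (
    DEFAULT_THRESHOLDS,
    build_grid,
    construct_cases,
    cross_validate,
    fit_lda,
    n_decided,
    predict_unknown,
)
from .stats import frequency_table, spearman
from .synth import GeneratorConfig, SyntheticConnectome, generate
from .topology import (
    degree_type_correlations,
    module_comparisons,
    node_summaries,
    robustness_scan,
)
from .variables import analysis_frame, pair_variables

__all__ = ["RunConfig", "run_all", "load_inputs"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs and switches for one pipeline run.

    Either ``input_dir`` (TSV files as written by the readers/writers in
    :mod:`connectopred.data`) or ``generator`` (synthesize the inputs)
    must be given.
    """

    out_dir: Path
    input_dir: Path | None = None
    generator: GeneratorConfig | None = None
    hierarchy: str | None = None  # name of the hierarchy to use; default: first
    thresholds: tuple = DEFAULT_THRESHOLDS
    prediction_theta: float = 0.75
    n_cv_cycles: int = 200
    seed: int = 20140726

    def __post_init__(self) -> None:
        if (self.input_dir is None) == (self.generator is None):
            raise ValueError("exactly one of input_dir / generator must be set")


def load_inputs(input_dir: Path) -> tuple[Parcellation, ProjectionTable, dict, pd.DataFrame | None]:
    """Load a collation directory written by the data module.

    Expects connectivity*.tsv, adjacency*.tsv, areas*.tsv,
    hierarchies*.tsv and optionally directions*.tsv.
    """
    input_dir = Path(input_dir)

    def _one(pattern: str, required: bool = True) -> Path | None:
        hits = sorted(input_dir.glob(pattern))
        if not hits:
            if required:
                raise FileNotFoundError(f"no {pattern} in {input_dir}")
            return None
        return hits[0]

    table = load_connectivity(_one("connectivity*.tsv"))
    adjacency = load_adjacency(_one("adjacency*.tsv"))
    areas = load_areas(_one("areas*.tsv"))
    parcellation = Parcellation(areas=areas, adjacency=adjacency)
    hier_path = _one("hierarchies*.tsv", required=False)
    hierarchies = load_hierarchies(hier_path) if hier_path else {}
    dir_path = _one("directions*.tsv", required=False)
    directions = pd.read_csv(dir_path, sep="\t", dtype={"source": str, "target": str}) if dir_path else None
    return parcellation, table, hierarchies, directions


def _digest(obj) -> str:
    return hashlib.sha256(repr(obj).encode()).hexdigest()[:16]


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return None if np.isnan(o) else float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if hasattr(o, "to_dict"):
        return o.to_dict()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_json(path: Path, payload: dict, provenance: dict) -> None:
    with open(path, "w") as fh:
        json.dump({"provenance": provenance, **payload}, fh, indent=1, default=_json_default, sort_keys=True)
        fh.write("\n")


def run_all(config: RunConfig) -> dict:
    """Run every analysis stage and write the report bundle.

    Returns a dict of the in-memory results keyed by stage name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    if config.generator is not None:
        bundle: SyntheticConnectome = generate(config.generator)
        parcellation, table = bundle.parcellation, bundle.table
        hierarchies, directions = bundle.hierarchies, bundle.directions
        source_desc = {"generator": vars(config.generator)}
    else:
        parcellation, table, hierarchies, directions = load_inputs(config.input_dir)
        source_desc = {"input_dir": str(config.input_dir)}
    provenance = {
        "version": __version__,
        "seed": config.seed,
        "inputs": _digest((sorted(table.records.items()), parcellation.names)),
        **source_desc,
    }

    hier_name = config.hierarchy or (next(iter(hierarchies)) if hierarchies else None)
    hierarchy = hierarchies.get(hier_name, {}) if hier_name else {}
    results: dict = {}

    # --- stage: variables -------------------------------------------------
    logger.info("stage variables")
    variables = pair_variables(parcellation, hierarchy)
    frame = analysis_frame(table, variables)
    frame.to_csv(out / "pair_variables.tsv", sep="\t", index=False)
    results["frame"] = frame

    # --- stage: existence statistics -------------------------------------
    logger.info("stage existence stats")
    stats_report: dict = {"counts": {k.value: v for k, v in table.counts().items()}}
    freq = {}
    for var in ("delta_dist", "abs_type", "abs_level"):
        try:
            ft = frequency_table(frame, var)
        except ValueError:
            continue
        ft.to_csv(out / f"frequencies_{var}.tsv", sep="\t", index=False)
        freq[var] = ft
        if len(ft) >= 3 and ft["rel_freq"].nunique() > 1:
            stats_report[f"spearman_relfreq_{var}"] = spearman(
                ft["rel_freq"].to_numpy(), ft["value"].to_numpy()
            )
    both = frame[frame["delta_type"].notna() & frame["delta_level"].notna()]
    if len(both) >= 3:
        stats_report["spearman_type_level"] = spearman(
            both["delta_type"].to_numpy(), both["delta_level"].to_numpy()
        )
    ind = frame[frame["delta_dist"].notna() & frame["abs_type"].notna()]
    stats_report["spearman_dist_abs_type"] = spearman(
        ind["delta_dist"].to_numpy(), ind["abs_type"].to_numpy()
    )
    _write_json(out / "existence_stats.json", {"stats": stats_report}, provenance)
    results["existence"] = stats_report
    results["frequencies"] = freq

    # --- stage: discriminant model ----------------------------------------
    logger.info("stage LDA")
    grid = build_grid(frame)
    grid.to_csv(out / "lda_grid.tsv", sep="\t", index=False)
    cases = construct_cases(grid)
    model = fit_lda(cases)
    cv = cross_validate(
        cases, thresholds=config.thresholds, n_cycles=config.n_cv_cycles, seed=config.seed
    )
    cv.to_csv(out / "crossval.tsv", sep="\t", index=False)
    predictions = predict_unknown(model, frame, thresholds=config.thresholds)
    predictions.to_csv(out / "predictions.tsv", sep="\t", index=False)
    _write_json(
        out / "lda_model.json",
        {
            "model": model.to_dict(),
            "n_cases": {"absent": int((cases["label"] == 0).sum()), "present": int((cases["label"] == 1).sum())},
            "n_unexamined": int(len(predictions)),
            "n_decided_at_theta": {
                f"{th:.2f}": n_decided(predictions, th) for th in config.thresholds
            },
        },
        provenance,
    )
    results.update({"grid": grid, "cases": cases, "model": model, "crossval": cv, "predictions": predictions})

    # --- stage: topology ---------------------------------------------------
    logger.info("stage topology")
    types = parcellation.structural_types
    summaries = node_summaries(table, variables, area_subset=sorted(types))
    summaries.to_csv(out / "node_summaries.tsv", sep="\t", index=False)
    topo_report: dict = {
        "degree_type": {k: v for k, v in degree_type_correlations(summaries, types).items()}
    }
    modules = parcellation.modules
    hubs = parcellation.hubs
    if modules and hubs:
        mc = module_comparisons(types, modules, hubs)
        topo_report["modules"] = {
            "hub_vs_nonhub": mc["hub_vs_nonhub"],
            "hub_median": mc["hub_median"],
            "nonhub_median": mc["nonhub_median"],
            "module_medians": mc["module_medians"],
            "kruskal_wallis": mc["modules_kruskal_wallis"],
            "trend_jt": mc["module_trend_jt"],
            "posthoc": [
                {
                    "modules": list(p["modules"]),
                    "result": p["result"],
                    "alpha_corrected": p["alpha_corrected"],
                    "significant": p["significant"],
                }
                for p in mc["posthoc"]
            ],
        }
    scan = robustness_scan(summaries, types)
    scan.to_csv(out / "robustness.tsv", sep="\t", index=False)
    topo_report["robustness_q_max_significant"] = scan.attrs["q_max_significant"]
    _write_json(out / "topology.json", {"topology": topo_report}, provenance)
    results.update({"summaries": summaries, "topology": topo_report, "robustness": scan})

    # --- stage: laminar ----------------------------------------------------
    if directions is not None and len(directions):
        logger.info("stage laminar")
        lam = direction_correlations(directions, variables)
        _write_json(out / "laminar.json", {"laminar": lam}, provenance)
        results["laminar"] = lam

    _write_json(
        out / "run.json",
        {"elapsed_s": round(time.time() - t0, 3), "stages": sorted(results.keys())},
        provenance,
    )
    return results
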