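"""Fit the discriminant model and predict unexamined connections.

Builds the co-occurrence-normalized (|type diff|, distance) grid,
expands it into labeled cases, fits the two-class linear discriminant
(uniform priors), cross-validates over 200 random 10% holdouts at
thresholds 0.60..0.90, and classifies every unexamined pair whose
posterior clears the threshold.

Run from the repository root:  python analysis/04_lda_predictions.py
"""

from pathlib import Path

from connectopred.lda import (
    DEFAULT_THRESHOLDS,
    build_grid,
    construct_cases,
    cross_validate,
    fit_lda,
    n_decided,
    predict_unknown,
)
from connectopred.pipeline import load_inputs
from connectopred.variables import analysis_frame, pair_variables

DATA = Path("data/synthetic_collation")
OUT = Path("results")
SEED = 20140726


def main() -> None:
    OUT.mkdir(exist_ok=True)
    parcellation, table, hierarchies, _ = load_inputs(DATA)
    frame = analysis_frame(table, pair_variables(parcellation, hierarchies["synthetic"]))

    grid = build_grid(frame)
    grid.to_csv(OUT / "lda_grid.tsv", sep="\t", index=False)
    cases = construct_cases(grid)
    model = fit_lda(cases)
    ca, cd = model.standardized_coefficients
    print(f"cases: {int((cases['label'] == 1).sum())} present, "
          f"{int((cases['label'] == 0).sum())} absent over {len(grid)} grid cells")
    print(f"standardized discriminant coefficients: |type diff| {ca:.2f}, distance {cd:.2f}")

    cv = cross_validate(cases, seed=SEED)
    cv.to_csv(OUT / "crossval.tsv", sep="\t", index=False)
    row = cv[cv["threshold"] == 0.75].iloc[0]
    print(f"cross-validation at theta=0.75: accuracy "
          f"present {row['acc_present_mean']:.2f}+-{row['acc_present_sd']:.2f}, "
          f"absent {row['acc_absent_mean']:.2f}+-{row['acc_absent_sd']:.2f}, "
          f"overall {row['acc_overall_mean']:.2f}; "
          f"{row['n_classified_mean']:.1f} test cases classified on average")

    predictions = predict_unknown(model, frame, thresholds=DEFAULT_THRESHOLDS)
    predictions.to_csv(OUT / "predictions.tsv", sep="\t", index=False)
    print(f"unexamined pairs: {len(predictions)}; decided at theta=0.75: "
          f"{n_decided(predictions, 0.75)}")


if __name__ == "__main__":
    main()
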