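"""Linear discriminant prediction of connection existence.

The model classifies ordered area pairs as connected or unconnected from
two predictors: the absolute structural type difference ``a = |delta_type|``
and the border distance ``d = delta_dist``.

Because the parcellation geometry makes some predictor combinations far
more frequent than others (small-a/small-d cells abound, a=4/d=4 cells are
rare), raw examined pairs would over-weight the densely sampled cells.
The observed absent/present counts in each (a, d) cell are therefore
normalized by the maximally possible number of co-occurrences of that
combination (counted over *all* ordered typed pairs, regardless of
examination status), giving per-cell percentages %absent and %present.
Note %absent + %present != 100: the remainder is unexamined.  The
percentages are then turned back into integer case counts (round half
up), which form the LDA training set.

The discriminant itself is the classical two-class model with a shared
(pooled, bias-corrected) covariance and uniform priors: with class means
m0 (absent), m1 (present) and pooled covariance S,

    w = S^-1 (m1 - m0),   b = -1/2 (m1 + m0)^T w,
    P(present | x) = logistic(w . x + b),

which is exactly the two-Gaussian, shared-covariance Bayes posterior.
Unexamined pairs are labeled present when the posterior reaches a
threshold theta, absent when it falls below 1 - theta, and left
unclassified in between.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "DiscriminantModel",
    "build_grid",
    "construct_cases",
    "fit_lda",
    "cross_validate",
    "predict_unknown",
    "n_decided",
    "DEFAULT_THRESHOLDS",
]

#: classification thresholds evaluated in cross-validation: 0.60 .. 0.90
DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.60, 0.91, 0.05), 2))


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)


@dataclass
class DiscriminantModel:
    """Fitted two-class linear discriminant with uniform priors."""

    mean_absent: np.ndarray
    mean_present: np.ndarray
    pooled_covariance: np.ndarray
    weights: np.ndarray
    bias: float
    standardized_coefficients: np.ndarray
    predictors: tuple[str, ...] = ("abs_type", "delta_dist")
    ridge: float = 0.0

    def posterior(self, X) -> np.ndarray:
        """P(present | x) for rows of X (n x 2)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return expit(X @ self.weights + self.bias)

    def to_dict(self) -> dict:
        return {
            "predictors": list(self.predictors),
            "mean_absent": self.mean_absent.tolist(),
            "mean_present": self.mean_present.tolist(),
            "pooled_covariance": self.pooled_covariance.tolist(),
            "weights": self.weights.tolist(),
            "bias": float(self.bias),
            "standardized_coefficients": self.standardized_coefficients.tolist(),
            "priors": [0.5, 0.5],
            "ridge": self.ridge,
        }


def build_grid(df: pd.DataFrame, variables: pd.DataFrame | None = None) -> pd.DataFrame:
    """Co-occurrence-normalized grid over (abs_type, delta_dist) cells.

    ``df`` is the analysis frame (pair variables joined with binarized
    statuses).  ``variables``, if given, supplies the full enumeration of
    ordered typed pairs used for n_possible; by default ``df`` itself is
    used (it already spans all ordered pairs, examined or not).

    Returns one row per occurring (abs_type, delta_dist) cell with
    n_possible, n_absent_obs, n_present_obs, pct_absent, pct_present.
    """
    universe = variables if variables is not None else df
    defined = universe[universe["abs_type"].notna() & universe["delta_dist"].notna()]
    possible = (
        defined.groupby(["abs_type", "delta_dist"]).size().rename("n_possible").reset_index()
    )
    obs = df[df["abs_type"].notna() & df["delta_dist"].notna() & (df["status"] != "unknown")]
    counts = (
        obs.groupby(["abs_type", "delta_dist", "status"]).size().unstack(fill_value=0)
    )
    for col in ("absent", "present"):
        if col not in counts:
            counts[col] = 0
    counts = counts.reset_index().rename(
        columns={"absent": "n_absent_obs", "present": "n_present_obs"}
    )
    grid = possible.merge(counts, on=["abs_type", "delta_dist"], how="left").fillna(
        {"n_absent_obs": 0, "n_present_obs": 0}
    )
    bad = grid[(grid["n_possible"] == 0) & ((grid["n_absent_obs"] + grid["n_present_obs"]) > 0)]
    if len(bad):
        raise ValueError("observations in cells with zero possible co-occurrences; inconsistent data")
    grid["n_absent_obs"] = grid["n_absent_obs"].astype(int)
    grid["n_present_obs"] = grid["n_present_obs"].astype(int)
    grid["pct_absent"] = 100.0 * grid["n_absent_obs"] / grid["n_possible"]
    grid["pct_present"] = 100.0 * grid["n_present_obs"] / grid["n_possible"]
    return grid


def construct_cases(grid: pd.DataFrame) -> pd.DataFrame:
    """Expand grid percentages into labeled cases for the discriminant.

    Per cell, round(pct_absent) cases labeled 0 and round(pct_present)
    cases labeled 1 (round half up), all carrying that cell's predictor
    values.  Columns: abs_type, delta_dist, label, cell.
    """
    rows = []
    for idx, row in grid.iterrows():
        n_a = int(_round_half_up(np.array([row["pct_absent"]]))[0])
        n_p = int(_round_half_up(np.array([row["pct_present"]]))[0])
        for label, count in ((0, n_a), (1, n_p)):
            for _ in range(count):
                rows.append((row["abs_type"], row["delta_dist"], label, idx))
    return pd.DataFrame(rows, columns=["abs_type", "delta_dist", "label", "cell"])


def fit_lda(cases: pd.DataFrame, ridge_eps: float = 1e-8) -> DiscriminantModel:
    """Fit the two-class discriminant on constructed cases.

    Pooled covariance uses the bias-corrected within-class estimator
    (denominator N - 2).  If it is numerically singular, a ridge of
    ``ridge_eps * trace`` is added once; if still singular the fit fails
    with the condition number.  Standardized coefficients are reported as
    magnitudes |w_j| * s_j with s_j the pooled within-class standard
    deviation of predictor j.
    """
    X = cases[["abs_type", "delta_dist"]].to_numpy(dtype=float)
    y = cases["label"].to_numpy(dtype=int)
    X0, X1 = X[y == 0], X[y == 1]
    if len(X0) == 0 or len(X1) == 0:
        raise ValueError("both classes must be non-empty to fit the discriminant")
    n0, n1 = len(X0), len(X1)
    m0, m1 = X0.mean(axis=0), X1.mean(axis=0)
    s0 = np.cov(X0, rowvar=False, ddof=1) if n0 > 1 else np.zeros((X.shape[1],) * 2)
    s1 = np.cov(X1, rowvar=False, ddof=1) if n1 > 1 else np.zeros((X.shape[1],) * 2)
    pooled = ((n0 - 1) * np.atleast_2d(s0) + (n1 - 1) * np.atleast_2d(s1)) / (n0 + n1 - 2)
    ridge = 0.0
    cov = pooled
    if np.linalg.cond(cov) > 1e12 or not np.isfinite(np.linalg.cond(cov)):
        ridge = ridge_eps * np.trace(pooled)
        cov = pooled + ridge * np.eye(pooled.shape[0])
        if np.linalg.cond(cov) > 1e12:
            raise np.linalg.LinAlgError(
                f"pooled covariance singular even after ridge; cond={np.linalg.cond(cov):.3g}"
            )
    w = np.linalg.solve(cov, m1 - m0)
    b = -0.5 * float((m1 + m0) @ w)  # uniform priors: no log-prior-ratio term
    std = np.sqrt(np.diag(cov))
    return DiscriminantModel(
        mean_absent=m0,
        mean_present=m1,
        pooled_covariance=cov,
        weights=w,
        bias=b,
        standardized_coefficients=np.abs(w) * std,
        ridge=ridge,
    )


def _decide(posterior: np.ndarray, theta: float) -> np.ndarray:
    """present / absent / unclassified decisions at one threshold."""
    out = np.full(posterior.shape, "unclassified", dtype=object)
    out[posterior >= theta] = "present"
    out[posterior <= 1.0 - theta] = "absent"
    return out


def cross_validate(
    cases: pd.DataFrame,
    thresholds=DEFAULT_THRESHOLDS,
    n_cycles: int = 200,
    holdout: float = 0.10,
    seed: int = 20140726,
    max_redraws: int = 1000,
) -> pd.DataFrame:
    """Repeated random holdout validation of the discriminant.

    Each cycle holds out ``holdout`` of the cases uniformly at random,
    fits on the rest, and classifies the held-out cases at every
    threshold; unclassified cases are excluded from the accuracies.  A
    cycle whose training set lacks a class is redrawn (counted, capped).

    Returns one row per threshold with mean/SD accuracy for the
    predicted-present, predicted-absent and all classified cases, plus
    the mean number of classified test cases.
    """
    rng = np.random.default_rng(seed)
    n = len(cases)
    n_test = max(1, int(round(holdout * n)))
    y_all = cases["label"].to_numpy()
    acc = {th: {"present": [], "absent": [], "overall": [], "n_classified": []} for th in thresholds}
    redraws = 0
    for _ in range(n_cycles):
        while True:
            perm = rng.permutation(n)
            test_idx, train_idx = perm[:n_test], perm[n_test:]
            if len(set(y_all[train_idx])) == 2:
                break
            redraws += 1
            if redraws > max_redraws:
                raise RuntimeError("could not draw a training set containing both classes")
        model = fit_lda(cases.iloc[train_idx])
        Xt = cases.iloc[test_idx][["abs_type", "delta_dist"]].to_numpy(dtype=float)
        yt = y_all[test_idx]
        post = model.posterior(Xt)
        for th in thresholds:
            dec = _decide(post, th)
            classified = dec != "unclassified"
            pred = np.where(dec == "present", 1, 0)
            correct = pred == yt
            acc[th]["n_classified"].append(int(classified.sum()))
            acc[th]["overall"].append(
                float(correct[classified].mean()) if classified.any() else np.nan
            )
            for name, label in (("present", "present"), ("absent", "absent")):
                mask = dec == label
                acc[th][name].append(float(correct[mask].mean()) if mask.any() else np.nan)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cycles at strict thresholds
        for th in thresholds:
            rows.append(
                {
                    "threshold": th,
                    "acc_present_mean": np.nanmean(acc[th]["present"]),
                    "acc_present_sd": np.nanstd(acc[th]["present"]),
                    "acc_absent_mean": np.nanmean(acc[th]["absent"]),
                    "acc_absent_sd": np.nanstd(acc[th]["absent"]),
                    "acc_overall_mean": np.nanmean(acc[th]["overall"]),
                    "acc_overall_sd": np.nanstd(acc[th]["overall"]),
                    "n_classified_mean": float(np.mean(acc[th]["n_classified"])),
                    "n_cycles": n_cycles,
                    "n_redraws": redraws,
                    "seed": seed,
                }
            )
    return pd.DataFrame(rows)


def predict_unknown(
    model: DiscriminantModel,
    df: pd.DataFrame,
    thresholds=DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Posterior and thresholded decisions for unexamined pairs.

    ``df`` is the analysis frame; only rows with status unknown are
    predicted.  Pairs with an undefined predictor keep a NaN posterior
    and no decision (they stay "white cells").  One decision column per
    threshold, named ``decision_<theta>``.
    """
    unknown = df[df["status"] == "unknown"].copy()
    defined = unknown["abs_type"].notna() & unknown["delta_dist"].notna()
    post = np.full(len(unknown), np.nan)
    if defined.any():
        X = unknown.loc[defined, ["abs_type", "delta_dist"]].to_numpy(dtype=float)
        post[defined.to_numpy()] = model.posterior(X)
    unknown["posterior"] = post
    for th in thresholds:
        col = np.full(len(unknown), "unpredicted", dtype=object)
        mask = defined.to_numpy()
        col[mask] = _decide(post[mask], th)
        unknown[f"decision_{th:.2f}"] = col
    return unknown


def n_decided(predictions: pd.DataFrame, theta: float) -> int:
    """Number of unexamined pairs given a present/absent call at theta."""
    col = predictions[f"decision_{theta:.2f}"]
    return int(col.isin(["present", "absent"]).sum())
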