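"""Discriminant model: grid normalization, case construction, posterior
correctness against closed-form and sklearn oracles, thresholding."""

import numpy as np
import pandas as pd
import pytest

from connectopred.lda import (
    DEFAULT_THRESHOLDS,
    build_grid,
    construct_cases,
    cross_validate,
    fit_lda,
    n_decided,
    predict_unknown,
)


def _cases_from_arrays(X, y):
    return pd.DataFrame({"abs_type": X[:, 0], "delta_dist": X[:, 1], "label": y})


def _random_model(rng):
    n = 300
    X = np.vstack(
        [
            rng.normal([1.0, 2.0], [0.8, 1.1], size=(n, 2)),
            rng.normal([2.5, 3.5], [0.8, 1.1], size=(n, 2)),
        ]
    )
    y = np.repeat([1, 0], n)
    return fit_lda(_cases_from_arrays(X, y))


class TestBuildGrid:
    def _frame(self):
        # 40 ordered pairs at (a=1, d=1): 20 present, 10 absent, 10 unknown;
        # 10 pairs at (a=0, d=2): all unknown
        rows = []
        rows += [{"abs_type": 1, "delta_dist": 1, "status": "present"}] * 20
        rows += [{"abs_type": 1, "delta_dist": 1, "status": "absent"}] * 10
        rows += [{"abs_type": 1, "delta_dist": 1, "status": "unknown"}] * 10
        rows += [{"abs_type": 0, "delta_dist": 2, "status": "unknown"}] * 10
        return pd.DataFrame(rows)

    def test_percentages_normalized_by_possible_pairs(self):
        grid = build_grid(self._frame()).set_index(["abs_type", "delta_dist"])
        cell = grid.loc[(1, 1)]
        assert cell["n_possible"] == 40
        assert cell["pct_present"] == 50.0
        assert cell["pct_absent"] == 25.0
        # %absent + %present < 100: the rest is unexamined
        assert cell["pct_absent"] + cell["pct_present"] < 100.0

    def test_unexamined_cell_has_zero_percentages(self):
        grid = build_grid(self._frame()).set_index(["abs_type", "delta_dist"])
        cell = grid.loc[(0, 2)]
        assert cell["pct_present"] == 0.0
        assert cell["pct_absent"] == 0.0


class TestConstructCases:
    def test_integer_percentages(self):
        grid = pd.DataFrame(
            {"abs_type": [1], "delta_dist": [1], "pct_absent": [25.0], "pct_present": [50.0]}
        )
        cases = construct_cases(grid)
        assert (cases["label"] == 1).sum() == 50
        assert (cases["label"] == 0).sum() == 25
        assert (cases["abs_type"] == 1).all()

    def test_round_half_up(self):
        grid = pd.DataFrame(
            {"abs_type": [2], "delta_dist": [3], "pct_absent": [2.5], "pct_present": [0.49]}
        )
        cases = construct_cases(grid)
        assert (cases["label"] == 0).sum() == 3  # 2.5 rounds up
        assert (cases["label"] == 1).sum() == 0

    def test_total_count_matches_recount_oracle(self, bundle):
        from connectopred.variables import analysis_frame, pair_variables

        frame = analysis_frame(bundle.table, pair_variables(bundle.parcellation))
        grid = build_grid(frame)
        cases = construct_cases(grid)
        expected = int(
            sum(np.floor(grid["pct_absent"] + 0.5)) + sum(np.floor(grid["pct_present"] + 0.5))
        )
        assert len(cases) == expected


class TestFitLda:
    def test_symmetric_classes_boundary_at_midpoint(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.r_[rng.normal(-1, 1, 500), rng.normal(1, 1, 500)], np.zeros(1000)])
        X[:, 1] = rng.normal(0, 1, 1000)  # uninformative second predictor
        y = np.repeat([0, 1], 500)
        model = fit_lda(_cases_from_arrays(X, y))
        assert model.posterior([[0.0, 0.0]])[0] == pytest.approx(0.5, abs=0.05)

    def test_matches_closed_form_univariate_posterior(self):
        """With a known 1-D Gaussian pair the posterior is logistic in x."""
        rng = np.random.default_rng(1)
        n = 4000
        x0 = rng.normal(0.0, 1.0, n)
        x1 = rng.normal(2.0, 1.0, n)
        X = np.column_stack([np.r_[x0, x1], rng.normal(0, 1, 2 * n)])
        y = np.repeat([0, 1], n)
        model = fit_lda(_cases_from_arrays(X, y))
        mu0, mu1 = x0.mean(), x1.mean()
        s2 = 0.5 * (x0.var(ddof=1) + x1.var(ddof=1))
        for xv in (-1.0, 0.0, 1.0, 2.0, 3.0):
            # two-Gaussian, shared-variance, uniform-prior Bayes posterior
            expected = 1.0 / (
                1.0 + np.exp(-((mu1 - mu0) / s2) * (xv - (mu0 + mu1) / 2.0))
            )
            got = model.posterior([[xv, 0.0]])[0]
            assert got == pytest.approx(expected, abs=0.02)

    def test_matches_sklearn_lda_posteriors(self):
        sklearn = pytest.importorskip("sklearn.discriminant_analysis")
        rng = np.random.default_rng(2)
        X = np.vstack(
            [rng.normal([0, 0], 1, (200, 2)), rng.normal([1.5, 1.0], 1, (200, 2))]
        )
        y = np.repeat([0, 1], 200)
        model = fit_lda(_cases_from_arrays(X, y))
        sk = sklearn.LinearDiscriminantAnalysis(priors=[0.5, 0.5]).fit(X, y)
        grid = np.array([[a, d] for a in (-1.0, 0.5, 2.0) for d in (-1.0, 0.5, 2.0)])
        np.testing.assert_allclose(
            model.posterior(grid), sk.predict_proba(grid)[:, 1], atol=1e-6
        )

    def test_standardized_coefficients_magnitudes(self):
        rng = np.random.default_rng(3)
        model = _random_model(rng)
        sd = np.sqrt(np.diag(model.pooled_covariance))
        np.testing.assert_allclose(
            model.standardized_coefficients, np.abs(model.weights) * sd
        )
        assert (model.standardized_coefficients >= 0).all()

    def test_one_empty_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        with pytest.raises(ValueError, match="both classes"):
            fit_lda(_cases_from_arrays(X, np.ones(10, dtype=int)))


class TestDecisionInvariants:
    @pytest.mark.parametrize("seed", range(20))
    def test_partition_and_threshold_monotonicity(self, seed):
        """At every threshold the decisions partition the pairs, and the
        decided count is non-increasing as the threshold rises."""
        rng = np.random.default_rng(seed)
        model = _random_model(rng)
        frame = pd.DataFrame(
            {
                "source": "s",
                "target": "t",
                "abs_type": rng.uniform(0, 4, 400),
                "delta_dist": rng.uniform(1, 6, 400),
                "status": "unknown",
            }
        )
        pred = predict_unknown(model, frame)
        counts = []
        for th in DEFAULT_THRESHOLDS:
            dec = pred[f"decision_{th:.2f}"]
            assert set(dec.unique()) <= {"present", "absent", "unclassified"}
            assert len(dec) == len(pred)
            counts.append(n_decided(pred, th))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_posterior_monotone_along_weights(self):
        rng = np.random.default_rng(7)
        model = _random_model(rng)
        assert (model.weights < 0).all()  # higher |dt| and d both disfavor presence
        base = np.array([[1.0, 2.0]])
        for j in (0, 1):
            step = np.zeros(2)
            step[j] = 1.0
            p0 = model.posterior(base)[0]
            p1 = model.posterior(base + step)[0]
            assert p1 < p0

    def test_threshold_rule(self):
        rng = np.random.default_rng(8)
        model = _random_model(rng)
        frame = pd.DataFrame(
            {
                "source": ["a"],
                "target": ["b"],
                "abs_type": [1.0],
                "delta_dist": [2.0],
                "status": ["unknown"],
            }
        )
        pred = predict_unknown(model, frame, thresholds=(0.75,))
        p = pred["posterior"].iloc[0]
        dec = pred["decision_0.75"].iloc[0]
        if p >= 0.75:
            assert dec == "present"
        elif p <= 0.25:
            assert dec == "absent"
        else:
            assert dec == "unclassified"

    def test_undefined_predictors_left_unpredicted(self):
        rng = np.random.default_rng(9)
        model = _random_model(rng)
        frame = pd.DataFrame(
            {
                "source": ["a", "c"],
                "target": ["b", "d"],
                "abs_type": [1.0, np.nan],
                "delta_dist": [2.0, 3.0],
                "status": ["unknown", "unknown"],
            }
        )
        pred = predict_unknown(model, frame, thresholds=(0.6,))
        assert np.isnan(pred["posterior"].iloc[1])
        assert pred["decision_0.60"].iloc[1] == "unpredicted"


class TestCrossValidation:
    def test_separable_cases_perfect_accuracy(self):
        rng = np.random.default_rng(0)
        X = np.vstack(
            [
                np.column_stack([rng.uniform(0, 1, 80), rng.uniform(1, 2, 80)]),
                np.column_stack([rng.uniform(3, 4, 80), rng.uniform(5, 6, 80)]),
            ]
        )
        y = np.repeat([1, 0], 80)
        cv = cross_validate(_cases_from_arrays(X, y), n_cycles=20, seed=0)
        acc = cv.loc[cv["n_classified_mean"] > 0, "acc_overall_mean"].to_numpy()
        assert len(acc) and np.allclose(acc, 1.0)

    def test_deterministic_under_seed(self, bundle):
        from connectopred.variables import analysis_frame, pair_variables

        frame = analysis_frame(bundle.table, pair_variables(bundle.parcellation))
        cases = construct_cases(build_grid(frame))
        cv1 = cross_validate(cases, n_cycles=10, seed=42)
        cv2 = cross_validate(cases, n_cycles=10, seed=42)
        pd.testing.assert_frame_equal(cv1, cv2)

    def test_classified_count_monotone_in_threshold(self, bundle):
        from connectopred.variables import analysis_frame, pair_variables

        frame = analysis_frame(bundle.table, pair_variables(bundle.parcellation))
        cases = construct_cases(build_grid(frame))
        cv = cross_validate(cases, n_cycles=25, seed=1)
        counts = cv["n_classified_mean"].to_numpy()
        assert all(a >= b - 1e-9 for a, b in zip(counts, counts[1:]))
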