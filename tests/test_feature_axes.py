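"""Firth logistic regression, feature-axis overlays, projections, and
extreme-point flagging."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from impres import (
    FeatureAxis,
    InvalidInputError,
    UnfoldingSolution,
    axis_cosine,
    firth_logistic,
    fit_categorical_axis,
    fit_continuous_axis,
    flag_extreme_points,
    project_points,
)


def make_solution(row_coords, col_coords):
    row_coords = np.atleast_2d(np.asarray(row_coords, dtype=float))
    col_coords = np.atleast_2d(np.asarray(col_coords, dtype=float))
    return UnfoldingSolution(
        row_coords=row_coords,
        col_coords=col_coords,
        ndim=row_coords.shape[1],
        stress=0.1,
        iterations=1,
        converged=True,
    )


def penalized_loglik(beta, x, y):
    """Independent definition of the Jeffreys-penalized log-likelihood."""
    eta = x @ beta
    ll = np.sum(y * eta - np.logaddexp(0.0, eta))
    p = expit(eta)
    info = (x * (p * (1 - p))[:, None]).T @ x
    sign, logdet = np.linalg.slogdet(info)
    return ll + 0.5 * logdet if sign > 0 else -np.inf


class TestFirthLogistic:
    def test_symmetry_irrelevant_dimension_gets_zero_coefficient(self):
        # labels determined by sign of coordinate 1; coordinate 2 symmetric
        coords = np.array(
            [[-1, -1], [-1, 1], [-1, -2], [-1, 2], [1, -1], [1, 1], [1, -2], [1, 2]],
            dtype=float,
        )
        y = (coords[:, 0] > 0).astype(float)
        x = np.hstack([np.ones((8, 1)), coords])
        beta = firth_logistic(x, y)
        assert np.all(np.isfinite(beta))
        assert beta[2] == pytest.approx(0.0, abs=1e-8)

    def test_balanced_labels_identical_coordinates_give_zero_slope(self):
        x = np.hstack([np.ones((6, 1)), np.full((6, 2), 0.7)])
        y = np.array([0.0, 1.0, 0.0, 1.0, 0.0, 1.0])
        beta = firth_logistic(x, y)
        assert beta[1] == pytest.approx(0.0, abs=1e-8)
        assert beta[2] == pytest.approx(0.0, abs=1e-8)

    def test_finite_under_complete_separation_battery(self, rng):
        """Plain ML diverges on every one of these; Firth stays finite."""
        for trial in range(8):
            m = int(rng.integers(6, 16))
            coords = rng.standard_normal((m, 2))
            direction = rng.standard_normal(2)
            y = (coords @ direction > 0).astype(float)  # perfectly separated
            if y.all() or not y.any():
                y[0] = 1 - y[0]
            x = np.hstack([np.ones((m, 1)), coords])
            beta = firth_logistic(x, y)
            assert np.all(np.isfinite(beta))
            assert np.linalg.norm(beta) < 50

    def test_matches_direct_penalized_likelihood_maximization(self):
        """Agreement with an independent numerical maximizer on seeded
        8-point 2-D instances."""
        for seed in range(3):
            rng = np.random.default_rng(seed)
            coords = rng.standard_normal((8, 2))
            y = (rng.random(8) < expit(coords @ [1.5, -0.7])).astype(float)
            if y.all() or not y.any():
                y[0] = 1 - y[0]
            x = np.hstack([np.ones((8, 1)), coords])
            beta = firth_logistic(x, y)
            best = None
            for s in range(5):
                r2 = np.random.default_rng(100 + s)
                res = minimize(
                    lambda b: -penalized_loglik(b, x, y),
                    r2.standard_normal(3) * 0.5,
                    method="Nelder-Mead",
                    options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
                )
                if best is None or res.fun < best.fun:
                    best = res
            assert np.allclose(beta, best.x, atol=1e-4)

    def test_rejects_nonbinary_labels(self):
        with pytest.raises(InvalidInputError):
            firth_logistic(np.ones((4, 1)), np.array([0.0, 1.0, 2.0, 1.0]))


class TestCategoricalAxis:
    def test_symmetric_configuration_gives_cardinal_direction(self):
        col = np.array(
            [[-1, -1], [-1, 1], [-1, -2], [-1, 2], [1, -1], [1, 1], [1, -2], [1, 2]],
            dtype=float,
        )
        sol = make_solution(np.zeros((3, 2)), col)
        labels = ["white" if c > 0 else "black" for c in col[:, 0]]
        axis = fit_categorical_axis(sol, labels, "race", "white")
        assert np.allclose(axis.direction, [1.0, 0.0], atol=1e-6)
        assert axis.goodness == 1.0

    def test_relabeling_flips_direction_exactly(self, rng):
        col = rng.standard_normal((12, 2))
        labels = ["a" if v > 0 else "b" for v in col @ [1.0, 0.4] + rng.normal(0, 0.5, 12)]
        sol = make_solution(np.zeros((3, 2)), col)
        ax_a = fit_categorical_axis(sol, labels, "f", "a")
        ax_b = fit_categorical_axis(sol, labels, "f", "b")
        assert np.allclose(ax_a.direction, -ax_b.direction, atol=1e-8)

    def test_random_labels_give_near_chance_goodness(self):
        accs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            col = rng.standard_normal((20, 2))
            labels = list(rng.permutation(["a"] * 10 + ["b"] * 10))
            sol = make_solution(np.zeros((3, 2)), col)
            accs.append(fit_categorical_axis(sol, labels, "f", "a").goodness)
        # a 2-D separator overfits 20 random labels somewhat, but stays far
        # below the perfect separation seen for real structure
        assert 0.45 < np.mean(accs) < 0.85

    def test_single_level_rejected(self):
        sol = make_solution(np.zeros((2, 2)), np.eye(2))
        with pytest.raises(InvalidInputError):
            fit_categorical_axis(sol, ["a", "a"], "f", "a")

    def test_equivariance_under_rotation(self, rng):
        col = rng.standard_normal((14, 2))
        labels = ["a" if v > 0 else "b" for v in col[:, 0] + 0.3 * col[:, 1]]
        sol = make_solution(rng.standard_normal((4, 2)), col)
        axis = fit_categorical_axis(sol, labels, "f", "a")
        theta = 1.1
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        sol_rot = make_solution(sol.row_coords @ rot, sol.col_coords @ rot)
        axis_rot = fit_categorical_axis(sol_rot, labels, "f", "a")
        assert axis_rot.direction @ (axis.direction @ rot) == pytest.approx(1.0, abs=1e-8)


class TestContinuousAxis:
    def test_values_equal_first_coordinate(self, rng):
        col = rng.standard_normal((10, 2))
        sol = make_solution(np.zeros((3, 2)), col)
        axis = fit_continuous_axis(sol, col[:, 0], "trust")
        assert np.allclose(axis.direction, [1.0, 0.0], atol=1e-10)
        assert axis.goodness == pytest.approx(1.0)

    def test_orthogonal_residual_values_give_zero_r2(self, rng):
        col = rng.standard_normal((12, 2))
        raw = rng.standard_normal(12)
        design = np.hstack([np.ones((12, 1)), col])
        beta, *_ = np.linalg.lstsq(design, raw, rcond=None)
        resid = raw - design @ beta
        resid = resid + 1.0  # nonconstant, orthogonal to coordinates
        sol = make_solution(np.zeros((3, 2)), col)
        axis = fit_continuous_axis(sol, resid, "noise")
        assert axis.goodness == pytest.approx(0.0, abs=1e-10)

    def test_matches_normal_equations(self, rng):
        col = rng.standard_normal((9, 2))
        vals = col @ [0.8, -0.4] + rng.normal(0, 0.3, 9)
        sol = make_solution(np.zeros((3, 2)), col)
        axis = fit_continuous_axis(sol, vals, "v")
        design = np.hstack([np.ones((9, 1)), col])
        beta = np.linalg.solve(design.T @ design, design.T @ vals)
        expected = beta[1:] / np.linalg.norm(beta[1:])
        assert np.allclose(axis.direction, expected, atol=1e-10)
        assert axis.intercept == pytest.approx(beta[0], abs=1e-10)

    def test_constant_values_rejected(self):
        sol = make_solution(np.zeros((3, 2)), np.eye(3, 2))
        with pytest.raises(InvalidInputError):
            fit_continuous_axis(sol, np.ones(3), "flat")


class TestAxisCosine:
    def test_identical_orthogonal_and_diagonal(self):
        a = FeatureAxis("f", "x", np.array([1.0, 0.0]), 0.0, "linear", 1.0)
        b = FeatureAxis("g", "y", np.array([0.0, 1.0]), 0.0, "linear", 1.0)
        c = FeatureAxis("h", "z", np.array([1.0, 1.0]), 0.0, "linear", 1.0)
        assert axis_cosine(a, a) == pytest.approx(1.0)
        assert axis_cosine(a, b) == pytest.approx(0.0)
        assert axis_cosine(c, a) == pytest.approx(np.sqrt(0.5))
        assert axis_cosine(a, c) == pytest.approx(axis_cosine(c, a))


class TestProjections:
    def test_centroid_point_scores_zero(self, rng):
        rows = rng.standard_normal((6, 2))
        rows[0] = rows[1:].sum(axis=0) / -1  # make centroid land on a known spot
        sol = make_solution(rows, rng.standard_normal((5, 2)))
        axis = FeatureAxis("f", "x", np.array([1.0, 0.0]), 0.0, "linear", 1.0)
        scores = project_points(sol, axis)
        centroid_score = (sol.row_coords.mean(axis=0) - sol.row_coords.mean(axis=0)) @ axis.direction
        assert centroid_score == 0.0
        assert scores.mean() == pytest.approx(0.0, abs=1e-12)

    def test_translation_invariance(self, rng):
        rows = rng.standard_normal((6, 2))
        cols = rng.standard_normal((5, 2))
        axis = FeatureAxis("f", "x", np.array([0.6, 0.8]), 0.0, "linear", 1.0)
        base = project_points(make_solution(rows, cols), axis)
        shifted = project_points(make_solution(rows + [5.0, -3.0], cols + [5.0, -3.0]), axis)
        assert np.allclose(base, shifted, atol=1e-12)

    def test_stimulus_projection_uses_participant_centroid(self, rng):
        rows = rng.standard_normal((6, 2)) + [2.0, 0.0]
        cols = rng.standard_normal((5, 2))
        axis = FeatureAxis("f", "x", np.array([1.0, 0.0]), 0.0, "linear", 1.0)
        scores = project_points(make_solution(rows, cols), axis, which="stimuli")
        expected = (cols - rows.mean(axis=0)) @ axis.direction
        assert np.allclose(scores, expected)


class TestExtremePoints:
    def test_tight_cluster_plus_one_outlier(self, rng):
        pts = np.vstack([rng.normal(0, 0.05, (15, 2)), [[6.0, 6.0]]])
        sol = make_solution(pts, np.zeros((2, 2)))
        assert flag_extreme_points(sol, k=3.0) == [15]

    def test_identical_points_flag_nothing(self):
        sol = make_solution(np.ones((8, 2)), np.zeros((2, 2)))
        assert flag_extreme_points(sol) == []

    def test_needs_at_least_five_points(self):
        sol = make_solution(np.zeros((4, 2)), np.zeros((2, 2)))
        with pytest.raises(InvalidInputError):
            flag_extreme_points(sol)

    def test_simulated_outlier_participants_are_flagged(self):
        """Participants with inflated attitude weights sit far outside the
        main cloud of (race, age) attitude coordinates and get flagged in
        >= 90% of seeded replicates."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            betas = rng.normal(0.0, 1.0, (40, 2))
            outlier = int(rng.integers(0, 40))
            betas[outlier] *= 4.0  # inflated attitude weights
            # ensure the multiplier actually moved the point outward
            if np.linalg.norm(betas[outlier]) < 6.0:
                betas[outlier] *= 6.0 / max(np.linalg.norm(betas[outlier]), 1e-9)
            sol = make_solution(betas, np.zeros((2, 2)))
            if outlier in flag_extreme_points(sol, k=3.0):
                hits += 1
        assert hits >= 90
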