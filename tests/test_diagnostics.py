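"""Directional-derivative optimality diagnostics, posteriors, predictions."""

import numpy as np
import pytest

from npag import (
    ControlParams,
    ErrorModel,
    MixtureEstimate,
    NPMLModel,
    directional_derivative,
    optimality_check,
    posterior_mean,
    posterior_weights,
    prediction_table,
    predictions,
    psi_matrix,
    subject_log_density,
)

from conftest import TOY_DOMAIN, TOY_MODEL, make_toy_subject

EM1 = ErrorModel("constant", gamma=1.0)


def point_mass(theta):
    return MixtureEstimate(np.array([[theta]]), np.array([1.0]), 0.0, 0, True)


class TestDirectionalDerivative:
    def test_zero_at_point_mass_self_evaluation(self):
        subjects = [make_toy_subject(0.7, "a"), make_toy_subject(0.4, "b")]
        est = point_mass(0.9)
        d = directional_derivative(np.array([0.9]), est, subjects, TOY_MODEL, EM1)
        assert d == 0.0  # each ratio is exactly 1; sum N - N

    def test_negative_far_from_data(self, toy_three_subject_fit):
        model, res, _ = toy_three_subject_fit
        d = directional_derivative(
            np.array([1.99]), res.estimate, model.subjects, TOY_MODEL,
            model.error_model,
        )
        assert d < 0

    def test_small_at_support_of_converged_fit(self, toy_noiseless_fit):
        model, res = toy_noiseless_fit
        for k in np.flatnonzero(res.weights > 1e-6):
            d = directional_derivative(
                res.support_points[k], res.estimate, model.subjects,
                TOY_MODEL, model.error_model,
            )
            assert abs(d) <= 1e-6


class TestOptimalityCheck:
    def test_converged_toy_fit_has_tiny_gap(self, toy_noiseless_fit):
        model, res = toy_noiseless_fit
        report = optimality_check(
            res.estimate, model.subjects, TOY_MODEL, model.error_model,
            TOY_DOMAIN, n_starts=20, seed=1,
        )
        # dense-scan oracle agrees: best D over a fine grid is tiny too
        scan = np.linspace(0.05, 2.0, 5001)
        dvals = [
            directional_derivative(np.array([t]), res.estimate,
                                   model.subjects, TOY_MODEL, model.error_model)
            for t in scan
        ]
        assert max(dvals) <= report.d_max + 1e-3
        assert report.d_max <= 1e-3
        assert report.loglik_gap_bound == max(report.d_max, 0.0)

    def test_truncated_fit_reports_positive_gap(self):
        subjects = [make_toy_subject(th, f"s{i}", noise_sd=0.05,
                                     sigma=0.05, rng=np.random.default_rng(i))
                    for i, th in enumerate((0.3, 1.4))]
        model = NPMLModel(subjects, TOY_DOMAIN, TOY_MODEL,
                          ErrorModel("constant", gamma=0.05))
        # deliberately stop after one cycle from a coarse start
        res = model.fit(5, controls=ControlParams(max_cycles=1))
        report = optimality_check(
            res.estimate, subjects, TOY_MODEL, model.error_model,
            TOY_DOMAIN, n_starts=10, seed=0,
        )
        assert report.d_max > 0
        assert report.loglik_gap_bound > 0

    def test_zero_starts_evaluates_support_only(self, toy_noiseless_fit):
        model, res = toy_noiseless_fit
        report = optimality_check(
            res.estimate, model.subjects, TOY_MODEL, model.error_model,
            TOY_DOMAIN, n_starts=0,
        )
        d_sup = max(
            directional_derivative(p, res.estimate, model.subjects,
                                   TOY_MODEL, model.error_model)
            for p in res.support_points
        )
        assert report.d_max == d_sup
        assert report.n_starts == 0


class TestPosteriors:
    def test_single_support_point_posterior_is_one(self):
        s = make_toy_subject(0.7)
        est = point_mass(0.6)
        np.testing.assert_array_equal(
            posterior_weights(s, est, TOY_MODEL, EM1), [1.0]
        )

    def test_two_point_flat_prior_follows_likelihood_ratio(self):
        s = make_toy_subject(0.7)
        grid = np.array([[0.6], [0.8]])
        est = MixtureEstimate(grid, np.array([0.5, 0.5]), 0.0, 0, True)
        l1 = np.exp(subject_log_density(s, grid[0], TOY_MODEL, EM1))
        l2 = np.exp(subject_log_density(s, grid[1], TOY_MODEL, EM1))
        w = posterior_weights(s, est, TOY_MODEL, EM1)
        np.testing.assert_allclose(w, [l1 / (l1 + l2), l2 / (l1 + l2)],
                                   atol=1e-12)

    def test_matches_normalized_product_oracle(self, toy_three_subject_fit):
        model, res, _ = toy_three_subject_fit
        s = model.subjects[1]
        w = posterior_weights(s, res.estimate, TOY_MODEL, model.error_model)
        raw = np.array([
            lam * np.exp(subject_log_density(s, phi, TOY_MODEL, model.error_model))
            for lam, phi in zip(res.weights, res.support_points)
        ])
        np.testing.assert_allclose(w, raw / raw.sum(), atol=1e-12)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_posterior_mean_inside_support_hull(self, toy_three_subject_fit):
        model, res, _ = toy_three_subject_fit
        for s in model.subjects:
            m = posterior_mean(s, res.estimate, TOY_MODEL, model.error_model)
            assert res.support_points.min() - 1e-12 <= m[0]
            assert m[0] <= res.support_points.max() + 1e-12


class TestPredictions:
    def test_single_point_modes_coincide(self):
        s = make_toy_subject(0.7)
        est = point_mass(0.6)
        pop = predictions(s, est, TOY_MODEL, "population")
        bay = predictions(s, est, TOY_MODEL, "bayesian", EM1)
        np.testing.assert_allclose(pop, bay, atol=1e-12)

    def test_population_mode_is_weighted_average(self, toy_three_subject_fit):
        model, res, _ = toy_three_subject_fit
        s = model.subjects[0]
        pop = predictions(s, res.estimate, TOY_MODEL, "population")
        obs_points = [(o.time, 0) for o in s.observations]
        manual = sum(
            lam * TOY_MODEL.predict(phi[None, :], [], obs_points)[0]
            for lam, phi in zip(res.weights, res.support_points)
        )
        np.testing.assert_allclose(pop, manual, atol=1e-12)

    def test_noiseless_fit_reproduces_observations(self, toy_noiseless_fit):
        model, res = toy_noiseless_fit
        s = model.subjects[0]
        bay = predictions(s, res.estimate, TOY_MODEL, "bayesian",
                          model.error_model)
        obs = np.array([o.value for o in s.observations])
        np.testing.assert_allclose(bay, obs, rtol=1e-3)

    def test_prediction_table_layout(self, toy_three_subject_fit):
        model, res, _ = toy_three_subject_fit
        tab = prediction_table(model.subjects, res.estimate, TOY_MODEL,
                               model.error_model)
        assert len(tab) == sum(s.n_obs for s in model.subjects)
        assert set(tab.columns) == {
            "id", "time", "output", "observed", "pred_population",
            "pred_bayesian",
        }
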