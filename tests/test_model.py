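import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize

from rsmkit import (
    category_probabilities,
    expected_score,
    fit_rsm,
    log_likelihood,
    score_variance,
)
from rsmkit.errors import DegenerateDataError
from rsmkit.model import RatingScaleModel, _solve_theta
from rsmkit.simulate import SimulationConfig, evenly_spaced_betas, simulate_responses

from conftest import make_matrix

finite = st.floats(-5, 5, allow_nan=False)


class TestCategoryProbabilities:
    def test_full_symmetry_is_uniform(self):
        p = category_probabilities(0.7, 0.7, np.zeros(4))
        assert np.allclose(p, 0.2)

    def test_dichotomous_midpoint(self):
        p = category_probabilities(0.0, 0.0, [0.0])
        assert np.allclose(p, [0.5, 0.5])

    def test_dichotomous_logistic_closed_form(self):
        p = category_probabilities(1.0, 0.0, [0.0])
        assert p[1] == pytest.approx(np.e / (1 + np.e), abs=1e-6)
        assert p[1] == pytest.approx(0.73106, abs=1e-5)

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError):
            category_probabilities(np.inf, 0.0, [0.0])

    @given(theta=finite, beta=finite, tau=st.lists(finite, min_size=1, max_size=6))
    @settings(max_examples=200, deadline=None)
    def test_normalization_and_nonnegativity(self, theta, beta, tau):
        p = category_probabilities(theta, beta, tau)
        assert np.all(p >= 0)
        assert abs(p.sum() - 1) < 1e-12

    @given(theta=finite, beta=finite, shift=finite,
           tau=st.lists(finite, min_size=1, max_size=6))
    @settings(max_examples=200, deadline=None)
    def test_translation_invariance(self, theta, beta, shift, tau):
        p1 = category_probabilities(theta, beta, tau)
        p2 = category_probabilities(theta + shift, beta + shift, tau)
        assert np.allclose(p1, p2, atol=1e-10)

    def test_overflow_safe_at_large_logits(self):
        p = category_probabilities(300.0, -300.0, np.zeros(4))
        assert np.isfinite(p).all() and p[-1] == pytest.approx(1.0)


class TestExpectedScoreAndVariance:
    def test_symmetric_case_gives_half_range(self):
        assert expected_score(1.3, 1.3, np.zeros(4)) == pytest.approx(2.0)

    def test_low_trait_limit(self):
        assert expected_score(-30.0, 0.0, np.zeros(4)) == pytest.approx(0.0, abs=1e-9)
        assert score_variance(-30.0, 0.0, np.zeros(4)) == pytest.approx(0.0, abs=1e-9)

    def test_dichotomous_matches_probability(self):
        e = expected_score(1.0, 0.0, [0.0])
        assert e == pytest.approx(0.73106, abs=1e-5)

    def test_bernoulli_variance(self):
        assert score_variance(0.0, 0.0, [0.0]) == pytest.approx(0.25)

    def test_uniform_category_variance(self):
        # theta=beta, tau=0: X uniform on {0..4}, variance 2
        assert score_variance(0.0, 0.0, np.zeros(4)) == pytest.approx(2.0)

    @given(beta=finite, tau=st.lists(finite, min_size=1, max_size=5))
    @settings(max_examples=100, deadline=None)
    def test_expected_score_increasing_in_theta(self, beta, tau):
        grid = np.linspace(-6, 6, 25)
        e = expected_score(grid, beta, tau)
        assert np.all(np.diff(e) > 0)


class TestLogLikelihood:
    def test_single_response_equals_log_category_probability(self):
        rm = make_matrix([[2]], n_categories=5)
        ll = log_likelihood(rm, [0.0], [0.0], np.zeros(4))
        assert ll == pytest.approx(np.log(0.2))

    def test_person_permutation_invariance(self):
        rm = make_matrix([[0, 3], [2, None], [4, 1]])
        perm = make_matrix([[4, 1], [0, 3], [2, None]])
        theta = np.array([0.5, -0.2, 1.0])
        beta = np.array([0.3, -0.3])
        tau = np.zeros(4)
        assert log_likelihood(rm, theta, beta, tau) == pytest.approx(
            log_likelihood(perm, theta[[2, 0, 1]], beta, tau)
        )


@pytest.mark.filterwarnings("ignore::UserWarning")
class TestJMLE:
    def test_identification_constraints_hold(self, recovery_fit):
        assert recovery_fit.beta_.mean() == pytest.approx(0.0, abs=1e-10)
        assert recovery_fit.tau_.sum() == pytest.approx(0.0, abs=1e-10)

    def test_converged_flag_and_tolerance(self, recovery_fit):
        assert recovery_fit.converged_
        assert recovery_fit.max_last_change_ < recovery_fit.tol

    def test_loglik_non_decreasing_over_accepted_cycles(self, recovery_fit):
        assert np.all(np.diff(recovery_fit.loglik_path_) >= -1e-6)

    def test_parameter_recovery(self, recovery_study, recovery_fit_corrected):
        rm, truth = recovery_study
        fit = recovery_fit_corrected
        assert np.corrcoef(fit.beta_, truth.beta)[0, 1] >= 0.98
        assert np.sqrt(np.mean((fit.beta_ - truth.beta) ** 2)) <= 0.15
        ok = ~fit.extreme_persons_
        assert np.corrcoef(fit.theta_[ok], truth.theta[ok])[0, 1] > 0.85

    def test_standard_errors_positive_for_non_extreme(self, recovery_fit):
        assert np.all(recovery_fit.se_beta_ > 0)
        assert np.all(recovery_fit.se_theta_[~recovery_fit.extreme_persons_] > 0)

    def test_bias_shrinks_with_sample_size(self):
        # mean absolute item bias decreases from n=100 to n=500
        biases = {}
        for n in (100, 500):
            cfg = SimulationConfig(
                n_persons=n, item_betas=tuple(evenly_spaced_betas(8)), seed=9
            )
            rm, truth = simulate_responses(cfg)
            fit = fit_rsm(rm, bias_correction=True)
            biases[n] = np.mean(np.abs(fit.beta_ - truth.beta))
        assert biases[500] < biases[100]

    def test_grid_oracle_on_two_by_two_toy(self):
        # 2 persons x 2 items, 3 categories, all categories observed;
        # oracle = direct maximization of the joint likelihood over the
        # 4 free parameters (theta1, theta2, beta1=-beta2, tau1=-tau2)
        rm = make_matrix([[0, 1], [2, 0]], n_categories=3)

        def negll(p):
            t1, t2, b1, ta1 = p
            return -log_likelihood(
                rm, np.array([t1, t2]), np.array([b1, -b1]), np.array([ta1, -ta1])
            )

        oracle = optimize.minimize(
            negll, [0.1, 0.2, 0.1, 0.1], method="Nelder-Mead",
            options=dict(xatol=1e-10, fatol=1e-13, maxiter=50000, maxfev=50000),
        )
        t1, t2, b1, ta1 = oracle.x
        fit = fit_rsm(rm, tol=1e-6, max_iter=2000)
        assert fit.theta_ == pytest.approx([t1, t2], abs=0.01)
        assert fit.beta_ == pytest.approx([b1, -b1], abs=0.01)
        assert fit.tau_ == pytest.approx([ta1, -ta1], abs=0.01)

    def test_dichotomous_reduction_matches_logistic_regression_oracle(self):
        # With K=1 the RSM is the dichotomous Rasch model, whose JMLE is a
        # logistic regression on person and item indicator contrasts.
        import statsmodels.api as sm

        cfg = SimulationConfig(
            n_persons=60,
            item_betas=tuple(evenly_spaced_betas(6, 1.0)),
            taus=(0.0,),
            n_categories=2,
            seed=3,
        )
        rm, _ = simulate_responses(cfg)
        fit = fit_rsm(rm, tol=1e-7, max_iter=1000)
        keep = ~fit.extreme_persons_
        n, m = rm.n_persons, rm.n_items
        rows, y = [], []
        for p in range(n):
            if not keep[p]:
                continue
            for i in range(m):
                y.append(rm.responses[p, i])
                r = np.zeros(n + m)
                r[p] = 1
                r[n + i] = -1
                rows.append(r)
        X = np.array(rows)
        # identification: last item as reference, kept persons free
        Xr = np.hstack([X[:, :n][:, keep], X[:, n : n + m - 1]])
        glm = sm.GLM(np.array(y), Xr, family=sm.families.Binomial()).fit()
        nk = int(keep.sum())
        beta_g = np.concatenate([glm.params[nk:], [0.0]])
        theta_g = glm.params[:nk]
        c = beta_g.mean()
        beta_g, theta_g = beta_g - c, theta_g - c
        assert fit.beta_ == pytest.approx(beta_g, abs=1e-3)
        assert fit.theta_[keep] == pytest.approx(theta_g, abs=1e-3)

    def test_missing_at_random_leaves_items_within_two_se(self, recovery_study):
        rm, _ = recovery_study
        full_fit = fit_rsm(rm)
        scores = rm.responses.copy()
        rng = np.random.default_rng(4)
        scores[rng.random(scores.shape) < 0.10] = np.nan
        sparse = make_matrix(scores, person_ids=rm.person_ids, item_ids=rm.item_ids)
        sparse_fit = fit_rsm(sparse)
        delta = np.abs(sparse_fit.beta_ - full_fit.beta_)
        assert np.all(delta < 2 * np.hypot(full_fit.se_beta_, sparse_fit.se_beta_))

    def test_extreme_person_flagged_with_finite_adjusted_measure(self):
        rows = [[4] * 6] + [[0, 1, 2, 3, 2, 1], [1, 2, 0, 1, 3, 2],
                            [2, 3, 1, 0, 2, 4], [3, 1, 2, 2, 0, 1]] * 5
        rm = make_matrix(rows)
        fit = fit_rsm(rm)
        assert fit.extreme_persons_[0]
        assert np.isfinite(fit.theta_[0])
        assert fit.theta_[0] > fit.theta_[1:].max()

    def test_interior_constant_item_dropped_with_warning(self):
        rng = np.random.default_rng(0)
        scores = rng.integers(0, 5, (40, 5)).astype(float)
        scores[:, 2] = 2.0
        rm = make_matrix(scores)
        with pytest.warns(UserWarning, match="uninformative"):
            fit = fit_rsm(rm)
        assert "i2" in fit.dropped_items_
        assert fit.n_items_ == 4

    def test_non_convergence_warns_and_is_flagged(self, recovery_study):
        rm, _ = recovery_study
        with pytest.warns(UserWarning, match="did not converge"):
            fit = fit_rsm(rm, max_iter=2)
        assert not fit.converged_

    def test_too_small_matrix_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            fit_rsm(make_matrix([[1, 2], [2, None]]))

    def test_anchored_scoring_agrees_with_joint_estimates(self, recovery_study,
                                                          recovery_fit):
        rm, _ = recovery_study
        theta, se = recovery_fit.score_persons(rm)
        ok = ~recovery_fit.extreme_persons_
        # anchored scoring re-derives measures from the same item anchors
        assert np.allclose(theta[ok], recovery_fit.theta_[ok], atol=0.02)
        assert np.all(se[ok] > 0)

    def test_sklearn_param_interface(self):
        model = RatingScaleModel(tol=1e-4)
        assert model.get_params()["tol"] == 1e-4
        model.set_params(max_iter=50)
        assert model.max_iter == 50


class TestThetaSolver:
    @pytest.mark.parametrize("target", [0.5, 3.0, 10.0, 19.5])
    def test_expected_score_matches_target(self, target):
        betas = evenly_spaced_betas(5)
        tau = np.array([-1.5, -0.5, 0.5, 1.5])
        theta = _solve_theta(target, betas, tau)
        assert expected_score(theta, betas, tau).sum() == pytest.approx(
            target, abs=1e-6
        )
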