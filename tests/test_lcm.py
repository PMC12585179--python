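"""The latent cause model: operations, invariants, and the fast kernel."""

import math

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import norm

from latentcause import ParamSet, simulate_paradigm
from latentcause import _kernel
from latentcause.lcm import (
    ModelState,
    cause_prior,
    e_step,
    emit_cr,
    feature_likelihood,
    m_step,
    outcome_likelihood,
    predict_outcome,
    simulate_trial,
    temporal_kernel,
)

from conftest import random_paramsets


def _params(**kw):
    base = dict(alpha=1.0, g=0.5, eta=0.5, max_em_iter=3, w0=0.0,
                sigma_r2=1.0, sigma_x2=1.0, theta=0.03, lam=0.02, K=10)
    base.update(kw)
    return ParamSet(**base)


class TestParamSet:
    def test_vector_round_trip(self):
        p = _params()
        assert ParamSet.from_vector(p.to_vector()) == p

    def test_integer_params_ceiled_from_vector(self):
        vec = _params().to_vector()
        vec[3] = 1.2  # max_em_iter
        vec[9] = 5.7  # K
        p = ParamSet.from_vector(vec)
        assert (p.max_em_iter, p.K) == (2, 6)

    @pytest.mark.parametrize("kw", [
        dict(alpha=0.0), dict(g=-0.1), dict(eta=0.0), dict(eta=1.5),
        dict(max_em_iter=0), dict(sigma_r2=0.0), dict(lam=0.0), dict(K=0),
    ])
    def test_invalid_rejected(self, kw):
        with pytest.raises(ValueError):
            _params(**kw)


class TestTemporalKernel:
    def test_unit_delta_and_zero_g(self):
        assert temporal_kernel(1.0, 2.0) == 1.0
        assert temporal_kernel(123.4, 0.0) == 1.0

    def test_known_value(self):
        assert temporal_kernel(20.0, 0.316) == pytest.approx(0.3881, abs=1e-3)

    def test_strictly_decreasing_for_positive_g(self):
        deltas = np.linspace(1.0, 50.0, 40)
        vals = temporal_kernel(deltas, 0.7)
        assert (np.diff(vals) < 0).all()

    def test_nonpositive_delta_rejected(self):
        with pytest.raises(ValueError):
            temporal_kernel(0.0, 1.0)


class TestCausePrior:
    def test_empty_state_all_mass_on_new(self):
        prior = cause_prior(ModelState(K=5), 1.0, _params())
        np.testing.assert_array_equal(prior, [1.0])

    def test_single_past_trial_unit_alpha(self):
        state = ModelState(K=5, n_active=1, assignments=[0], assign_times=[0.0])
        prior = cause_prior(state, 1.0, _params(alpha=1.0, g=0.7))
        np.testing.assert_allclose(prior, [0.5, 0.5])

    def test_g_zero_equals_count_crp(self):
        # independent count-based CRP oracle at g = 0
        state = ModelState(K=5, n_active=1, assignments=[0, 0],
                           assign_times=[0.0, 1.0])
        prior = cause_prior(state, 5.0, _params(alpha=2.0, g=0.0))
        np.testing.assert_allclose(prior, [0.5, 0.5])

    def test_g_zero_count_oracle_random_histories(self):
        rng = np.random.default_rng(3)
        p = _params(alpha=1.7, g=0.0, K=6)
        for _ in range(20):
            n_past = int(rng.integers(1, 12))
            assignments = sorted(rng.integers(0, 3, size=n_past).tolist())
            # relabel to make assignment indices contiguous from 0
            labels = {z: i for i, z in enumerate(dict.fromkeys(assignments))}
            assignments = [labels[z] for z in assignments]
            n_active = max(assignments) + 1
            state = ModelState(K=6, n_active=n_active, assignments=assignments,
                               assign_times=list(range(n_past)))
            prior = cause_prior(state, float(n_past), p)
            counts = np.bincount(assignments, minlength=n_active).astype(float)
            oracle = np.append(counts, p.alpha)
            oracle /= oracle.sum()
            np.testing.assert_allclose(prior, oracle, atol=1e-14)

    def test_no_new_slot_at_capacity(self):
        state = ModelState(K=1, n_active=1, assignments=[0], assign_times=[0.0])
        prior = cause_prior(state, 1.0, _params(K=1))
        np.testing.assert_array_equal(prior, [1.0])


class TestLikelihoods:
    def test_matched_cause_peak_density(self):
        x = np.array([1.0, 0.2])
        state = ModelState(K=3, n_active=1, assignments=[0], assign_times=[0.0],
                           feature_sums=np.array([[2.0, 0.4], [0, 0], [0, 0.0]]),
                           feature_counts=np.array([2, 0, 0]))
        dens = feature_likelihood(x, state, _params(sigma_x2=1.0))
        assert dens[0] == pytest.approx(1 / (2 * math.pi), rel=1e-12)

    def test_new_slot_mean_zero(self):
        dens = feature_likelihood(np.array([1.0, 0.2]), ModelState(K=3), _params())
        expected = norm.pdf(1.0) * norm.pdf(0.2)
        assert dens[0] == pytest.approx(expected, rel=1e-12)
        assert dens[0] == pytest.approx(0.0946, abs=2e-4)

    def test_symmetric_causes_equal_density(self):
        x = np.array([0.5, 0.0])
        state = ModelState(K=3, n_active=2, assignments=[0, 1], assign_times=[0, 1],
                           feature_sums=np.array([[0.0, 0.0], [1.0, 0.0], [0, 0.0]]),
                           feature_counts=np.array([1, 1, 0]))
        dens = feature_likelihood(x, state, _params(), include_new=False)
        assert dens[0] == pytest.approx(dens[1], rel=1e-12)

    def test_outcome_peak_and_monotone_decay(self):
        p = _params(sigma_r2=1.0)
        w = np.array([[1.0, 0.0]])
        x = np.array([1.0, 0.2])
        assert outcome_likelihood(1.0, x, w, p) == pytest.approx(1 / math.sqrt(2 * math.pi))
        assert outcome_likelihood(0.0, np.array([0.0, 0.0]), np.zeros((1, 2)), p) \
            == pytest.approx(1 / math.sqrt(2 * math.pi))
        devs = [outcome_likelihood(1.0 + d, x, w, p) for d in (0.0, 0.5, 1.0, 2.0)]
        assert (np.diff(devs) < 0).all()


class TestEStep:
    def test_hand_bayes_two_causes(self):
        post = e_step(np.array([0.5, 0.5]), np.array([3.0, 1.0]))
        np.testing.assert_allclose(post, [0.75, 0.25])

    def test_degenerate_prior_passthrough(self):
        post = e_step(np.array([1.0, 0.0]), np.array([0.1, 99.0]))
        np.testing.assert_allclose(post, [1.0, 0.0])

    def test_equal_likelihoods_return_prior(self):
        prior = np.array([0.2, 0.3, 0.5])
        np.testing.assert_allclose(e_step(prior, np.full(3, 0.7)), prior)

    def test_all_zero_mass_is_error(self):
        with pytest.raises(ValueError):
            e_step(np.array([0.5, 0.5]), np.array([0.0, 0.0]))


class TestMStepPredict:
    def test_single_update_step(self):
        p = _params(eta=0.5)
        w = m_step(np.array([1.0]), np.array([1.0, 0.2]), 1.0,
                   np.zeros((1, 2)), p)
        np.testing.assert_allclose(w, [[0.5, 0.1]])

    def test_zero_prediction_error_fixed_point(self):
        p = _params(eta=1.0)
        w0 = np.array([[0.8, 1.0]])
        x = np.array([1.0, 0.2])
        r = float((w0 @ x)[0])
        np.testing.assert_array_equal(m_step(np.array([1.0]), x, r, w0, p), w0)

    def test_zero_posterior_leaves_weights(self):
        p = _params()
        w0 = np.array([[0.3, 0.3]])
        np.testing.assert_array_equal(
            m_step(np.array([0.0]), np.array([1.0, 0.2]), 1.0, w0, p), w0
        )

    def test_predict_outcome_mixture(self):
        x = np.array([1.0, 0.2])
        assert predict_outcome(np.array([1.0]), np.array([[1.0, 0.0]]), x) == 1.0
        assert predict_outcome(np.array([0.5, 0.5]),
                               np.array([[1.0, 0.0], [0.0, 0.0]]), x) == 0.5
        assert predict_outcome(np.array([0.5, 0.5]), np.zeros((2, 2)), x) == 0.0


class TestEmitCR:
    def test_at_threshold_half(self):
        assert emit_cr(0.03, _params(theta=0.03)) == pytest.approx(0.5)

    def test_known_tail_value(self):
        assert emit_cr(0.0, _params(theta=0.03, lam=0.02)) == pytest.approx(0.416, abs=1e-3)

    def test_agrees_with_numerical_integration(self):
        p = _params(theta=0.03, lam=0.02)
        for er in (-0.2, 0.0, 0.03, 0.1, 0.9):
            numeric, _ = integrate.quad(
                lambda v: norm.pdf(v, loc=er, scale=math.sqrt(p.lam)), p.theta, np.inf
            )
            assert emit_cr(er, p) == pytest.approx(numeric, abs=1e-8)

    def test_strictly_increasing_in_expected_shock(self):
        p = _params()
        # strictly increasing wherever the Gaussian tail is not saturated
        vals = [emit_cr(er, p) for er in np.linspace(-0.5, 0.6, 50)]
        assert (np.diff(vals) > 0).all()
        assert emit_cr(5.0, p) == 1.0  # saturates far above threshold

    def test_small_lambda_limit(self):
        assert emit_cr(0.5, _params(theta=0.03, lam=1e-10)) == pytest.approx(1.0)


class TestSimulateTrial:
    def test_first_trial_closed_form_cr(self, schedule):
        p = _params(w0=0.0, theta=0.03, lam=0.02)
        state = ModelState(K=p.K)
        cr, info = simulate_trial(state, 0.0, np.array([1.0, 0.2]), 1.0, p)
        assert cr == pytest.approx(1 - norm.cdf(0.03 / math.sqrt(0.02)), abs=1e-12)
        assert info["instantiated"] and state.n_active == 1

    def test_no_new_slot_when_at_capacity(self):
        p = _params(K=1)
        state = ModelState(K=1)
        simulate_trial(state, 0.0, np.array([1.0, 0.2]), 1.0, p)
        _, info = simulate_trial(state, 1.0, np.array([1.0, 0.2]), 0.0, p)
        assert len(info["posterior"]) == 1

    def test_deterministic(self):
        p = _params()
        out = []
        for _ in range(2):
            state = ModelState(K=p.K)
            cr1, _ = simulate_trial(state, 0.0, np.array([1.0, 0.2]), 1.0, p)
            cr2, _ = simulate_trial(state, 1.0, np.array([1.0, 0.2]), 1.0, p)
            out.append((cr1, cr2))
        assert out[0] == out[1]


class TestSimulateParadigm:
    def test_posteriors_normalized_and_map_consistent(self, schedule):
        for p in random_paramsets(30, seed=1):
            res = simulate_paradigm(p, schedule)
            np.testing.assert_allclose(res.posterior.sum(axis=1), 1.0, atol=1e-12)
            np.testing.assert_allclose(res.posterior_stim.sum(axis=1), 1.0, atol=1e-12)
            np.testing.assert_array_equal(
                res.map_assignment, np.argmax(res.posterior, axis=1)
            )

    def test_cause_count_monotone_and_capped(self, schedule, fig_params):
        for p in random_paramsets(20, seed=2):
            res = simulate_paradigm(p, schedule)
            assert res.n_causes <= p.K
            seen = set()
            prev = 0
            for z in res.map_assignment:
                seen.add(int(z))
                assert len(seen) >= prev
                prev = len(seen)
        res = simulate_paradigm(fig_params["12mo_control"], schedule)
        assert res.n_causes <= 4  # K = 4 caps the cause count

    def test_tiny_alpha_single_acquisition_cause(self, schedule):
        p = _params(alpha=1e-6, g=0.0)
        res = simulate_paradigm(p, schedule)
        assert set(res.map_assignment[:3].tolist()) == {0}

    def test_reinstatement_in_12mo_control(self, schedule, fig_params):
        cr = simulate_paradigm(fig_params["12mo_control"], schedule).cr.values
        assert cr[35] > cr[33]  # test 3 above test 2 after the unsignaled shock

    def test_bit_reproducible(self, schedule, fig_params):
        a = simulate_paradigm(fig_params["wildtype_2mo"], schedule)
        b = simulate_paradigm(fig_params["wildtype_2mo"], schedule)
        np.testing.assert_array_equal(a.cr.values, b.cr.values)
        np.testing.assert_array_equal(a.posterior, b.posterior)

    def test_export_frame_shape(self, schedule, fig_params):
        res = simulate_paradigm(fig_params["wildtype_2mo"], schedule)
        frame = res.to_frame()
        assert len(frame) == 36
        assert {"trial", "cr", "map_cause", "posterior_new"} <= set(frame.columns)


class TestKernelAgreement:
    """The compiled kernel is a second, independent route to the same CR trace."""

    def test_kernel_matches_reference_on_random_paramsets(self, schedule):
        arrays = _kernel.schedule_arrays(schedule)
        for p in random_paramsets(60, seed=11):
            ref = simulate_paradigm(p, schedule).cr.values
            fast = _kernel.simulate_cr(p.to_vector(), *arrays)
            np.testing.assert_allclose(fast, ref, atol=1e-10)

    def test_kernel_handles_continuous_integer_relaxation(self, schedule):
        arrays = _kernel.schedule_arrays(schedule)
        vec = ParamSet(1.5, 0.3, 0.5, 4, 0.0, 1.0, 1.0, 0.03, 0.02, 7).to_vector()
        relaxed = vec.copy()
        relaxed[3] = 3.2  # ceil -> 4
        relaxed[9] = 6.01  # ceil -> 7
        np.testing.assert_array_equal(
            _kernel.simulate_cr(relaxed, *arrays), _kernel.simulate_cr(vec, *arrays)
        )
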