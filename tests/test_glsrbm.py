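"""RBM conditionals, CD gradients, penalty parameter gradients, pretraining."""

import numpy as np
import pytest

from glsdbn.glsrbm import (
    RBMParams,
    TrainConfig,
    cd_gradients,
    hidden_probabilities,
    penalty_param_grads,
    train_glsrbm,
    visible_probabilities,
)
from glsdbn.metrics import mean_activation_sparseness
from glsdbn.penalties import PenaltyConfig, build_groups, penalty_value


def _params(rng, nv=6, nh=8, scale=0.5):
    return RBMParams.initialize(nv, nh, rng, scale)


class TestConditionals:
    def test_zero_parameters_give_half(self):
        p = RBMParams(np.zeros((4, 3)), np.zeros(4), np.zeros(3))
        V = np.random.default_rng(0).uniform(size=(5, 4))
        assert np.allclose(hidden_probabilities(V, p), 0.5)
        H = np.random.default_rng(1).uniform(size=(5, 3))
        assert np.allclose(visible_probabilities(H, p), 0.5)

    def test_bias_saturation(self):
        b = np.array([30.0, -30.0])
        p = RBMParams(np.zeros((2, 2)), np.array([-30.0, 0.0]), b)
        P = hidden_probabilities(np.zeros((1, 2)), p)
        assert P[0, 0] > 1 - 1e-12 and P[0, 1] < 1e-12
        Q = visible_probabilities(np.zeros((1, 2)), p)
        assert Q[0, 0] < 1e-12

    def test_logistic_closed_form(self):
        # v . W[:, 0] = ln 3 with zero bias -> sigmoid(ln 3) = 0.75
        W = np.array([[np.log(3.0)]])
        p = RBMParams(W, np.zeros(1), np.zeros(1))
        assert hidden_probabilities(np.ones((1, 1)), p)[0, 0] == pytest.approx(0.75)

    def test_transpose_symmetry(self, rng):
        p = _params(rng)
        pt = RBMParams(p.W.T.copy(), p.b.copy(), p.a.copy())
        H = rng.uniform(size=(3, p.n_hidden))
        assert np.allclose(
            visible_probabilities(H, p), hidden_probabilities(H, pt)
        )

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            hidden_probabilities(np.zeros((2, 5)), _params(rng, nv=6))


class TestCDGradients:
    def test_zero_data_zero_params_data_term(self, rng):
        p = RBMParams(np.zeros((4, 3)), np.zeros(4), np.zeros(3))
        dW, da, db = cd_gradients(np.zeros((5, 4)), p, rng=rng)
        # data term <v p> is exactly zero; only the reconstruction term remains
        assert dW.shape == (4, 3) and da.shape == (4,) and db.shape == (3,)

    def test_gradient_step_reduces_reconstruction_error(self):
        """One CD step on a repeated binary pattern should not hurt, averaged
        over seeds."""
        pattern = np.array([1.0, 0.0, 1.0, 1.0, 0.0, 0.0])
        V = np.tile(pattern, (10, 1))
        deltas = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            p = RBMParams.initialize(6, 4, rng, 0.1)

            def recon_err(par, r):
                P = hidden_probabilities(V, par)
                H = (r.random(P.shape) < P).astype(float)
                return ((visible_probabilities(H, par) - V) ** 2).mean()

            before = recon_err(p, np.random.default_rng(100 + seed))
            dW, da, db = cd_gradients(V, p, rng=rng)
            p.W -= 0.1 * dW
            p.a -= 0.1 * da
            p.b -= 0.1 * db
            after = recon_err(p, np.random.default_rng(100 + seed))
            deltas.append(after - before)
        assert np.mean(deltas) <= 0


class TestPenaltyParamGrads:
    def test_matches_finite_differences(self, rng):
        """Permanent oracle: exact chain rule through the sigmoid conditional."""
        worst = 0.0
        for t in range(6):
            nv, nh, m = 6, 8, 4
            gs = build_groups(nh, 2, 0.25, "relaxed")
            cfg = PenaltyConfig(
                lam=1.0, phi=1.0, gamma=1.0, mu=0.025, cauchy_sign=-1 if t % 2 else 1
            )
            params = _params(rng, nv, nh)
            V = rng.uniform(size=(m, nv))
            dW, db = penalty_param_grads(V, params, cfg, gs)

            def f(par):
                return penalty_value(hidden_probabilities(V, par), cfg, gs)

            eps = 1e-6
            for i in range(nv):
                for j in range(nh):
                    p1, p2 = params.copy(), params.copy()
                    p1.W[i, j] += eps
                    p2.W[i, j] -= eps
                    worst = max(worst, abs(dW[i, j] - (f(p1) - f(p2)) / (2 * eps)))
            for j in range(nh):
                p1, p2 = params.copy(), params.copy()
                p1.b[j] += eps
                p2.b[j] -= eps
                worst = max(worst, abs(db[j] - (f(p1) - f(p2)) / (2 * eps)))
        assert worst < 1e-5

    def test_zero_weights_give_zero_gradients(self, rng):
        gs = build_groups(8, 2, 0.25, "relaxed")
        cfg = PenaltyConfig(lam=0.0, phi=0.0)
        dW, db = penalty_param_grads(rng.uniform(size=(3, 6)), _params(rng), cfg, gs)
        assert np.allclose(dW, 0) and np.allclose(db, 0)

    def test_factored_form_differs_from_exact(self, rng):
        """The factored batch-average approximation is not the true gradient."""
        gs = build_groups(8, 2, 0.25, "relaxed")
        cfg = PenaltyConfig()
        params = _params(rng)
        V = rng.uniform(size=(4, 6))
        dW_exact, _ = penalty_param_grads(V, params, cfg, gs)
        dW_fact, _ = penalty_param_grads(V, params, cfg, gs, factored=True)
        assert not np.allclose(dW_exact, dW_fact)


class TestTrainGLSRBM:
    def test_seeded_training_is_bit_reproducible(self, small_cohort):
        fm, _ = small_cohort
        cfg = TrainConfig(epochs=3, seed=11)
        gs = build_groups(12, 3, 0.2, "relaxed")
        p1, _ = train_glsrbm(fm.values, 12, cfg, PenaltyConfig(), gs)
        p2, _ = train_glsrbm(fm.values, 12, cfg, PenaltyConfig(), gs)
        assert np.array_equal(p1.W, p2.W)
        assert np.array_equal(p1.a, p2.a)
        assert np.array_equal(p1.b, p2.b)

    def test_tau_zero_equals_penalty_free_run(self, small_cohort):
        """With tau=0 the trainer is byte-for-byte a plain CD-trained RBM."""
        fm, _ = small_cohort
        cfg = TrainConfig(epochs=4, seed=5)
        gs = build_groups(10, 2, 0.2, "relaxed")
        p_tau0, _ = train_glsrbm(
            fm.values, 10, cfg, PenaltyConfig(tau=0.0), gs
        )
        p_plain, _ = train_glsrbm(fm.values, 10, cfg, None, None)
        assert np.array_equal(p_tau0.W, p_plain.W)
        assert np.array_equal(p_tau0.a, p_plain.a)
        assert np.array_equal(p_tau0.b, p_plain.b)

    def test_reconstruction_error_decreases_over_training(self, small_cohort):
        fm, _ = small_cohort
        cfg = TrainConfig(epochs=50, seed=2, learning_rate=0.05)
        params, hist = train_glsrbm(fm.values, 12, cfg, None, None)
        assert hist.reconstruction_error[-1] < hist.reconstruction_error[0]

    def test_penalty_raises_sparseness(self, small_cohort):
        fm, _ = small_cohort
        gs = build_groups(30, 5, 0.2, "relaxed")
        cfg = TrainConfig(epochs=30, seed=1)
        base, _ = train_glsrbm(fm.values, 30, cfg, None, None)
        gls, _ = train_glsrbm(fm.values, 30, cfg, PenaltyConfig(), gs)
        s_base = mean_activation_sparseness(base, fm.values).mean
        s_gls = mean_activation_sparseness(gls, fm.values).mean
        assert s_gls > s_base

    def test_sparseness_weakly_increases_with_tau(self, small_cohort):
        fm, _ = small_cohort
        gs = build_groups(30, 5, 0.2, "relaxed")
        cfg = TrainConfig(epochs=20, seed=4)
        means = []
        for tau in (0.0, 1.0, 4.0):
            p, _ = train_glsrbm(fm.values, 30, cfg, PenaltyConfig(tau=tau), gs)
            means.append(mean_activation_sparseness(p, fm.values).mean)
        assert means[0] <= means[1] <= means[2]

    def test_probabilities_and_parameters_stay_finite(self, small_cohort):
        fm, _ = small_cohort
        cfg = TrainConfig(epochs=10, seed=9, learning_rate=0.1)
        gs = build_groups(16, 4, 0.25, "relaxed")
        params, _ = train_glsrbm(fm.values, 16, cfg, PenaltyConfig(), gs)
        assert np.isfinite(params.W).all()
        P = hidden_probabilities(fm.values, params)
        assert (P > 0).all() and (P < 1).all()

    def test_out_of_range_input_rejected(self):
        with pytest.raises(ValueError, match="0, 1"):
            train_glsrbm(np.array([[1.5, 0.2]]), 4, TrainConfig(epochs=1))
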