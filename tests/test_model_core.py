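"""Model core: likelihood/KL closed forms, causality, gradients, training."""

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import norm

from calfads import synth
from calfads.model import (
    ModelConfig,
    _init_params,
    forward_causal,
    gaussian_log_likelihood,
    kl_diag_gaussians,
    loss_and_grads,
    posterior_average,
    split_train_valid,
    train,
)
from calfads.synth import SessionData

from conftest import make_untrained_model


class TestGaussianLogLikelihood:
    def test_single_element_at_mean_unit_variance(self):
        assert np.isclose(
            gaussian_log_likelihood(np.array([0.0]), np.array([0.0]), np.array([1.0])),
            -0.5 * np.log(2 * np.pi),
        )

    def test_one_sigma_deviation(self):
        sigma = 1.7
        got = gaussian_log_likelihood(
            np.array([sigma]), np.array([0.0]), np.array([sigma**2])
        )
        assert np.isclose(got, -0.5 * np.log(2 * np.pi * sigma**2) - 0.5)

    def test_matches_density_product_oracle(self, rng):
        obs = rng.normal(size=(5, 5))
        mean = rng.normal(size=(5, 5))
        var = rng.uniform(0.5, 2.0, size=(5, 5))
        expected = norm.logpdf(obs, loc=mean, scale=np.sqrt(var)).sum()
        assert np.isclose(gaussian_log_likelihood(obs, mean, var), expected, atol=1e-10)

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            gaussian_log_likelihood(np.zeros(2), np.zeros(2), np.array([1.0, 0.0]))


class TestKLDiagGaussians:
    def test_identical_distributions_give_zero(self, rng):
        m = rng.normal(size=4)
        v = rng.uniform(0.5, 2, size=4)
        assert np.isclose(kl_diag_gaussians(m, v, m, v), 0.0)

    def test_closed_form_scale_mismatch(self):
        # q = N(0,1), p = N(0,e): KL = (log e + 1/e - 1)/2 per dimension
        d = 3
        got = kl_diag_gaussians(np.zeros(d), np.ones(d), np.zeros(d), np.full(d, np.e))
        assert np.isclose(got, d * 0.5 * (1.0 + 1.0 / np.e - 1.0))

    def test_matches_quadrature_oracle(self, rng):
        mq, vq = rng.normal(size=3), rng.uniform(0.5, 2, size=3)
        mp, vp = rng.normal(size=3), rng.uniform(0.5, 2, size=3)
        expected = 0.0
        for i in range(3):
            f = lambda x: norm.pdf(x, mq[i], np.sqrt(vq[i])) * (
                norm.logpdf(x, mq[i], np.sqrt(vq[i]))
                - norm.logpdf(x, mp[i], np.sqrt(vp[i]))
            )
            val, _ = integrate.quad(f, -20, 20)
            expected += val
        assert np.isclose(kl_diag_gaussians(mq, vq, mp, vp), expected, atol=1e-6)

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            kl_diag_gaussians(np.zeros(2), np.zeros(2), np.zeros(2), np.ones(2))


class TestSplitTrainValid:
    @pytest.mark.parametrize(
        "n_trials,n_train,n_valid", [(4, 2, 2), (2, 1, 1), (5, 3, 2)]
    )
    def test_odd_even_split_counts(self, n_trials, n_train, n_valid):
        data = SessionData(
            fluorescence=np.arange(n_trials * 4 * 2, dtype=float).reshape(n_trials, 4, 2),
            trial_type=np.array(["rewarded"] * n_trials, dtype=object),
            cue_bin=1,
        )
        tr, va = split_train_valid(data)
        assert tr.n_trials == n_train and va.n_trials == n_valid
        # 1-based odd trials (session order preserved) go to training
        np.testing.assert_array_equal(tr.fluorescence, data.fluorescence[0::2])
        np.testing.assert_array_equal(va.fluorescence, data.fluorescence[1::2])

    def test_single_trial_rejected(self):
        data = SessionData(
            fluorescence=np.zeros((1, 4, 2)),
            trial_type=np.array(["rewarded"], dtype=object),
            cue_bin=1,
        )
        with pytest.raises(ValueError):
            split_train_valid(data)


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self, rng):
        """BPTT gradients vs central finite differences, all parameter groups."""
        cfg = ModelConfig(
            n_generator_units=6, n_factors=3, n_input_dims=2,
            n_encoder_units=5, n_controller_units=4,
            l2_penalty=1e-3, dropout_keep_rate=0.8, seed=0,
        )
        B, T, N = 3, 5, 4
        X = rng.normal(size=(B, T, N))
        params = _init_params(cfg, N, rng)
        kw = dict(
            eps_ic=rng.standard_normal((B, cfg.n_generator_units)),
            eps_u=rng.standard_normal((B, T, cfg.n_input_dims)),
            mask_x=(rng.random((B, T, N)) < 0.8) / 0.8,
            mask_g=(rng.random((B, T, cfg.n_generator_units)) < 0.8) / 0.8,
        )
        _, grads, _ = loss_and_grads(params, X, X, cfg, 0.7, **kw)
        h = 1e-6
        check_rng = np.random.default_rng(1)
        for k in params:
            idxs = list(np.ndindex(*params[k].shape)) if params[k].ndim else [()]
            picks = [
                idxs[i]
                for i in check_rng.choice(len(idxs), min(3, len(idxs)), replace=False)
            ]
            for idx in picks:
                orig = params[k][idx]
                params[k][idx] = orig + h
                lp, _, _ = loss_and_grads(params, X, X, cfg, 0.7, **kw)
                params[k][idx] = orig - h
                lm, _, _ = loss_and_grads(params, X, X, cfg, 0.7, **kw)
                params[k][idx] = orig
                fd = (lp - lm) / (2 * h)
                assert np.isclose(grads[k][idx], fd, rtol=1e-4, atol=1e-8), k


def _perturbed_pair(rng, model, B=2, T=10, t_split=4):
    """Two sessions identical up to bin t_split-1, differing afterwards."""
    base = rng.normal(size=(B, T, model.n_neurons))
    other = base.copy()
    other[:, t_split:] += rng.normal(size=(B, T - t_split, model.n_neurons))
    def wrap(X):
        return SessionData(
            fluorescence=X,
            trial_type=np.array(["rewarded"] * B, dtype=object),
            cue_bin=2,
        )
    return wrap(base), wrap(other)


class TestCausality:
    def test_future_perturbations_leave_past_inference_unchanged(self, rng, untrained_model):
        """Inferred quantities at bins <= t are bitwise invariant to bins > t."""
        for _ in range(10):
            t_split = int(rng.integers(1, 9))
            a, b = _perturbed_pair(rng, untrained_model, t_split=t_split)
            pa = forward_causal(untrained_model, a, mode="mean")
            pb = forward_causal(untrained_model, b, mode="mean")
            np.testing.assert_array_equal(
                pa.inferred_inputs[:, :t_split], pb.inferred_inputs[:, :t_split]
            )
            np.testing.assert_array_equal(
                pa.factors[:, :t_split], pb.factors[:, :t_split]
            )
            np.testing.assert_array_equal(
                pa.denoised_means[:, :t_split], pb.denoised_means[:, :t_split]
            )

    def test_sample_mode_deterministic_given_seed(self, rng, untrained_model):
        a, _ = _perturbed_pair(rng, untrained_model)
        p1 = forward_causal(untrained_model, a, mode="sample", seed=3)
        p2 = forward_causal(untrained_model, a, mode="sample", seed=3)
        np.testing.assert_array_equal(p1.denoised_means, p2.denoised_means)
        assert p1.elbo == p2.elbo and np.isfinite(p1.elbo)

    def test_invalid_mode_rejected(self, rng, untrained_model):
        a, _ = _perturbed_pair(rng, untrained_model)
        with pytest.raises(ValueError):
            forward_causal(untrained_model, a, mode="map")


class TestElboDecomposition:
    def test_components_match_independent_closed_forms(self, rng, untrained_model):
        """recon/kl_g0/kl_u recomputed from outputs with the closed-form oracles."""
        a, _ = _perturbed_pair(rng, untrained_model)
        po = forward_causal(untrained_model, a, mode="mean")
        var = np.exp(untrained_model.params["out_logvar"])
        recon = gaussian_log_likelihood(
            a.fluorescence, po.denoised_means, np.broadcast_to(var, a.fluorescence.shape)
        )
        assert np.isclose(recon, po.recon, atol=1e-8)
        kl0 = kl_diag_gaussians(
            po.ic_mean.ravel(), po.ic_var.ravel(),
            np.zeros(po.ic_mean.size), np.ones(po.ic_mean.size),
        )
        assert np.isclose(kl0, po.kl_g0, atol=1e-8)
        # input KL against the stationary AR(1) sequence prior, recomputed by
        # the independent full-covariance route: prior Sigma[i,j] = phi^|i-j|
        cfg = untrained_model.config
        phi = np.exp(-cfg.bin_size / cfg.input_prior_tau)
        T = po.input_mean.shape[1]
        Sp = phi ** np.abs(np.subtract.outer(np.arange(T), np.arange(T)))
        Sp_inv = np.linalg.inv(Sp)
        _, logdet_p = np.linalg.slogdet(Sp)
        klu = 0.0
        for b in range(po.input_mean.shape[0]):
            for d in range(po.input_mean.shape[2]):
                m = po.input_mean[b, :, d]
                v = po.input_var[b, :, d]
                klu += 0.5 * (
                    np.trace(Sp_inv @ np.diag(v)) + m @ Sp_inv @ m - T
                    - np.sum(np.log(v)) + logdet_p
                )
        assert np.isclose(klu, po.kl_u, atol=1e-6)
        assert np.isclose(po.elbo, po.recon - po.kl_g0 - po.kl_u, atol=1e-8)


class TestPosteriorAverage:
    def test_single_sample_matches_forward_sample(self, rng, untrained_model):
        a, _ = _perturbed_pair(rng, untrained_model)
        avg = posterior_average(untrained_model, a, 1, seed=5)
        rng_inner = np.random.default_rng(5)
        po = forward_causal(
            untrained_model, a, mode="sample", seed=int(rng_inner.integers(2**31))
        )
        np.testing.assert_array_equal(avg.denoised_means, po.denoised_means)

    def test_monte_carlo_convergence(self, rng, untrained_model):
        a, _ = _perturbed_pair(rng, untrained_model)
        ref = forward_causal(untrained_model, a, mode="mean").denoised_means
        err = []
        for n in (4, 64):
            avg = posterior_average(untrained_model, a, n, seed=0)
            err.append(np.linalg.norm(avg.denoised_means - ref))
        assert err[1] < err[0]

    def test_reproducible_given_seed(self, rng, untrained_model):
        a, _ = _perturbed_pair(rng, untrained_model)
        r1 = posterior_average(untrained_model, a, 3, seed=2)
        r2 = posterior_average(untrained_model, a, 3, seed=2)
        np.testing.assert_array_equal(r1.inferred_inputs, r2.inferred_inputs)


@pytest.fixture(scope="module")
def tiny_session():
    system = synth.make_system("line", 3, 6, seed=3)
    data, _ = synth.simulate_session(system, 12, 0.8, 12, seed=3)
    return data


class TestTraining:

    def test_elbo_improves_and_is_deterministic(self, tiny_session):
        cfg = ModelConfig.test_scale(
            n_generator_units=16, n_factors=4, n_encoder_units=12,
            n_controller_units=8, max_epochs=40, kl_warmup_epochs=10, seed=0,
        )
        m1 = train(tiny_session, cfg)
        assert m1.training_curve["train_elbo"][-1] > m1.training_curve["train_elbo"][0]
        m2 = train(tiny_session, cfg)
        for k in m1.params:
            np.testing.assert_array_equal(m1.params[k], m2.params[k])

    def test_l2_penalty_shrinks_recurrent_weights(self, tiny_session):
        kw = dict(
            n_generator_units=16, n_factors=4, n_encoder_units=12,
            n_controller_units=8, max_epochs=30, kl_warmup_epochs=10, seed=0,
        )
        free = train(tiny_session, ModelConfig.test_scale(l2_penalty=0.0, **kw))
        tight = train(tiny_session, ModelConfig.test_scale(l2_penalty=1e6, **kw))
        assert (
            np.linalg.norm(tight.params["gen_Wh"])
            < np.linalg.norm(free.params["gen_Wh"])
        )

    def test_degenerate_neuron_rejected(self, tiny_session):
        bad = SessionData(
            fluorescence=np.concatenate(
                [tiny_session.fluorescence,
                 np.zeros_like(tiny_session.fluorescence[:, :, :1])], axis=2
            ),
            trial_type=tiny_session.trial_type,
            cue_bin=tiny_session.cue_bin,
        )
        with pytest.raises(ValueError):
            train(bad, ModelConfig.test_scale(seed=0))
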