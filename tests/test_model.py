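"""Model components: KL closed form, reparameterization, decoders, losses,
early stopping, and estimator behaviour."""

import math

import numpy as np
import pytest
from sklearn.base import clone

from gaitspeed.model import (EarlyStopping, Encoder, EncoderConfig,
                             LSTMCNNDecoder, PredictionHead, SVAERegressor,
                             SineDecoder, feedforward_loss, kl_gaussian,
                             reparameterize, svae_loss)
from gaitspeed.nn import Adam, Tensor


class TestKLGaussian:
    def test_standard_normal_is_zero(self):
        assert kl_gaussian(np.zeros(3), np.ones(3)) == pytest.approx(0.0)

    def test_unit_mean_closed_form(self):
        # 0.5 (mu^2 + sigma^2 - 1 - ln sigma^2) = 0.5 at mu=1, sigma=1
        assert kl_gaussian([1.0], [1.0]) == pytest.approx(0.5)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            kl_gaussian([0.0], [0.0])

    def test_matches_monte_carlo_estimate(self):
        """Closed form within 1% of a 1e6-sample MC estimate of
        E_q[log q(z) − log p(z)] for random (μ, σ) at L = 4."""
        rng = np.random.default_rng(10)
        for _ in range(5):
            mu = rng.normal(0, 1, 4)
            sigma = rng.uniform(0.5, 2.0, 4)
            z = mu + sigma * rng.standard_normal((1_000_000, 4))
            log_q = -0.5 * np.sum(((z - mu) / sigma) ** 2 + np.log(2 * np.pi)
                                  + 2 * np.log(sigma), axis=1)
            log_p = -0.5 * np.sum(z ** 2 + np.log(2 * np.pi), axis=1)
            mc = np.mean(log_q - log_p)
            assert abs(kl_gaussian(mu, sigma) - mc) / mc < 0.01


class TestReparameterize:
    def test_zero_eps_returns_mean(self):
        np.testing.assert_array_equal(
            reparameterize([1.0, -2.0], [0.5, 3.0], [0.0, 0.0]), [1.0, -2.0])

    def test_zero_sigma_collapses_to_mean(self):
        np.testing.assert_array_equal(
            reparameterize([1.0, -2.0], [0.0, 0.0], [5.0, -7.0]), [1.0, -2.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            reparameterize([1.0], [1.0], [0.0, 0.0])

    def test_sample_moments_match_posterior(self):
        rng = np.random.default_rng(11)
        mu, sigma = np.array([0.7, -1.2]), np.array([0.9, 1.6])
        eps = rng.standard_normal((100_000, 2))
        z = reparameterize(np.broadcast_to(mu, eps.shape),
                           np.broadcast_to(sigma, eps.shape), eps)
        np.testing.assert_allclose(z.mean(axis=0), mu, atol=0.02 * np.abs(mu).max() + 0.01)
        np.testing.assert_allclose(z.std(axis=0), sigma, rtol=0.02)


class TestEncoder:
    CFG = EncoderConfig(conv_channels=2, hidden_size=16, hidden_depth=1,
                        latent_len=8, n_conv_layers=1)

    def test_output_shapes_and_determinism(self):
        enc = Encoder(3, 64, self.CFG, np.random.default_rng(0))
        X = np.random.default_rng(1).normal(size=(3, 64))
        code1, code2 = enc.encode(X), enc.encode(X)
        assert code1.mu.shape == (8,)
        np.testing.assert_array_equal(code1.mu, code2.mu)
        np.testing.assert_array_equal(code1.log_sigma, code2.log_sigma)

    def test_sigma_strictly_positive(self):
        """Exponential parameterization keeps σ > 0 for random weights/inputs."""
        rng = np.random.default_rng(2)
        for trial in range(20):
            enc = Encoder(2, 32, EncoderConfig(conv_channels=1, hidden_size=8,
                                               hidden_depth=1, latent_len=4,
                                               n_conv_layers=1),
                          np.random.default_rng(trial))
            X = rng.normal(size=(50, 2, 32)) * 10
            code = enc.encode(X)
            assert np.all(code.sigma > 0)

    def test_non_finite_input_rejected(self):
        enc = Encoder(3, 64, self.CFG, np.random.default_rng(0))
        X = np.full((3, 64), np.nan)
        with pytest.raises(ValueError):
            enc.encode(X)


class TestSineDecoder:
    def test_zero_latent_bias_free_gives_zero_window(self):
        dec = SineDecoder(4, 2, 32, 3, np.random.default_rng(0), affine=False)
        out = dec.decode(np.zeros(4))
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_constructive_exactness_single_sinusoid(self):
        """A window that IS a weighted sinusoid is reconstructed exactly when
        the maps are pinned to its (A, ω, φ)."""
        C, T, H = 2, 64, 5
        dec = SineDecoder(3, C, T, H, np.random.default_rng(0))
        tau = np.arange(T) - T // 2
        A_true, omega, phi = np.array([1.3, -0.4]), 0.37, 0.9
        target = A_true[:, None] * np.sin(omega * tau + phi)[None, :]
        A = np.zeros((C, H))
        A[:, 0] = A_true
        dec.set_constant(A, [omega] + [0.0] * (H - 1), [phi] + [0.0] * (H - 1))
        out = dec.decode(np.random.default_rng(1).normal(size=3))
        assert np.mean((out - target) ** 2) < 1e-10

    def test_sum_of_components_reconstructed(self):
        C, T, H = 3, 48, 4
        rng = np.random.default_rng(2)
        A = rng.normal(size=(C, H))
        omega = rng.uniform(0.05, 0.5, H)
        phi = rng.uniform(0, 2 * np.pi, H)
        tau = np.arange(T) - T // 2
        target = np.einsum("ch,ht->ct", A, np.sin(np.outer(omega, tau) + phi[:, None]))
        dec = SineDecoder(2, C, T, H, rng)
        dec.set_constant(A, omega, phi)
        assert np.mean((dec.decode(np.zeros(2)) - target) ** 2) < 1e-10

    def test_output_bounded_by_amplitude_sum(self):
        rng = np.random.default_rng(3)
        dec = SineDecoder(6, 2, 40, 8, rng)
        z = rng.normal(size=6)
        out = dec.decode(z)
        A = dec.amp_map.weight.data.T @ z + dec.amp_map.bias.data
        bound = np.abs(A.reshape(2, 8)).sum(axis=1)
        assert np.all(np.abs(out) <= bound[:, None] + 1e-12)

    def test_gradients_match_finite_differences(self):
        """Analytic ∂MSE/∂(W1,W2,W3) within 1e-4 relative of central FD."""
        C, T, L, H = 2, 32, 3, 2
        rng = np.random.default_rng(4)
        dec = SineDecoder(L, C, T, H, rng)
        z = Tensor(rng.normal(size=(1, L)))
        target = rng.normal(size=(1, C, T))

        def loss_value():
            return float((((dec.forward(z) - Tensor(target)) ** 2).mean()).data)

        loss = ((dec.forward(z) - Tensor(target)) ** 2).mean()
        loss.backward()
        for p in dec.parameters():
            analytic = p.grad.copy()
            fd = np.zeros_like(p.data)
            it = np.nditer(p.data, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                old = p.data[i]
                h = 1e-6 * max(1.0, abs(old))
                p.data[i] = old + h
                up = loss_value()
                p.data[i] = old - h
                dn = loss_value()
                p.data[i] = old
                fd[i] = (up - dn) / (2 * h)
            denom = np.maximum(np.abs(fd), 1e-8)
            assert np.max(np.abs(analytic - fd) / denom) < 1e-4


class TestLSTMCNNDecoder:
    @pytest.mark.parametrize("conv_channels,latent_len", [(1, 64), (4, 128), (16, 256)])
    def test_output_shape_across_grid(self, conv_channels, latent_len):
        cfg = EncoderConfig(conv_channels=conv_channels, latent_len=latent_len,
                            n_conv_layers=2)
        dec = LSTMCNNDecoder(latent_len, 6, 128, cfg, np.random.default_rng(0))
        out = dec.decode(np.random.default_rng(1).normal(size=latent_len))
        assert out.shape == (6, 128)

    def test_deterministic(self):
        cfg = EncoderConfig(conv_channels=2, latent_len=8, n_conv_layers=1)
        dec = LSTMCNNDecoder(8, 2, 32, cfg, np.random.default_rng(0))
        z = np.random.default_rng(1).normal(size=8)
        np.testing.assert_array_equal(dec.decode(z), dec.decode(z))

    def test_capacity_fits_toy_windows(self):
        """Direct optimization on 4 fixed windows reaches MSE < 1e-2."""
        cfg = EncoderConfig(conv_channels=4, latent_len=4, n_conv_layers=1)
        rng = np.random.default_rng(5)
        dec = LSTMCNNDecoder(4, 2, 32, cfg, rng)
        z = Tensor(np.eye(4))
        tau = np.arange(32) - 16
        target = np.stack([a * np.sin(w * tau + p)[None, :].repeat(2, axis=0)
                           for a, w, p in [(0.5, 0.2, 0.0), (1.0, 0.3, 1.0),
                                           (0.8, 0.15, 2.0), (0.3, 0.4, 0.5)]])
        opt = Adam(dec.parameters(), lr=5e-3)
        mse = np.inf
        for _ in range(400):
            opt.zero_grad()
            loss = ((dec.forward(z) - Tensor(target)) ** 2).mean()
            loss.backward()
            opt.step()
            mse = float(loss.data)
            if mse < 1e-2:
                break
        assert mse < 1e-2


class TestPredictionHead:
    def test_deterministic_and_zero_weights_give_zero(self):
        head = PredictionHead(4, np.random.default_rng(0))
        z = np.random.default_rng(1).normal(size=4)
        assert head.predict(z) == head.predict(z)
        for p in head.parameters():
            p.data[:] = 0.0
        assert head.predict(z) == 0.0

    def test_recovers_linear_map(self):
        """Trained on (z, w·z) pairs the head reaches MSE < 1e-3."""
        rng = np.random.default_rng(6)
        w = np.array([0.5, -1.0, 0.25])
        Z = rng.normal(size=(128, 3))
        y = Z @ w
        head = PredictionHead(3, rng)
        opt = Adam(head.parameters(), lr=1e-2)
        for _ in range(600):
            opt.zero_grad()
            loss = ((head.forward(Tensor(Z)) - Tensor(y)) ** 2).mean()
            loss.backward()
            opt.step()
        assert float(loss.data) < 1e-3


class TestLosses:
    def test_feedforward_loss_values(self):
        assert feedforward_loss([5.0], [3.0]) == pytest.approx(4.0)
        assert feedforward_loss([3.0], [5.0]) == pytest.approx(4.0)
        assert feedforward_loss([2.0], [2.0]) == 0.0

    def _toy(self):
        X = np.array([[1.0, 2.0, 0.0, -1.0]])
        X_hat = np.array([[0.5, 1.5, 0.5, -0.5]])
        mu = np.array([0.3, -0.2])
        sigma = np.array([1.1, 0.8])
        return X, 5.0, X_hat, 4.2, mu, sigma

    def test_alpha_beta_zero_is_autoencoder_loss(self):
        X, y, X_hat, y_hat, mu, sigma = self._toy()
        total, parts = svae_loss(X, y, X_hat, y_hat, mu, sigma, alpha=0.0, beta=0.0)
        assert total == pytest.approx(np.sum((X - X_hat) ** 2), abs=1e-9)
        assert parts["reconstruction"] == pytest.approx(total, abs=1e-9)

    def test_beta_zero_identity(self):
        X, y, X_hat, y_hat, mu, sigma = self._toy()
        alpha = 0.01
        total, parts = svae_loss(X, y, X_hat, y_hat, mu, sigma, alpha=alpha, beta=0.0)
        assert total == parts["reconstruction"] + alpha * parts["prediction"]

    def test_hand_computed_toy_instance(self):
        X, y, X_hat, y_hat, mu, sigma = self._toy()
        # hand arithmetic: pred = (5−4.2)² ; recon = 4·0.5² ;
        # kl = ½[(0.09+1.21−1−2 ln 1.1)+(0.04+0.64−1−2 ln 0.8)]
        pred = 0.8 ** 2
        recon = 4 * 0.25
        kl = 0.5 * ((0.09 + 1.21 - 1 - 2 * math.log(1.1))
                    + (0.04 + 0.64 - 1 - 2 * math.log(0.8)))
        expected = 0.01 * pred + recon + 1e-4 * kl
        total, _ = svae_loss(X, y, X_hat, y_hat, mu, sigma, alpha=0.01, beta=1e-4)
        assert total == pytest.approx(expected, abs=1e-9)
        assert total == pytest.approx(1.006411783, abs=1e-6)

    def test_negative_weights_rejected(self):
        X, y, X_hat, y_hat, mu, sigma = self._toy()
        with pytest.raises(ValueError):
            svae_loss(X, y, X_hat, y_hat, mu, sigma, alpha=-0.1, beta=0.0)

    def test_loss_non_negative(self):
        X, y, X_hat, y_hat, mu, sigma = self._toy()
        total, parts = svae_loss(X, y, X_hat, y_hat, mu, sigma, alpha=0.1, beta=1e-5)
        assert total >= 0
        assert all(v >= 0 for v in parts.values())


class TestEarlyStopping:
    def test_stops_after_exact_patience_and_keeps_best(self):
        """Sequence [3, 2, then 20 non-improving] stops at the 20th
        non-improving check with best value 2."""
        stopper = EarlyStopping(patience=20)
        assert not stopper.update(3.0)
        assert not stopper.update(2.0)
        for k in range(19):
            assert not stopper.update(2.5 + 0.01 * k)
        assert stopper.update(2.7)  # 20th consecutive non-improvement
        assert stopper.best_value == 2.0
        assert stopper.best_index == 1
        assert stopper.n_checks == 22

    def test_equal_value_does_not_count_as_improvement(self):
        stopper = EarlyStopping(patience=2)
        stopper.update(1.0)
        assert not stopper.update(1.0)
        assert stopper.update(1.0)

    def test_reset_on_improvement(self):
        stopper = EarlyStopping(patience=3)
        for v in [5.0, 4.9, 4.95, 4.8, 4.85, 4.9]:
            assert not stopper.update(v)
        assert stopper.update(5.0)


class TestSVAERegressor:
    def _toy_data(self, n=24, C=2, T=32, seed=0):
        rng = np.random.default_rng(seed)
        y = rng.uniform(2, 20, n)
        tau = np.arange(T)
        X = np.stack([np.sin(0.05 * y_i * tau)[None, :].repeat(C, axis=0)
                      + 0.05 * rng.standard_normal((C, T)) for y_i in y])
        return X, y

    def _estimator(self, **kw):
        args = dict(conv_channels=2, hidden_size=16, hidden_depth=1, latent_len=4,
                    n_sine=3, n_conv_layers=1, max_epochs=4, batch_size=8, seed=0)
        args.update(kw)
        return SVAERegressor(**args)

    def test_training_loss_decreases(self):
        X, y = self._toy_data()
        est = self._estimator().fit(X, y)
        assert est.history_["train_loss"][-1] < est.history_["train_loss"][0]

    def test_fit_predict_shapes_and_range(self):
        X, y = self._toy_data()
        est = self._estimator().fit(X, y)
        pred = est.predict(X)
        assert pred.shape == y.shape
        assert np.all(np.isfinite(pred))

    def test_repeat_fit_is_deterministic(self):
        X, y = self._toy_data()
        h1 = self._estimator().fit(X, y).history_["train_loss"]
        h2 = self._estimator().fit(X, y).history_["train_loss"]
        np.testing.assert_array_equal(h1, h2)

    def test_sklearn_clone_and_params(self):
        est = self._estimator(alpha=0.01)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()

    def test_validation_early_stopping_restores_best(self):
        X, y = self._toy_data(n=32)
        est = self._estimator(max_epochs=12, patience=2)
        est.fit(X[:24], y[:24], X_val=X[24:], y_val=y[24:])
        assert est.n_epochs_ <= 12
        best = min(est.history_["val_mse"])
        # restored weights reproduce the best validation error
        Xv = est._standardize_X(X[24:])
        yv = (y[24:] - est.y_mean_) / est.y_std_
        val = float(np.mean((est._predict_standardized(Xv) - yv) ** 2))
        assert val == pytest.approx(best, rel=1e-9)

    def test_save_load_round_trip(self, tmp_path):
        X, y = self._toy_data()
        est = self._estimator().fit(X, y)
        f = tmp_path / "model.npz"
        est.save(f)
        loaded = SVAERegressor.load(f)
        np.testing.assert_allclose(loaded.predict(X), est.predict(X))

    def test_lstm_cnn_decoder_trains(self):
        X, y = self._toy_data(n=16)
        est = self._estimator(decoder="lstm_cnn", max_epochs=2).fit(X, y)
        assert est.history_["train_loss"][-1] < est.history_["train_loss"][0] * 1.5
        assert np.all(np.isfinite(est.predict(X)))
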