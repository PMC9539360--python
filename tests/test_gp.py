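import numpy as np
import pytest
from scipy.stats import multivariate_normal

from ivtbo import gp
from ivtbo.gp import GPHyperparams, GPModel

# independent kernel oracle
from sklearn.gaussian_process.kernels import Matern

MATERN_AT_UNIT_DISTANCE = 0.523994108831820  # (1+sqrt5+5/3)exp(-sqrt5)


def hyper(ls, sf2=1.0, sn2=0.0, mean=0.0):
    return GPHyperparams(np.asarray(ls, dtype=float), sf2, sn2, mean)


def dense_posterior_oracle(X, y, Xq, h: GPHyperparams):
    """Textbook dense-solve GP posterior, independent of the package's path."""
    kern = Matern(length_scale=h.length_scales, nu=2.5)
    K = h.signal_var * kern(X) + (h.noise_var + gp.JITTER_REL * h.signal_var) * np.eye(len(X))
    Ks = h.signal_var * kern(Xq, X)
    Kinv = np.linalg.inv(K)
    mu = h.mean + Ks @ Kinv @ (y - h.mean)
    var = h.signal_var - np.einsum("ij,jk,ik->i", Ks, Kinv, Ks)
    return mu, np.sqrt(np.maximum(var, 0.0))


class TestKernel:
    def test_zero_distance_gives_amplitude(self):
        h = hyper([1.0, 1.0], sf2=2.5)
        x = np.array([0.3, 0.7])
        assert gp.matern52(x, x, h) == pytest.approx(2.5)

    def test_unit_distance_closed_form(self):
        h = hyper([1.0])
        assert gp.matern52(np.array([0.0]), np.array([1.0]), h) == pytest.approx(
            MATERN_AT_UNIT_DISTANCE, abs=1e-12
        )

    def test_strictly_decreasing_to_zero(self):
        h = hyper([1.0])
        rs = np.linspace(0, 20, 200)
        vals = [gp.matern52(np.array([0.0]), np.array([r]), h) for r in rs]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 1e-8

    def test_matches_sklearn_matern_gram(self, rng):
        X = rng.random((15, 4))
        ls = np.array([0.3, 1.2, 0.7, 2.0])
        h = hyper(ls, sf2=3.0)
        ours = gp.matern52_gram(X, X, h)
        ref = 3.0 * Matern(length_scale=ls, nu=2.5)(X)
        np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_gram_psd_on_random_point_sets(self, rng):
        for _ in range(5):
            X = rng.random((25, 6))
            h = hyper(rng.uniform(0.1, 2.0, 6), sf2=1.7)
            w = np.linalg.eigvalsh(gp.matern52_gram(X, X, h))
            assert w.min() >= -1e-8

    def test_rejects_nonpositive_length_scale(self):
        with pytest.raises(ValueError):
            hyper([0.0])

    def test_rejects_dimension_mismatch(self):
        with pytest.raises(ValueError):
            gp.matern52(np.zeros(2), np.zeros(3), hyper([1.0, 1.0]))


class TestPosterior:
    def test_agrees_with_dense_solve_oracle(self, rng):
        X = rng.random((20, 3))
        y = rng.normal(5.0, 2.0, 20)
        h = hyper([0.4, 0.9, 1.5], sf2=4.0, sn2=0.3, mean=5.0)
        m = gp._build_model(X, y, h)
        Xq = rng.random((40, 3))
        mu, sd = gp.predict(m, Xq)
        mu_o, sd_o = dense_posterior_oracle(X, y, Xq, h)
        np.testing.assert_allclose(mu, mu_o, atol=1e-8)
        np.testing.assert_allclose(sd, sd_o, atol=1e-8)

    def test_interpolates_as_noise_vanishes(self, rng):
        X = rng.random((8, 2))
        y = rng.normal(0, 1, 8)
        m = gp._build_model(X, y, hyper([0.5, 0.5], sn2=0.0))
        mu, sd = gp.predict(m, X)
        np.testing.assert_allclose(mu, y, atol=1e-4)
        assert np.all(sd < 1e-2)

    def test_reverts_to_prior_far_from_data(self):
        X = np.zeros((3, 1)) + [[0.0], [0.01], [0.02]]
        y = np.array([4.0, 4.1, 3.9])
        h = hyper([0.05], sf2=2.0, sn2=0.1, mean=1.5)
        m = gp._build_model(X, y, h)
        mu, sd = gp.predict(m, np.array([[50.0]]))
        assert mu[0] == pytest.approx(1.5, abs=1e-6)
        assert sd[0] == pytest.approx(np.sqrt(2.0), abs=1e-6)

    def test_posterior_sd_never_exceeds_prior_sd(self, rng):
        X = rng.random((5, 2))
        y = rng.normal(0, 1, 5)
        h = hyper([0.7, 0.7], sf2=3.0, sn2=0.2)
        m = gp._build_model(X, y, h)
        _, sd = gp.predict(m, rng.random((100, 2)))
        assert np.all(sd <= np.sqrt(3.0) + 1e-10)

    def test_invariant_to_training_row_permutation(self, rng):
        X = rng.random((12, 3))
        y = rng.normal(0, 1, 12)
        h = hyper([0.5, 0.8, 1.1], sf2=1.0, sn2=0.05)
        perm = rng.permutation(12)
        Xq = rng.random((7, 3))
        mu1, sd1 = gp.predict(gp._build_model(X, y, h), Xq)
        mu2, sd2 = gp.predict(gp._build_model(X[perm], y[perm], h), Xq)
        np.testing.assert_allclose(mu1, mu2, atol=1e-9)
        np.testing.assert_allclose(sd1, sd2, atol=1e-9)

    def test_prior_prediction_with_no_data(self):
        h = hyper([1.0, 1.0], sf2=0.75, sn2=0.25, mean=3.0)
        m = gp.empty_model(h, dim=2)
        mu, sd = gp.predict(m, np.array([[0.1, 0.9]]))
        assert mu[0] == 3.0
        assert sd[0] == pytest.approx(1.0)

    def test_dimension_mismatch_raises(self, rng):
        m = gp._build_model(rng.random((4, 3)), rng.normal(size=4), hyper([1, 1, 1]))
        with pytest.raises(ValueError):
            gp.predict(m, np.zeros((2, 5)))


class TestLogMarginalLikelihood:
    def test_single_standard_normal_observation(self):
        h = hyper([1.0], sf2=0.6, sn2=0.4, mean=2.0)
        lml = gp.log_marginal_likelihood(np.array([[0.5]]), np.array([2.0]), h)
        assert lml == pytest.approx(-0.918938533204673, abs=1e-6)

    def test_matches_multivariate_normal_density(self, rng):
        X = rng.random((4, 2))
        y = rng.normal(1.0, 1.0, 4)
        h = hyper([0.6, 1.3], sf2=2.0, sn2=0.2, mean=1.0)
        cov = 2.0 * Matern(length_scale=h.length_scales, nu=2.5)(X)
        cov += (0.2 + gp.JITTER_REL * 2.0) * np.eye(4)
        ref = multivariate_normal(mean=np.full(4, 1.0), cov=cov).logpdf(y)
        lml = gp.log_marginal_likelihood(X, y, h)
        assert lml == pytest.approx(ref, abs=1e-8)

    def test_duplicate_observation_consistent_with_oracle(self, rng):
        X = rng.random((5, 2))
        X[4] = X[0]
        y = rng.normal(0, 1, 5)
        y[4] = y[0]
        h = hyper([0.8, 0.8], sf2=1.0, sn2=0.3)
        cov = Matern(length_scale=h.length_scales, nu=2.5)(X)
        cov += (0.3 + gp.JITTER_REL) * np.eye(5)
        ref = multivariate_normal(mean=np.zeros(5), cov=cov).logpdf(y)
        assert gp.log_marginal_likelihood(X, y, h) == pytest.approx(ref, abs=1e-8)


class TestFit:
    def test_analytic_gradient_matches_finite_differences(self, rng):
        X = rng.random((10, 3))
        y = rng.normal(2.0, 1.0, 10)
        D2 = (X[:, None, :] - X[None, :, :]) ** 2
        theta = np.concatenate([np.log([0.5, 1.0, 2.0]), [np.log(1.2), np.log(0.1), 1.8]])
        f0, g = gp._lml_and_grad(theta, D2, y)
        eps = 1e-6
        for k in range(len(theta)):
            t = theta.copy()
            t[k] += eps
            fp, _ = gp._lml_and_grad(t, D2, y)
            assert (fp - f0) / eps == pytest.approx(g[k], rel=1e-3, abs=1e-6)

    def test_recovers_constant_function(self):
        X = np.linspace(0, 1, 10).reshape(-1, 1)
        y = np.full(10, 7.0)
        m = gp.fit(X, y, restarts=4, seed=0)
        mu, _ = gp.predict(m, np.array([[0.37], [0.91]]))
        np.testing.assert_allclose(mu, 7.0, atol=0.05)

    def test_recovers_smooth_function_from_noise_free_samples(self):
        X = np.linspace(0, 1, 25).reshape(-1, 1)
        y = np.sin(2 * np.pi * X[:, 0])
        m = gp.fit(X, y, restarts=8, seed=1)
        Xq = np.linspace(0.005, 0.995, 100).reshape(-1, 1)
        mu, _ = gp.predict(m, Xq)
        rmse = np.sqrt(np.mean((mu - np.sin(2 * np.pi * Xq[:, 0])) ** 2))
        assert rmse < 0.05

    def test_deterministic_under_seed(self, rng):
        X = rng.random((15, 2))
        y = rng.normal(0, 1, 15)
        m1 = gp.fit(X, y, restarts=4, seed=5)
        m2 = gp.fit(X, y, restarts=4, seed=5)
        np.testing.assert_array_equal(m1.hyper.length_scales, m2.hyper.length_scales)
        assert m1.hyper.signal_var == m2.hyper.signal_var
        assert m1.hyper.noise_var == m2.hyper.noise_var

    def test_noise_floor_is_respected(self, rng):
        X = rng.random((20, 2))
        y = rng.normal(0, 1, 20)
        m = gp.fit(X, y, restarts=4, seed=0, noise_floor_var=0.25)
        assert m.hyper.noise_var >= 0.25

    def test_length_scale_recovery_from_prior_sample(self):
        # data simulated from the GP prior itself; fitted scales should land
        # within a factor of 3 of the generating scales
        rng = np.random.default_rng(0)
        true = hyper([0.2, 0.6], sf2=2.0, sn2=1e-4, mean=0.0)
        X = rng.random((100, 2))
        K = gp.matern52_gram(X, X, true) + 1e-4 * np.eye(100)
        y = rng.multivariate_normal(np.zeros(100), K)
        m = gp.fit(X, y, restarts=8, seed=0)
        for fitted, gen in zip(m.hyper.length_scales, true.length_scales):
            assert gen / 3 <= fitted <= gen * 3

    def test_too_few_observations_raises(self):
        with pytest.raises(ValueError):
            gp.fit(np.zeros((1, 2)), np.zeros(1))


class TestCheckpoint:
    def test_json_round_trip_reproduces_predictions(self, rng):
        X = rng.random((10, 3))
        y = rng.normal(3.0, 1.0, 10)
        m = gp.fit(X, y, restarts=2, seed=0)
        m2 = GPModel.from_json(m.to_json())
        Xq = rng.random((5, 3))
        np.testing.assert_allclose(gp.predict(m, Xq)[0], gp.predict(m2, Xq)[0], atol=1e-12)
        np.testing.assert_allclose(gp.predict(m, Xq)[1], gp.predict(m2, Xq)[1], atol=1e-12)
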