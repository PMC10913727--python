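import numpy as np
import pytest

from mssid.identify import extended_observability, extended_reachability
from mssid.moments import (
    MomentTransformError,
    SilentChannelError,
    assemble_hankel,
    assemble_hankel_from_lags,
    compute_empirical_moments,
    compute_lag_moments,
    interpolate_continuous,
    standardize_continuous,
    transform_moments,
)
from mssid.params import pset_from_nset
from mssid.simulate import MultimodalData, simulate_data


def make_data(N, y, M=1):
    T = N.shape[0] if N.size else y.shape[0]
    mask = np.ones(T, dtype=bool)
    if M > 1:
        mask = np.zeros(T, dtype=bool)
        mask[::M] = True
        y = y.copy()
        y[~mask] = np.nan
    return MultimodalData(N=N.astype(np.int64), y=y, mask=mask, M=M)


class TestInterpolation:
    def test_identity_at_M1(self):
        y = np.random.default_rng(0).standard_normal((50, 3))
        assert np.array_equal(interpolate_continuous(y, 1), y)

    def test_constant_preserved(self):
        y = np.full((200, 2), 3.7)
        y[np.arange(200) % 5 != 0] = np.nan
        out = interpolate_continuous(y, 5)
        assert np.allclose(out, 3.7, atol=1e-6)

    def test_bandlimited_sinusoid_reconstruction(self):
        t = np.arange(2000)
        true = np.sin(2 * np.pi * t / 40.0)[:, None]
        sparse = true.copy()
        sparse[t % 5 != 0] = np.nan
        out = interpolate_continuous(sparse, 5)
        interior = slice(100, -100)
        rmse = np.linalg.norm(out[interior] - true[interior]) / np.linalg.norm(true[interior])
        assert rmse < 1e-2

    def test_observed_samples_pass_through(self):
        rng = np.random.default_rng(1)
        y = rng.standard_normal((100, 2))
        y[np.arange(100) % 4 != 0] = np.nan
        out = interpolate_continuous(y, 4)
        assert np.allclose(out[::4], y[::4])

    def test_too_few_samples_raises(self):
        y = np.full((10, 1), np.nan)
        y[::5] = 1.0
        with pytest.raises(ValueError, match="filter"):
            interpolate_continuous(y, 5)


class TestStackedMoments:
    def test_constant_counts_degenerate(self):
        N = np.full((30, 2), 3)
        y = np.random.default_rng(0).standard_normal((30, 1))
        em = compute_empirical_moments(make_data(N, y), h_z=2, h_y=2)
        assert np.allclose(em.mu_N, 3.0)
        assert np.allclose(em.Sigma_NN, 0.0)

    def test_matches_bruteforce_stacked_covariance(self):
        """Streamed windowed-Gram computation equals the naive double loop."""
        rng = np.random.default_rng(3)
        T, n_z, n_y, h = 24, 2, 3, 2
        N = rng.poisson(1.0, size=(T, n_z))
        y = rng.standard_normal((T, n_y))
        em = compute_empirical_moments(make_data(N, y), h_z=h, h_y=h)
        # naive: build stacked vectors at each anchor, then sample covariances
        anchors = range(h, T - h + 1)
        def stack(series, t):
            fut = np.concatenate([series[t + i] for i in range(h)])
            past = np.concatenate([series[t - 1 - i] for i in range(h)])
            return np.concatenate([fut, past])
        Nfp = np.array([stack(N.astype(float), t) for t in anchors])
        yfp = np.array([stack(y, t) for t in anchors])
        n = Nfp.shape[0]
        cN = Nfp - Nfp.mean(axis=0)
        cy = yfp - yfp.mean(axis=0)
        assert np.allclose(em.mu_N, Nfp.mean(axis=0))
        assert np.allclose(em.Sigma_NN, cN.T @ cN / (n - 1), atol=1e-12)
        assert np.allclose(em.Sigma_yy, cy.T @ cy / (n - 1), atol=1e-12)
        assert np.allclose(em.Sigma_Ny, cN.T @ cy / (n - 1), atol=1e-12)

    def test_iid_series_has_no_lag_structure(self):
        rng = np.random.default_rng(4)
        T = 30_000
        y = rng.standard_normal((T, 1))
        N = rng.poisson(1.0, size=(T, 1))
        em = compute_empirical_moments(make_data(N, y), h_z=2, h_y=2)
        off = em.Sigma_yy[0, 1]  # Cov[y_t, y_{t+1}]
        assert abs(off) < 5 / np.sqrt(T)

    def test_silent_channel_rejected(self):
        N = np.zeros((40, 2), dtype=int)
        N[:, 0] = 1
        y = np.random.default_rng(0).standard_normal((40, 1))
        with pytest.raises(SilentChannelError, match="1"):
            compute_empirical_moments(make_data(N, y), h_z=2, h_y=2)

    def test_translation_consistency(self):
        rng = np.random.default_rng(5)
        N = rng.poisson(1.0, size=(200, 1))
        y = rng.standard_normal((200, 2))
        em1 = compute_empirical_moments(make_data(N, y), 2, 2)
        em2 = compute_empirical_moments(make_data(N, y + 10.0), 2, 2)
        assert np.allclose(em2.mu_y, em1.mu_y + 10.0)
        assert np.allclose(em2.Sigma_yy, em1.Sigma_yy, atol=1e-10)
        assert np.allclose(em2.Sigma_Ny, em1.Sigma_Ny, atol=1e-10)


class TestTransform:
    def test_pure_poisson_variance_forces_zero_log_rate_variance(self):
        # mu = 2, Var[N] = 2 -> mu_z = log 2 and Sigma_zz = 0
        class EM:
            mu_N = np.array([2.0])
            Sigma_NN = np.array([[2.0]])
            Sigma_Ny = np.zeros((1, 0))
            Sigma_yy = np.zeros((0, 0))
        mu_z, Sigma_zz, _, _ = transform_moments(EM())
        assert np.isclose(mu_z[0], np.log(2.0))
        assert np.isclose(Sigma_zz[0, 0], 0.0, atol=1e-12)

    def test_cross_covariance_is_direct_division(self):
        class EM:
            mu_N = np.array([4.0])
            Sigma_NN = np.array([[4.0]])
            Sigma_Ny = np.array([[2.0]])
            Sigma_yy = np.zeros((1, 1))
        _, _, Sigma_zy, _ = transform_moments(EM())
        assert np.isclose(Sigma_zy[0, 0], 0.5)

    def test_monte_carlo_forward_oracle(self):
        """Sampling the generative chain and inverting recovers the moments."""
        rng = np.random.default_rng(8)
        n = 1_000_000
        z = rng.normal(0.5, np.sqrt(0.3), size=n)
        y = z + rng.normal(0, 0.5, size=n)
        N = rng.poisson(np.exp(z))
        class EM:
            mu_N = np.array([N.mean()])
            Sigma_NN = np.atleast_2d(np.cov(N))
            Sigma_Ny = np.atleast_2d(np.cov(N, y)[0, 1])
            Sigma_yy = np.atleast_2d(np.cov(y))
        mu_z, Sigma_zz, Sigma_zy, _ = transform_moments(EM())
        assert abs(mu_z[0] - 0.5) < 0.01
        assert abs(Sigma_zz[0, 0] - 0.3) < 0.02
        assert abs(Sigma_zy[0, 0] - 0.3) < 0.02  # Cov[z, y] = Var[z]

    def test_nonpositive_mean_rejected(self):
        class EM:
            mu_N = np.array([0.0])
            Sigma_NN = np.array([[1.0]])
            Sigma_Ny = np.zeros((1, 0))
            Sigma_yy = np.zeros((0, 0))
        with pytest.raises(MomentTransformError):
            transform_moments(EM())

    def test_heavy_clipping_warns(self):
        class EM:
            mu_N = np.array([1.0, 1.0])
            Sigma_NN = np.array([[1.0, -2.0], [-2.0, 1.0]])  # impossible moments
            Sigma_Ny = np.zeros((2, 0))
            Sigma_yy = np.zeros((0, 0))
        with pytest.warns(RuntimeWarning, match="floored"):
            transform_moments(EM())


class TestHankelAssembly:
    def test_analytic_factorization_oracle(self, small_model):
        """Population moments built from the model factor exactly as O_w C_w."""
        p = pset_from_nset(small_model)
        h = 4
        O = extended_observability(p.A, p.C_z, p.C_y, h, h)
        Cw = extended_reachability(p.A, p.G_z, p.G_y, h, h)
        H_true = O @ Cw
        # long simulation, lag-based estimation
        d = simulate_data(small_model, T=400_000, M=1, seed=12)
        lm = compute_lag_moments(d, h, h)
        tm = assemble_hankel_from_lags(lm)
        assert np.linalg.norm(tm.H_w - H_true) / np.linalg.norm(H_true) < 0.05
        assert np.linalg.norm(tm.Lambda0 - p.Lambda0) / np.linalg.norm(p.Lambda0) < 0.05

    def test_hankel_shape(self, small_model):
        d = simulate_data(small_model, T=2_000, M=1, seed=1)
        em = compute_empirical_moments(d, 3, 4)
        tm = assemble_hankel(em)
        dim = 3 * small_model.n_z + 4 * small_model.n_y
        assert tm.H_w.shape == (dim, dim)

    def test_stacked_and_lag_paths_agree_at_full_rate(self, small_model):
        d = simulate_data(small_model, T=60_000, M=1, seed=2)
        tm1 = assemble_hankel(compute_empirical_moments(d, 3, 3))
        tm2 = assemble_hankel_from_lags(compute_lag_moments(d, 3, 3))
        assert np.linalg.norm(tm1.H_w - tm2.H_w) / np.linalg.norm(tm1.H_w) < 0.01
        assert np.allclose(tm1.Lambda0, tm2.Lambda0, rtol=0.05, atol=1e-3)

    def test_multirate_lag_hankel_is_unbiased(self, study_model):
        """Stride-M Hankel from M=5 data matches its analytic factorization."""
        cfg, model, _ = study_model
        p = pset_from_nset(model)
        d = simulate_data(model, T=150_000, M=5, seed=31)
        lm = compute_lag_moments(d, 6, 6)
        tm = assemble_hankel_from_lags(lm)
        A, M = p.A, 5
        AM = np.linalg.matrix_power(A, M)
        O_rows, blk = [], p.C_z.copy()
        for _ in range(6):
            O_rows.append(blk); blk = blk @ A
        blk = p.C_y.copy()
        for _ in range(6):
            O_rows.append(blk); blk = blk @ AM
        C_cols, blk = [], p.G_z.copy()
        for _ in range(6):
            C_cols.append(blk); blk = A @ blk
        blk = np.linalg.matrix_power(A, M - 1) @ p.G_y
        for _ in range(6):
            C_cols.append(blk); blk = AM @ blk
        H_true = np.vstack(O_rows) @ np.hstack(C_cols)
        rel = np.linalg.norm(tm.H_w - H_true) / np.linalg.norm(H_true)
        assert rel < 0.1


class TestStandardize:
    def test_idempotent_on_standardized_input(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal((5000, 3))
        y = (y - y.mean(0)) / y.std(0, ddof=1)
        out, _, stats = standardize_continuous(y)
        assert np.allclose(out, y, atol=1e-10)

    def test_constant_channel_rejected(self):
        y = np.ones((100, 2))
        y[:, 0] = np.random.default_rng(0).standard_normal(100)
        with pytest.raises(ValueError, match="1"):
            standardize_continuous(y)

    def test_self_consistency_and_inverse(self):
        rng = np.random.default_rng(2)
        y = rng.normal(5, 3, size=(1000, 2))
        out, _, stats = standardize_continuous(y)
        assert np.allclose(out.mean(0), 0.0, atol=1e-12)
        assert np.allclose(out.std(0, ddof=1), 1.0, atol=1e-12)
        assert np.allclose(stats.inverse_transform(out), y, atol=1e-10)
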