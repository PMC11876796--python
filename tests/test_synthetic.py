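"""The synthetic generator: planted VAR dynamics, confounders, missingness."""

import numpy as np
import pytest
from scipy.linalg import solve_discrete_lyapunov

from stgate.core_types import SpatioTemporalSeries
from stgate.synthetic import (BURN_IN, MissingSpec, VarSpec, apply_missing,
                              companion_spectral_radius, default_var_spec,
                              inject_confounders, make_dataset,
                              ridge_recovery_auc, simulate_var,
                              training_mask_sampler)


def _spec(coeffs, T=60, noise_sd=1.0, seed=7):
    N, _, p = coeffs.shape
    return VarSpec(n_series=N, length=T, lag_order=p, coeffs=coeffs,
                   noise_sd=noise_sd, seed=seed)


class TestSimulateVar:
    def test_zero_coefficients_give_white_noise_and_empty_graph(self):
        spec = _spec(np.zeros((3, 3, 1)), T=4000)
        series, G = simulate_var(spec)
        assert G.sum() == 0
        # no serial correlation beyond Monte-Carlo error
        y = series.Y
        r1 = np.mean([np.corrcoef(y[i, :-1], y[i, 1:])[0, 1] for i in range(3)])
        assert abs(r1) < 3 / np.sqrt(y.shape[1])

    def test_matches_independent_recursion_oracle(self):
        # brute-force re-simulation with the same noise draws
        coeffs = np.zeros((2, 2, 2))
        coeffs[0, 0, 0] = 0.4
        coeffs[1, 0, 0] = 0.9
        coeffs[1, 1, 1] = -0.2
        spec = _spec(coeffs, T=50, seed=11)
        series, G = simulate_var(spec)
        rng = np.random.default_rng(11)
        N, p, total = 2, 2, 50 + BURN_IN + 2
        eps = rng.normal(0.0, 1.0, size=(N, total))
        Y = np.zeros((N, total))
        Y[:, :p] = eps[:, :p]
        for t in range(p, total):
            Y[:, t] = (coeffs[:, :, 0] @ Y[:, t - 1]
                       + coeffs[:, :, 1] @ Y[:, t - 2] + eps[:, t])
        assert np.allclose(series.Y, Y[:, -50:])
        assert np.array_equal(G, np.array([[1, 1], [0, 1]]))

    def test_var1_moments_match_yule_walker(self):
        A = np.array([[0.5, 0.2], [0.0, 0.3]])
        spec = _spec(A[:, :, None], T=200_000, seed=3)
        series, _ = simulate_var(spec)
        gamma0 = solve_discrete_lyapunov(A, np.eye(2))
        gamma1 = A @ gamma0
        emp0 = np.cov(series.Y)
        y = series.Y
        emp1 = (y[:, 1:] - y.mean(1, keepdims=True)) @ \
            (y[:, :-1] - y.mean(1, keepdims=True)).T / (y.shape[1] - 1)
        assert np.allclose(emp0, gamma0, atol=0.05)
        assert np.allclose(emp1, gamma1, atol=0.05)

    def test_nonstationary_coefficients_rejected(self):
        c = np.zeros((2, 2, 1))
        c[0, 0, 0] = 1.05
        with pytest.raises(ValueError, match="spectral radius"):
            simulate_var(_spec(c))

    def test_seed_reproducibility(self):
        spec, A, _ = default_var_spec(5)
        y1, _ = simulate_var(spec)
        y2, _ = simulate_var(spec)
        assert np.array_equal(y1.Y, y2.Y)


class TestInjectConfounders:
    def test_identity_when_disabled(self, rng):
        Y = rng.normal(size=(4, 30))
        A = np.eye(4)
        G = np.zeros((4, 4), dtype=int)
        Yc, A2, edges = inject_confounders(Y, A, G, 0.0, 0, seed=1)
        assert np.array_equal(Yc.Y, Y) and np.array_equal(A2, A)
        assert edges == []

    def test_shortcut_count_and_disjointness(self):
        spec, A, _ = default_var_spec(2)
        Y, G = simulate_var(spec)
        _, A2, edges = inject_confounders(Y, A, G, 0.0, 3, seed=4)
        assert len(edges) == 3
        assert (A2 != 0).sum() == (A != 0).sum() + 3
        for i, j in edges:
            assert G[i, j] == 0 and G[j, i] == 0 and A[i, j] == 0

    def test_background_noise_raises_cross_correlation(self, rng):
        Y = rng.normal(size=(6, 400))
        G = np.zeros((6, 6), dtype=int)

        def mean_corr(y):
            c = np.corrcoef(y)
            return c[~np.eye(6, dtype=bool)].mean()

        quiet, _, _ = inject_confounders(Y, np.eye(6), G, 0.0, 0, seed=2)
        loud, _, _ = inject_confounders(Y, np.eye(6), G, 2.0, 0, seed=2)
        assert mean_corr(loud.Y) > mean_corr(quiet.Y)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            inject_confounders(np.zeros((2, 5)), np.eye(2),
                               np.zeros((2, 2)), -0.1, 0)


def _complete(N=100, T=100, seed=0):
    rng = np.random.default_rng(seed)
    return SpatioTemporalSeries(rng.normal(size=(N, T)), np.eye(N),
                                np.ones((N, T), dtype=int))


class TestApplyMissing:
    def test_zero_rate_is_identity(self):
        s = _complete(10, 10)
        out, emask = apply_missing(s, MissingSpec(point_rate=0.0, seed=1))
        assert np.array_equal(out.M, s.M) and emask.sum() == 0

    def test_rate_one_masks_everything(self):
        s = _complete(10, 10)
        out, emask = apply_missing(s, MissingSpec(point_rate=1.0, seed=1))
        assert out.M.sum() == 0
        assert np.array_equal(emask, s.M)

    def test_point_rate_within_binomial_bound(self):
        s = _complete(100, 100)
        out, emask = apply_missing(s, MissingSpec(point_rate=0.25, seed=5))
        frac = emask.mean()
        tol = 3 * np.sqrt(0.25 * 0.75 / 10_000)
        assert abs(frac - 0.25) < tol

    @pytest.mark.parametrize("mode", ["point", "block"])
    def test_never_unmasks(self, mode, rng):
        s = _complete(20, 60, seed=3)
        s.M = (rng.random((20, 60)) < 0.8).astype(int)
        spec = MissingSpec(mode=mode, point_rate=0.3,
                           block_temporal_rate=0.05,
                           block_spatial_rate=0.2, seed=9)
        out, emask = apply_missing(s, spec)
        assert np.all(out.M <= s.M)
        assert np.all(emask <= s.M)          # only held-out observed cells
        assert np.all(emask + out.M <= 1)    # disjoint from surviving mask

    def test_block_mode_produces_runs(self):
        s = _complete(30, 200)
        spec = MissingSpec(mode="block", block_temporal_rate=0.02,
                           block_spatial_rate=0.0, block_len_range=(4, 4),
                           seed=2)
        out, _ = apply_missing(s, spec)
        # masked cells come in multi-step runs (length-4 blocks, possibly
        # merged or truncated at the series end)
        gaps = 1 - out.M
        lengths = []
        for i in range(30):
            padded = np.r_[0, gaps[i], 0]
            starts = np.flatnonzero(np.diff(padded) == 1)
            ends = np.flatnonzero(np.diff(padded) == -1)
            lengths.extend(ends - starts)
        lengths = np.array(lengths)
        assert lengths.size > 0
        assert lengths.max() >= 4
        interior = lengths[:-1] if gaps[:, -1].any() else lengths
        assert np.mean(interior >= 4) > 0.9

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            MissingSpec(point_rate=1.5)


class TestTrainingMaskSampler:
    def test_expected_target_count(self):
        X = np.zeros((10, 10))
        M = np.ones((10, 10), dtype=int)
        rng = np.random.default_rng(0)
        counts = [training_mask_sampler(X, M, (0.5,), rng)[1].sum()
                  for _ in range(50)]
        assert abs(np.mean(counts) - 50) < 3 * np.sqrt(25) / np.sqrt(50)

    def test_missing_cells_never_loss_targets(self, rng):
        X = rng.normal(size=(8, 12))
        M = (rng.random((8, 12)) < 0.6).astype(int)
        for _ in range(10):
            m_in, m_loss, p = training_mask_sampler(X, M, (0.2, 0.5, 0.8), rng)
            assert np.all(m_loss <= M)
            assert np.all(m_in <= M)
            assert np.all(m_in + m_loss <= 1)

    def test_same_seed_same_masks(self, rng):
        X = rng.normal(size=(6, 9))
        M = np.ones((6, 9), dtype=int)
        a = training_mask_sampler(X, M, (0.5,), np.random.default_rng(3))
        b = training_mask_sampler(X, M, (0.5,), np.random.default_rng(3))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_empty_rates_rejected(self):
        with pytest.raises(ValueError):
            training_mask_sampler(np.zeros((2, 2)), np.ones((2, 2)), (),
                                  np.random.default_rng(0))


class TestDefaultStudy:
    def test_planted_graph_recoverable_by_ridge(self):
        data = make_dataset(0)
        auc = ridge_recovery_auc(data.clean.Y, data.G_true)
        assert auc > 0.9

    def test_dataset_is_reproducible_and_consistent(self):
        a = make_dataset(3)
        b = make_dataset(3)
        assert np.array_equal(a.series.X, b.series.X)
        assert np.array_equal(a.G_true, b.G_true)
        # planted edges are adjacency-supported; shortcuts are not causal
        tgt_src = a.G_true.T  # W-orientation
        assert np.all(a.series.A[tgt_src.astype(bool)] > 0)
        for i, j in a.shortcut_edges:
            assert a.G_true[i, j] == 0 and a.G_true[j, i] == 0
        assert companion_spectral_radius(a.var_spec.coeffs) < 1.0
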