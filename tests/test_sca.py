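"""Spatiotemporal causal attention against independent enumeration oracles."""

import numpy as np
import pytest

from stgate.autodiff import Tensor
from stgate.sca import (ScaParams, causal_probability, correlation_weights,
                        edges_from_adjacency, export_gate_state, gumbel_gate,
                        message_value, sca_forward)


# --------------------------------------------------------------------- oracles
def brute_force_alpha(H, A, params):
    """Softmax over explicitly enumerated (neighbor, time) pairs, per head."""
    N, T, d = H.shape
    hh, dh = params.n_heads, params.d // params.n_heads
    out = {}
    for i in range(N):
        nb = [j for j in range(N) if A[i, j] != 0]
        for t in range(T):
            for h in range(hh):
                sl = slice(h * dh, (h + 1) * dh)
                q = (H[i, t] @ params.Wq.data)[sl]
                scores = {(j, t2): float(q @ (H[j, t2] @ params.Wk.data)[sl])
                          / np.sqrt(dh) for j in nb for t2 in range(T)}
                mx = max(scores.values())
                z = sum(np.exp(s - mx) for s in scores.values())
                for key, s in scores.items():
                    out[(h, i, t) + key] = np.exp(s - mx) / z
    return out


def brute_force_sca(H, A, params, beta_lookup):
    """Triple sum of Eq-style gated attention with explicit normalization."""
    N, T, d = H.shape
    hh, dh = params.n_heads, params.d // params.n_heads
    alpha = brute_force_alpha(H, A, params)
    out = np.zeros((N, T, d))
    for i in range(N):
        nb = [j for j in range(N) if A[i, j] != 0]
        for t in range(T):
            for h in range(hh):
                sl = slice(h * dh, (h + 1) * dh)
                num, Z = np.zeros(dh), 0.0
                for j in nb:
                    for t2 in range(T):
                        a = alpha[(h, i, t, j, t2)]
                        b = beta_lookup(i, j, t, t2)
                        v = message_value(H[i, t], H[j, t2], params)[sl]
                        num += b * a * v
                        Z += b * a
                out[i, t, sl] = num / max(Z, 1e-8)
    return out


def _instance(seed, N=3, T=4, d=8, heads=2, density=0.6):
    rng = np.random.default_rng(seed)
    A = (rng.random((N, N)) < density).astype(float)
    np.fill_diagonal(A, 1.0)
    params = ScaParams(np.random.default_rng(seed + 1), d, n_heads=heads)
    H = rng.normal(size=(N, T, d))
    return H, A, params


class TestCorrelationWeights:
    def test_singleton_context(self):
        H, _, params = _instance(0, N=1, T=1)
        alpha, edges = correlation_weights(H, np.eye(1), params)
        assert np.allclose(alpha, 1.0)

    def test_uniform_when_query_projection_is_zero(self):
        H, A, params = _instance(1)
        params.Wq.data = np.zeros_like(params.Wq.data)
        alpha, edges = correlation_weights(H, A, params)
        for i in range(3):
            size = (np.array(edges.tgt) == i).sum() * 4
            sel = alpha[:, edges.tgt == i, 0, :]
            assert np.allclose(sel, 1.0 / size)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration(self, seed):
        H, A, params = _instance(seed)
        alpha, edges = correlation_weights(H, A, params)
        ref = brute_force_alpha(H, A, params)
        for e in range(edges.n_pairs):
            for t in range(4):
                for t2 in range(4):
                    for h in range(params.n_heads):
                        key = (h, edges.tgt[e], t, edges.src[e], t2)
                        assert np.isclose(alpha[h, e, t, t2], ref[key],
                                          atol=1e-10)

    def test_normalization_per_query(self):
        H, A, params = _instance(2)
        alpha, edges = correlation_weights(H, A, params)
        for i in range(3):
            total = alpha[:, edges.tgt == i].sum(axis=(1, 3))
            assert np.allclose(total, 1.0, atol=1e-8)

    def test_empty_neighborhood_rejected(self):
        A = np.eye(3)
        A[1, 1] = 0.0
        with pytest.raises(ValueError, match="neighborhood"):
            edges_from_adjacency(A)


class TestCausalProbability:
    def test_zero_weights_give_half(self):
        H, A, params = _instance(3)
        for w in (params.wc_q, params.wc_k):
            w.data = np.zeros_like(w.data)
        rho, _ = causal_probability(H, A, params)
        assert np.allclose(rho, 0.5)

    def test_sigmoid_saturation_under_scaling(self):
        H, A, params = _instance(4)
        rho0, _ = causal_probability(H, A, params)
        params.wc_q.data *= 500.0
        params.wc_k.data *= 500.0
        rho1, _ = causal_probability(H, A, params)
        saturated = (rho1 < 1e-3) | (rho1 > 1 - 1e-3)
        assert saturated.mean() > 0.95
        # sign-preserving scaling never flips a verdict
        assert np.all((rho1 >= 0.5) == (rho0 >= 0.5))

    def test_matches_direct_formula(self):
        H, A, params = _instance(5)
        rho, edges = causal_probability(H, A, params)
        for e in range(edges.n_pairs):
            for t in range(4):
                for t2 in range(4):
                    hq = H[edges.tgt[e], t] @ params.Wqc.data
                    hk = H[edges.src[e], t2] @ params.Wkc.data
                    logit = (hq @ params.wc_q.data
                             + hk @ params.wc_k.data).item()
                    assert np.isclose(rho[e, t, t2],
                                      1 / (1 + np.exp(-logit)), atol=1e-9)
        assert np.all((rho > 0) & (rho < 1))


class TestGumbelGate:
    def test_symmetric_draws_at_half(self):
        u = np.full((3, 3), 0.37)
        beta = gumbel_gate(Tensor(np.full((3, 3), 0.5)), 0.5, u, u)
        assert np.allclose(beta.data, 0.5)

    def test_low_temperature_limit(self):
        u = np.full((2,), 0.6)
        beta = gumbel_gate(Tensor(np.full((2,), 0.9)), 1e-3, u, u)
        assert np.all(beta.data > 1 - 1e-6)

    def test_gumbel_max_property(self):
        # as tau -> 0, P(beta > 0.5) -> rho
        rho = 0.7
        n = 100_000
        rng = np.random.default_rng(8)
        u1, u2 = rng.random(n), rng.random(n)
        beta = gumbel_gate(Tensor(np.full(n, rho)), 0.1, u1, u2)
        p = (beta.data > 0.5).mean()
        assert abs(p - rho) < 3 * np.sqrt(rho * (1 - rho) / n)

    def test_extreme_uniforms_are_clamped(self):
        beta = gumbel_gate(Tensor(np.array([0.5])), 0.5,
                           np.array([0.0]), np.array([1.0]))
        assert np.isfinite(beta.data).all()

    def test_differentiable_in_rho(self):
        rho = Tensor(np.array([0.3, 0.8]), requires_grad=True)
        beta = gumbel_gate(rho, 0.5, np.array([0.4, 0.6]),
                           np.array([0.7, 0.2]))
        beta.sum().backward()
        eps = 1e-6
        for k in range(2):
            rp = rho.data.copy()
            rp[k] += eps
            bp = gumbel_gate(Tensor(rp), 0.5, np.array([0.4, 0.6]),
                             np.array([0.7, 0.2])).data
            rm = rho.data.copy()
            rm[k] -= eps
            bm = gumbel_gate(Tensor(rm), 0.5, np.array([0.4, 0.6]),
                             np.array([0.7, 0.2])).data
            assert np.isclose(rho.grad[k], (bp[k] - bm[k]) / (2 * eps),
                              atol=1e-5)


class TestMessageValue:
    def test_zero_parameters_give_zero(self):
        _, _, params = _instance(6)
        for w in (params.W1q, params.W1k, params.b1, params.W2, params.b2):
            w.data = np.zeros_like(w.data)
        v = message_value(np.ones(8), np.ones(8), params)
        assert np.allclose(v, 0.0)

    def test_depends_on_query(self, rng):
        _, _, params = _instance(7)
        hk = rng.normal(size=8)
        v1 = message_value(rng.normal(size=8), hk, params)
        v2 = message_value(rng.normal(size=8), hk, params)
        assert not np.allclose(v1, v2)

    def test_matches_concatenated_mlp(self, rng):
        _, _, params = _instance(8)
        hq, hk = rng.normal(size=8), rng.normal(size=8)
        W1 = np.vstack([params.W1q.data, params.W1k.data])  # (2d, d)
        hidden = np.maximum(np.concatenate([hq, hk]) @ W1 + params.b1.data, 0)
        ref = hidden @ params.W2.data + params.b2.data
        assert np.allclose(message_value(hq, hk, params), ref, atol=1e-12)


class TestScaForward:
    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_with_hard_gates(self, seed):
        H, A, params = _instance(seed + 10)
        out, state = sca_forward(H, A, params, mode="eval")
        lut = {}
        for e in range(state.edges.n_pairs):
            lut[(state.edges.tgt[e], state.edges.src[e])] = state.beta[0, e]
        ref = brute_force_sca(H, A, params,
                              lambda i, j, t, t2: lut[(i, j)][t, t2])
        assert np.allclose(out.data, ref, atol=1e-8)

    def test_open_gates_equal_plain_attention_and_unit_Z(self):
        H, A, params = _instance(20)
        out, state = sca_forward(H, A, params, mode="eval", no_gate=True)
        ref = brute_force_sca(H, A, params, lambda *a: 1.0)
        assert np.allclose(out.data, ref, atol=1e-10)
        # Z = sum of beta*alpha = sum of alpha = 1 per query and head
        edges = state.edges
        for i in range(3):
            z = (state.beta[0, edges.tgt == i][None]
                 * state.alpha[0][:, edges.tgt == i]).sum(axis=(1, 3))
            assert np.allclose(z, 1.0, atol=1e-9)

    def test_all_closed_gates_flagged_and_zero(self):
        H, A, params = _instance(21)
        # positive embeddings + negative query scorer => logit < 0 everywhere
        H = np.abs(H) + 0.1
        params.Wqc.data = np.eye(8)
        params.wc_q.data = np.full_like(params.wc_q.data, -5.0)
        params.Wkc.data = np.zeros_like(params.Wkc.data)
        out, state = sca_forward(H, A, params, mode="eval")
        assert np.all(state.rho < 0.5)
        assert state.all_closed.all()
        assert np.allclose(out.data, 0.0)

    def test_train_mode_uses_soft_gates_and_is_replayable(self):
        H, A, params = _instance(22)
        rng = np.random.default_rng(5)
        out1, s1 = sca_forward(H, A, params, mode="train", rng=rng)
        assert not s1.hard
        assert np.all((s1.beta > 0) & (s1.beta < 1))
        out2, s2 = sca_forward(H, A, params, mode="train",
                               rng=np.random.default_rng(5))
        assert np.allclose(out1.data, out2.data)

    def test_locality_non_neighbor_perturbation_is_invisible(self):
        H, A, params = _instance(23, N=4, density=0.3)
        A[0, 3] = 0.0  # ensure 3 is not a neighbor of 0
        out1, _ = sca_forward(H, A, params, mode="eval")
        H2 = H.copy()
        H2[3] += 10.0
        out2, _ = sca_forward(H2, A, params, mode="eval")
        assert np.allclose(out1.data[0], out2.data[0], atol=1e-10)

    def test_permutation_equivariance(self):
        H, A, params = _instance(24, N=4)
        perm = np.array([2, 0, 3, 1])
        out, _ = sca_forward(H, A, params, mode="eval")
        out_p, _ = sca_forward(H[perm], A[np.ix_(perm, perm)], params,
                               mode="eval")
        assert np.allclose(out.data[perm], out_p.data, atol=1e-8)

    def test_constrained_mode_ignores_future_keys(self):
        H, A, params = _instance(25)
        out1, state = sca_forward(H, A, params, mode="eval", constrained=True)
        H2 = H.copy()
        H2[:, -1, :] += 5.0  # perturb the last step
        out2, _ = sca_forward(H2, A, params, mode="eval", constrained=True)
        assert np.allclose(out1.data[:, :-1], out2.data[:, :-1], atol=1e-8)
        assert np.all(state.valid == np.tril(np.ones((4, 4), dtype=bool)))

    def test_score_count_is_neighbor_restricted(self):
        H, A, params = _instance(26, N=5, density=0.4)
        _, state = sca_forward(H, A, params, mode="eval")
        degrees = (A != 0).sum(axis=1)
        assert state.alpha.shape[2] == degrees.sum()  # Σ|N(i)| pairs, × T²

    def test_gate_state_export(self, tmp_path):
        import pandas as pd
        H, A, params = _instance(27)
        _, state = sca_forward(H, A, params, mode="eval")
        export_gate_state(state, tmp_path / "gates.tsv")
        df = pd.read_csv(tmp_path / "gates.tsv", sep="\t")
        assert len(df) == state.edges.n_pairs * 16
        assert set(df.columns) >= {"rho", "beta", "alpha", "query_node",
                                   "key_node"}
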