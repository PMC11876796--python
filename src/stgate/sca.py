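"""Spatiotemporal Causal Attention (SCA).

Each query point (node i, time t) attends over the full time range of its
graph neighbors N(i) = {i' : A[i, i'] != 0}.  Two scorers run side by side:

* a correlation scorer — scaled dot-product attention weights α, softmax over
  the query's whole context {(i', t') : i' ∈ N(i), t' = 0..T-1};
* a causal gate — a learned Bernoulli probability ρ per (query, key) pair,
  reparameterized with Gumbel-Softmax noise into a soft gate β during
  training and hardened to 1[ρ ≥ 0.5] at evaluation.

The output for a query is the gated, renormalized message sum
``h_out = (1/Z) Σ β·α·v`` with ``Z = Σ β·α`` (floored at 1e-8), so Z ≤ 1 and
Z = 1 exactly when every gate is open.  Messages v are an MLP of the
concatenated query and key embeddings.  α is multi-head; the gate ρ is shared
across heads — one causal verdict per point pair.

Context is restricted to graph neighbors, never all node pairs, so the score
count is Σ_i |N(i)|·T² rather than N²T².
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, maximum_scalar, segment_sum
from .nn import Module, glorot

__all__ = [
    "EdgeIndex",
    "ScaParams",
    "GateState",
    "edges_from_adjacency",
    "gumbel_gate",
    "sca_forward",
    "correlation_weights",
    "causal_probability",
    "message_value",
    "export_gate_state",
]

Z_FLOOR = 1e-8
U_CLAMP = 1e-6   # uniform draws are clamped into [U_CLAMP, 1-U_CLAMP]
RHO_CLAMP = 1e-4  # rho kept inside (0,1): finite Gumbel logits, recoverable gates


@dataclass
class EdgeIndex:
    """Directed (target, source) node pairs with A[target, source] != 0."""

    tgt: np.ndarray
    src: np.ndarray
    n_nodes: int

    @property
    def n_pairs(self) -> int:
        return len(self.tgt)


def edges_from_adjacency(A: np.ndarray) -> EdgeIndex:
    A = np.asarray(A)
    pairs = np.argwhere(A != 0)
    N = A.shape[0]
    degrees = np.bincount(pairs[:, 0], minlength=N)
    if np.any(degrees == 0):
        i = int(np.argmin(degrees))
        raise ValueError(f"node {i} has an empty neighborhood; "
                         f"adjacency needs self-loops (A[i,i] > 0)")
    return EdgeIndex(tgt=pairs[:, 0].astype(np.int64),
                     src=pairs[:, 1].astype(np.int64), n_nodes=N)


class ScaParams(Module):
    """Parameters of one SCA layer."""

    def __init__(self, rng: np.random.Generator, d: int, n_heads: int = 4,
                 tau: float = 0.5):
        if tau <= 0:
            raise ValueError(f"tau must be positive, got {tau}")
        if d % n_heads:
            raise ValueError(f"d={d} not divisible by n_heads={n_heads}")
        self.Wq = glorot(rng, d, d)
        self.Wk = glorot(rng, d, d)
        # gate scorer: rho = sigmoid(Wc · [Wqc h_q ; Wkc h_k]); Wc is split
        # into its query and key halves so no concatenation is materialized
        self.Wqc = glorot(rng, d, d)
        self.Wkc = glorot(rng, d, d)
        self.wc_q = glorot(rng, 2 * d, 1, shape=(d, 1))
        self.wc_k = glorot(rng, 2 * d, 1, shape=(d, 1))
        # message MLP 2d -> d -> d; first layer stored as query/key halves
        self.W1q = glorot(rng, 2 * d, d, shape=(d, d))
        self.W1k = glorot(rng, 2 * d, d, shape=(d, d))
        self.b1 = Tensor(np.zeros(d), requires_grad=True)
        self.W2 = glorot(rng, d, d)
        self.b2 = Tensor(np.zeros(d), requires_grad=True)
        self.n_heads = n_heads
        self.tau = tau
        self.d = d


@dataclass
class GateState:
    """Gate and attention values of one SCA forward pass.

    Arrays are indexed (batch, pair, t_query, t_key); ``alpha`` carries an
    extra head axis after batch.  ``rho_tensor`` stays attached to the
    autodiff graph so the training loss can penalize it.
    """

    edges: EdgeIndex
    rho: np.ndarray                    # (B, P, T, T)
    beta: np.ndarray                   # (B, P, T, T) soft or hard
    alpha: np.ndarray                  # (B, H, P, T, T)
    gumbel_u: tuple[np.ndarray, np.ndarray] | None
    hard: bool
    all_closed: np.ndarray             # (B, N, T) queries with every gate shut
    valid: np.ndarray                  # (T, T) context validity (time constraint)
    rho_tensor: Tensor | None = None

    def rho_values(self) -> np.ndarray:
        """Gate probabilities over the valid context, flattened."""
        return self.rho[..., self.valid].ravel()


def gumbel_gate(rho: Tensor | np.ndarray, tau: float,
                u1: np.ndarray, u2: np.ndarray) -> Tensor:
    """Binary Gumbel-Softmax relaxation of β ~ Bernoulli(ρ).

    β = softmax([(log ρ + g₁)/τ, (log(1-ρ) + g₂)/τ])[0] with Gumbel noise
    g = -log(-log u).  Differentiable in ρ; uniforms are clamped away from
    {0, 1} before the double logarithm.
    """
    rho = rho if isinstance(rho, Tensor) else Tensor(rho)
    dt = rho.data.dtype
    g1 = -np.log(-np.log(np.clip(u1, U_CLAMP, 1 - U_CLAMP))).astype(dt)
    g2 = -np.log(-np.log(np.clip(u2, U_CLAMP, 1 - U_CLAMP))).astype(dt)
    # stable two-way softmax: beta = sigmoid((logit(rho) + g1 - g2) / tau),
    # fused into one op — dβ/dρ = β(1-β) / (τ ρ(1-ρ))
    r = rho.data
    with np.errstate(over="ignore", divide="ignore"):
        logits = (np.log(r) - np.log1p(-r) + (g1 - g2)) * (1.0 / tau)
        val = 1.0 / (1.0 + np.exp(-logits))
    out = Tensor(val, parents=(rho,))

    def bw(g):
        rho._accum(g * (val * (1.0 - val)) / (tau * r * (1.0 - r)))
    out._backward = bw if out.requires_grad else None
    return out


def _split_heads(x: Tensor, n_heads: int) -> Tensor:
    # (B, N, T, d) -> (B, H, N, T, dh)
    B, N, T, d = x.shape
    return x.reshape(B, N, T, n_heads, d // n_heads).transpose(0, 3, 1, 2, 4)


def _time_validity(T: int, constrained: bool) -> np.ndarray:
    if not constrained:
        return np.ones((T, T), dtype=bool)
    return np.tril(np.ones((T, T), dtype=bool))  # keys limited to t' <= t


def _alpha(H: Tensor, edges: EdgeIndex, params: ScaParams,
           valid: np.ndarray) -> Tensor:
    """Group softmax over each query's context; Σ_context α = 1 per head."""
    q = _split_heads(H @ params.Wq, params.n_heads).take(edges.tgt, axis=2)
    k = _split_heads(H @ params.Wk, params.n_heads).take(edges.src, axis=2)
    dh = params.d // params.n_heads
    scores = (q @ k.swapaxes(-1, -2)) * (1.0 / math.sqrt(dh))  # (B,H,P,T,T)
    s = scores.data
    dt = s.dtype
    if not valid.all():
        s = s + np.where(valid, 0.0, -1e30).astype(dt)
    B, Hh, P, T, _ = s.shape
    tgt, N = edges.tgt, edges.n_nodes
    # fused grouped softmax: only alpha survives to backward
    m = np.full((B, Hh, N, T), -np.inf, dtype=dt)
    np.maximum.at(m, (slice(None), slice(None), tgt), s.max(axis=-1))
    e = np.exp(s - np.take(m, tgt, axis=2)[..., None])
    denom = np.zeros((B, Hh, N, T), dtype=dt)
    np.add.at(denom, (slice(None), slice(None), tgt), e.sum(axis=-1))
    alpha = e / np.take(denom, tgt, axis=2)[..., None]
    out = Tensor(alpha, parents=(scores,))

    def bw(g):
        inner = np.zeros((B, Hh, N, T), dtype=dt)
        np.add.at(inner, (slice(None), slice(None), tgt),
                  (alpha * g).sum(axis=-1))
        scores._accum(alpha * (g - np.take(inner, tgt, axis=2)[..., None]))
    out._backward = bw if out.requires_grad else None
    return out


def _rho(H: Tensor, edges: EdgeIndex, params: ScaParams) -> Tensor:
    rq = (H @ params.Wqc) @ params.wc_q   # (B, N, T, 1)
    rk = (H @ params.Wkc) @ params.wc_k
    rq_e = rq.take(edges.tgt, axis=1)                      # (B, P, T, 1)
    rk_e = rk.take(edges.src, axis=1).swapaxes(-1, -2)     # (B, P, 1, T)
    logits = rq_e + rk_e
    # clamped sigmoid: rho strictly inside (0,1) so saturated gates keep a
    # finite Gumbel logit and a nonzero gradient to recover through
    with np.errstate(over="ignore"):  # exp overflow saturates to 0, then clips
        val = np.clip(1.0 / (1.0 + np.exp(-logits.data)),
                      RHO_CLAMP, 1.0 - RHO_CLAMP)
    out = Tensor(val, parents=(logits,))

    def bw(g):
        logits._accum(g * (val * (1.0 - val)))
    out._backward = bw if out.requires_grad else None
    return out                                             # (B, P, T, T)


def _gated_message_mix(q1: Tensor, k1: Tensor, w: Tensor) -> Tensor:
    """Fused Σ_{t'} w · relu(q1 ⊕ k1): the message MLP's hidden layer
    contracted against the gated attention weights.

    q1: (B,P,T,d) query half (bias folded in); k1: (B,P,T',d) key half;
    w: (B,P,T,H,T') gated weights.  Returns (B,P,T,H,d).  Only the post-ReLU
    pair tensor is materialized; its activation mask drives the backward.
    """
    hidden = np.maximum(q1.data[:, :, :, None, :] + k1.data[:, :, None, :, :],
                        0.0)                                  # (B,P,T,T',d)
    out = Tensor(w.data @ hidden, parents=(q1, k1, w))

    def bw(g):
        if w.requires_grad:
            w._accum(g @ np.swapaxes(hidden, -1, -2))
        d_hidden = np.swapaxes(w.data, -1, -2) @ g
        d_hidden *= hidden > 0
        if q1.requires_grad:
            q1._accum(d_hidden.sum(axis=3))
        if k1.requires_grad:
            k1._accum(d_hidden.sum(axis=2))
    out._backward = bw if out.requires_grad else None
    return out


def sca_forward(H: Tensor | np.ndarray, A: np.ndarray | EdgeIndex,
                params: ScaParams, mode: str = "eval",
                rng: np.random.Generator | None = None,
                no_gate: bool = False, constrained: bool = False
                ) -> tuple[Tensor, GateState]:
    """One SCA pass.  ``H`` is (B, N, T, d) or (N, T, d).

    ``mode='train'`` samples soft Gumbel gates (requires ``rng``);
    ``mode='eval'`` hardens gates deterministically at ρ ≥ 0.5.
    ``no_gate`` forces β ≡ 1 (the gateless-attention ablation).
    """
    H = H if isinstance(H, Tensor) else Tensor(H)
    squeeze = H.ndim == 3
    if squeeze:
        H = H.expand_dims(0)
    edges = A if isinstance(A, EdgeIndex) else edges_from_adjacency(A)
    B, N, T, d = H.shape
    valid = _time_validity(T, constrained)

    alpha = _alpha(H, edges, params, valid)
    rho = _rho(H, edges, params)
    gumbel_u = None
    dt = H.data.dtype
    if no_gate:
        beta = Tensor(np.ones((B, edges.n_pairs, T, T), dtype=dt))
        hard = True
    elif mode == "train":
        if rng is None:
            raise ValueError("train mode needs an rng for Gumbel draws")
        u1 = rng.random((B, edges.n_pairs, T, T))
        u2 = rng.random((B, edges.n_pairs, T, T))
        gumbel_u = (u1, u2)
        beta = gumbel_gate(rho, params.tau, u1, u2)
        hard = False
    elif mode == "eval":
        beta = Tensor((rho.data >= 0.5).astype(dt))
        hard = True
    else:
        raise ValueError(f"unknown mode {mode!r}")

    hh = params.n_heads
    dh = d // hh
    w = alpha * beta.expand_dims(1)                      # (B,H,P,T,T)
    if not valid.all():
        w = w * valid.astype(dt)
    q1 = (H @ params.W1q + params.b1).take(edges.tgt, axis=1)  # (B,P,T,d)
    k1 = (H @ params.W1k).take(edges.src, axis=1)              # (B,P,T',d)
    mixed = _gated_message_mix(q1, k1, w.transpose(0, 2, 3, 1, 4))
    mixed = mixed.transpose(0, 3, 1, 2, 4)               # (B,H,P,T,d)
    num_h = segment_sum(mixed, edges.tgt, N, axis=2)     # (B,H,N,T,d)
    Z = segment_sum(w.sum(axis=-1), edges.tgt, N, axis=2)  # (B,H,N,T)
    # apply the message MLP's output map per head block: v_h = hidden@W2_h + b2_h
    W2_h = params.W2.reshape(d, hh, dh).transpose(1, 0, 2).expand_dims(1)
    b2_h = params.b2.reshape(1, hh, 1, 1, dh)
    num = num_h @ W2_h + Z.expand_dims(-1) * b2_h        # (B,H,N,T,dh)
    out = num / maximum_scalar(Z, Z_FLOOR).expand_dims(-1)
    out = out.transpose(0, 2, 3, 1, 4).reshape(B, N, T, d)

    all_closed = Z.data.max(axis=1) <= Z_FLOOR           # (B, N, T)
    # forward activations are never mutated, so views are safe here
    state = GateState(edges=edges, rho=rho.data, beta=beta.data,
                      alpha=alpha.data, gumbel_u=gumbel_u, hard=hard,
                      all_closed=all_closed, valid=valid, rho_tensor=rho)
    if squeeze:
        out = out.reshape(N, T, d)
    return out, state


# ----------------------------------------------------------- public inspection
def correlation_weights(H: np.ndarray, A: np.ndarray, params: ScaParams,
                        constrained: bool = False
                        ) -> tuple[np.ndarray, EdgeIndex]:
    """Attention weights α, shape (H, P, T, T); Σ over a query's context = 1."""
    edges = edges_from_adjacency(A)
    T = H.shape[1]
    alpha = _alpha(Tensor(H).expand_dims(0), edges, params,
                   _time_validity(T, constrained))
    return alpha.data[0], edges


def causal_probability(H: np.ndarray, A: np.ndarray, params: ScaParams
                       ) -> tuple[np.ndarray, EdgeIndex]:
    """Gate probabilities ρ per neighbor pair, shape (P, T, T), in (0, 1)."""
    edges = edges_from_adjacency(A)
    rho = _rho(Tensor(H).expand_dims(0), edges, params)
    return rho.data[0], edges


def message_value(h_q: np.ndarray, h_k: np.ndarray,
                  params: ScaParams) -> np.ndarray:
    """Message MLP on the concatenated (query, key) embeddings."""
    hq, hk = Tensor(h_q), Tensor(h_k)
    hidden = (hq @ params.W1q + hk @ params.W1k + params.b1).relu()
    return (hidden @ params.W2 + params.b2).data


def export_gate_state(state: GateState, path, layer: int = 0,
                      batch: int = 0) -> None:
    """Dump one window's gates to TSV for attention-map inspection."""
    import pandas as pd

    edges = state.edges
    rows = []
    T = state.rho.shape[-1]
    alpha_mean = state.alpha[batch].mean(axis=0)
    for e in range(edges.n_pairs):
        for t in range(T):
            for t2 in range(T):
                if not state.valid[t, t2]:
                    continue
                rows.append((layer, int(edges.tgt[e]), t, int(edges.src[e]), t2,
                             state.rho[batch, e, t, t2],
                             state.beta[batch, e, t, t2],
                             alpha_mean[e, t, t2]))
    pd.DataFrame(rows, columns=["layer", "query_node", "query_t", "key_node",
                                "key_t", "rho", "beta", "alpha"]
                 ).to_csv(path, sep="\t", index=False)
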