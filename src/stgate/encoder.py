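"""The L-layer encoder: input/skip projection, per-series temporal
transformer, spatiotemporal causal attention, and residual layer norm.

Layer recipe, starting from H(0) = input_project(X, M):

    H_skip = H(l-1) + MLP_l(X) ⊙ M + m ⊙ (1 - M)      (skip projection)
    H_in   = Transformer_l(H_skip + positional codes)  (per-node, along time)
    H_out  = SCA_l(H_in, A)
    H(l)   = LayerNorm(H_in + H_out)

The missing-value token m is a single learned d-vector shared by all layers;
skip MLPs are layer-specific.  Sinusoidal positional encodings are added on
the time axis before each temporal transformer, since nothing else orders the
steps.  Ablation switches: ``no_gate`` (β ≡ 1), ``no_skip`` (skip projection
reduces to identity), ``no_graph`` (A replaced by the identity, killing all
cross-node attention), ``constrained`` (keys restricted to t' ≤ t).
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor
from .nn import MLP, LayerNorm, Module, TransformerLayer, sinusoidal_positions
from .sca import EdgeIndex, GateState, ScaParams, edges_from_adjacency, sca_forward

__all__ = ["EncoderParams", "input_project", "skip_project",
           "temporal_transform", "encode"]


class EncoderParams(Module):
    def __init__(self, rng: np.random.Generator, d: int = 32, L: int = 2,
                 n_heads: int = 4, tau: float = 0.5):
        if L < 1 or d < 1:
            raise ValueError(f"need d >= 1 and L >= 1, got d={d}, L={L}")
        self.m = Tensor(rng.normal(0.0, 0.02, size=d), requires_grad=True)
        self.input_mlp = MLP(rng, [1, d, d])
        self.skip_mlps = [MLP(rng, [1, d, d]) for _ in range(L)]
        self.transformers = [TransformerLayer(rng, d, n_heads) for _ in range(L)]
        self.sca_layers = [ScaParams(rng, d, n_heads=n_heads, tau=tau)
                           for _ in range(L)]
        self.norms = [LayerNorm(d) for _ in range(L)]
        self.d = d
        self.L = L


def _cell_mlp(mlp: MLP, X: Tensor) -> Tensor:
    """Apply a 1→d perceptron to every scalar cell of (B, N, T)."""
    return mlp(X.expand_dims(-1))


def _masked_embed(mlp: MLP, m: Tensor, X: Tensor, M: np.ndarray) -> Tensor:
    """MLP(X) ⊙ M + m ⊙ (1 - M), the shared missing-token substitution."""
    Mf = np.asarray(M, dtype=X.data.dtype)[..., None]
    return _cell_mlp(mlp, X) * Mf + m * (1.0 - Mf)


def input_project(X: Tensor | np.ndarray, M: np.ndarray,
                  params: EncoderParams) -> Tensor:
    """H(0): observed cells get their value embedding, missing cells get m."""
    X = X if isinstance(X, Tensor) else Tensor(X)
    return _masked_embed(params.input_mlp, params.m, X, M)


def skip_project(H_prev: Tensor, X: Tensor | np.ndarray, M: np.ndarray,
                 params: EncoderParams, layer: int) -> Tensor:
    """Re-inject the raw input into the embeddings of the previous layer."""
    X = X if isinstance(X, Tensor) else Tensor(X)
    return H_prev + _masked_embed(params.skip_mlps[layer], params.m, X, M)


def temporal_transform(H_skip: Tensor, params: EncoderParams,
                       layer: int, constrained: bool = False) -> Tensor:
    """Transformer encoder layer per node along its T steps; no cross-node
    mixing.  Positional codes are added first.  In constrained mode the
    temporal attention is causally masked (t' <= t) so no stage of the
    encoder can read the future."""
    T, d = H_skip.shape[-2], H_skip.shape[-1]
    pe = sinusoidal_positions(T, d).astype(H_skip.data.dtype)
    return params.transformers[layer](H_skip + pe, causal=constrained)


def encode(X: np.ndarray, M: np.ndarray, A: np.ndarray | EdgeIndex,
           params: EncoderParams, mode: str = "eval",
           rng: np.random.Generator | None = None,
           no_gate: bool = False, no_skip: bool = False,
           no_graph: bool = False, constrained: bool = False
           ) -> tuple[Tensor, list[GateState]]:
    """Run the full encoder; X, M are (B, N, T) or (N, T).

    Returns the final embeddings H(L) of shape (..., N, T, d) plus the gate
    state of every layer.
    """
    X = np.asarray(X, dtype=params.m.data.dtype)
    squeeze = X.ndim == 2
    if squeeze:
        X, M = X[None], np.asarray(M)[None]
    if no_graph:
        n = X.shape[1]
        edges = edges_from_adjacency(np.eye(n))
    else:
        edges = A if isinstance(A, EdgeIndex) else edges_from_adjacency(A)

    Xt = Tensor(X)
    H = input_project(Xt, M, params)
    states: list[GateState] = []
    for layer in range(params.L):
        H_skip = H if no_skip else skip_project(H, Xt, M, params, layer)
        H_in = temporal_transform(H_skip, params, layer, constrained=constrained)
        H_out, state = sca_forward(H_in, edges, params.sca_layers[layer],
                                   mode=mode, rng=rng, no_gate=no_gate,
                                   constrained=constrained)
        H = params.norms[layer](H_in + H_out)
        states.append(state)
    if squeeze:
        B, N, T, d = H.shape
        H = H.reshape(N, T, d)
    return H, states
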