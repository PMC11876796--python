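"""Prompt Based Decoder (PBD).

The decoder realizes a frontdoor-style readout: instead of predicting from a
cell's embedding alone, each embedding attends (scaled dot product, multi-
head) over a bank of learnable prompt vectors — a trainable stand-in for the
marginal over dataset contexts — and the attended summary is projected
(linear + LayerNorm) and mapped to one scalar prediction per cell.

Ablation variants: ``mlp`` replaces the whole decoder with a per-cell
perceptron; ``kmeans``/``sample`` run the same attention over an externally
supplied frozen bank instead of learnable prompts.
"""

from __future__ import annotations

import math

import numpy as np

from .autodiff import Tensor
from .nn import Linear, LayerNorm, MLP, Module, softmax

__all__ = ["PromptBank", "PbdParams", "pbd_forward", "decoder_variant",
           "load_prompt_bank"]

# unit-variance prompts: the queries attending over the bank are layer-norm
# outputs of scale ~1, and near-identical tiny prompts make the decoder an
# almost-constant function that optimizes extremely slowly
PROMPT_INIT_SD = 1.0


class PromptBank(Module):
    """N_P learnable prompt vectors, Normal(0, 0.02²) initialized."""

    def __init__(self, rng: np.random.Generator, n_prompts: int, d: int,
                 values: np.ndarray | None = None, learnable: bool = True):
        if n_prompts < 1:
            raise ValueError(f"need at least one prompt, got {n_prompts}")
        if values is not None:
            values = np.asarray(values, dtype=np.float64)
            if values.shape != (n_prompts, d):
                raise ValueError(f"bank shape {values.shape} != "
                                 f"({n_prompts}, {d})")
            if not np.all(np.isfinite(values)):
                raise ValueError("prompt bank contains non-finite entries")
        else:
            values = rng.normal(0.0, PROMPT_INIT_SD, size=(n_prompts, d))
        self.P = Tensor(values, requires_grad=learnable)
        self.n_prompts = n_prompts


class PbdParams(Module):
    def __init__(self, rng: np.random.Generator, d: int,
                 n_prompts: int = 1000, n_heads: int = 4,
                 bank: PromptBank | None = None):
        if d % n_heads:
            raise ValueError(f"d={d} not divisible by n_heads={n_heads}")
        self.bank = bank if bank is not None else PromptBank(rng, n_prompts, d)
        self.wq = Linear(rng, d, d)
        self.wk = Linear(rng, d, d)
        self.wv = Linear(rng, d, d)
        self.project = Linear(rng, d, d)
        self.ln = LayerNorm(d)
        self.head = Linear(rng, d, 1)
        self.n_heads = n_heads
        self.d = d


def pbd_forward(H: Tensor | np.ndarray, params: PbdParams) -> Tensor:
    """Predictions Ŷ of shape (..., N, T) from embeddings (..., N, T, d).

    Every cell embedding queries the prompt bank; keys and values are
    projected prompts.  Deterministic.
    """
    H = H if isinstance(H, Tensor) else Tensor(H)
    *lead, N, T, d = H.shape
    h = params.n_heads
    dh = d // h

    q = params.wq(H).reshape(*lead, N * T, h, dh).swapaxes(-2, -3)
    # prompts: (N_P, d) -> (h, N_P, dh)
    k = params.wk(params.bank.P).reshape(-1, h, dh).swapaxes(0, 1)
    v = params.wv(params.bank.P).reshape(-1, h, dh).swapaxes(0, 1)

    scores = (q @ k.swapaxes(-1, -2)) * (1.0 / math.sqrt(dh))
    attn = softmax(scores, axis=-1)          # (..., h, NT, N_P)
    ctx = attn @ v                           # (..., h, NT, dh)
    ctx = ctx.swapaxes(-2, -3).reshape(*lead, N, T, d)
    out = params.ln(params.project(ctx))
    return params.head(out).reshape(*lead, N, T)


class MlpDecoder(Module):
    """Per-cell d → 1 perceptron (the decoder-ablation variant)."""

    def __init__(self, rng: np.random.Generator, d: int):
        self.mlp = MLP(rng, [d, d, 1])
        self.d = d

    def __call__(self, H: Tensor) -> Tensor:
        *lead, N, T, d = H.shape
        return self.mlp(H).reshape(*lead, N, T)


def decoder_variant(rng: np.random.Generator, d: int, mode: str = "pbd",
                    n_prompts: int = 1000, n_heads: int = 4,
                    bank_values: np.ndarray | None = None) -> Module:
    """Build the decoder for a config: pbd | mlp | kmeans | sample.

    kmeans/sample take a frozen externally supplied bank (e.g. cluster
    centers of pre-trained embeddings) in place of learnable prompts.
    """
    if mode == "mlp":
        return MlpDecoder(rng, d)
    if mode == "pbd":
        return PbdParams(rng, d, n_prompts=n_prompts, n_heads=n_heads)
    if mode in ("kmeans", "sample"):
        if bank_values is None:
            raise ValueError(f"decoder mode {mode!r} requires an external "
                             f"prompt bank (bank_values or --bank file)")
        bank_values = np.asarray(bank_values, dtype=np.float64)
        bank = PromptBank(rng, bank_values.shape[0], d, values=bank_values,
                          learnable=False)
        return PbdParams(rng, d, n_prompts=bank.n_prompts, n_heads=n_heads,
                         bank=bank)
    raise ValueError(f"unknown decoder mode {mode!r}")


def load_prompt_bank(path, d: int) -> np.ndarray:
    """Frozen bank from TSV: N_P rows × d columns."""
    import pandas as pd

    values = pd.read_csv(path, sep="\t", header=None).to_numpy(dtype=np.float64)
    if values.ndim != 2 or values.shape[1] != d:
        raise ValueError(f"bank in {path} has shape {values.shape}, "
                         f"expected (N_P, {d})")
    return values
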