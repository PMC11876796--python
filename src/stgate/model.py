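"""Full imputation model: encoder with causal attention + prompt decoder."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .autodiff import Tensor
from .encoder import EncoderParams, encode
from .nn import Module
from .pbd import PbdParams, decoder_variant, pbd_forward
from .sca import EdgeIndex, GateState

__all__ = ["ModelConfig", "ImputationModel", "save_checkpoint",
           "load_checkpoint"]

CHECKPOINT_SCHEMA = 1


@dataclass
class ModelConfig:
    """Architectural hyperparameters.

    ``d``: embedding width.  ``L``: encoder layers (2 suits a few dozen
    nodes; 4 for larger networks).  ``n_prompts``: decoder bank size (stable
    over roughly 200–1400).  ``tau``: Gumbel temperature, fixed (no
    annealing).  Ablations: ``no_gate`` (β ≡ 1), ``no_pbd``/``decoder='mlp'``,
    ``no_graph``, ``constrained`` (t' ≤ t), ``no_skip``.
    """

    d: int = 32
    L: int = 2
    n_heads: int = 4
    n_prompts: int = 1000
    tau: float = 0.5
    decoder: str = "pbd"            # pbd | mlp | kmeans | sample
    window_T: int = 24
    no_gate: bool = False
    no_skip: bool = False
    no_graph: bool = False
    constrained: bool = False

    def __post_init__(self):
        if self.decoder not in ("pbd", "mlp", "kmeans", "sample"):
            raise ValueError(f"unknown decoder {self.decoder!r}")

    @property
    def no_pbd(self) -> bool:
        return self.decoder == "mlp"


class ImputationModel(Module):
    """Encoder + decoder pair operating on (X, M) windows over adjacency A."""

    def __init__(self, config: ModelConfig, seed: int = 0,
                 bank_values: np.ndarray | None = None,
                 dtype: str = "float64"):
        rng = np.random.default_rng(seed)
        self.config = config
        self.encoder = EncoderParams(rng, d=config.d, L=config.L,
                                     n_heads=config.n_heads, tau=config.tau)
        self.decoder = decoder_variant(rng, config.d, mode=config.decoder,
                                       n_prompts=config.n_prompts,
                                       n_heads=config.n_heads,
                                       bank_values=bank_values)
        # z-score normalization applied to inputs inside forward(); set by
        # the trainer from the observed cells.  Predictions stay in
        # standardized units — impute() maps them back to data units.
        self.norm_mu = 0.0
        self.norm_sd = 1.0
        if dtype != "float64":
            self.astype(np.dtype(dtype))

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=np.float64) - self.norm_mu) / self.norm_sd

    def destandardize(self, Y: np.ndarray) -> np.ndarray:
        return np.asarray(Y, dtype=np.float64) * self.norm_sd + self.norm_mu

    def forward(self, X: np.ndarray, M: np.ndarray, A: np.ndarray | EdgeIndex,
                mode: str = "eval", rng: np.random.Generator | None = None
                ) -> tuple[Tensor, list[GateState]]:
        """Predictions in standardized units, plus per-layer gate states.

        ``X`` is in data units; masked cells are ignored whatever they hold.
        """
        cfg = self.config
        X = self.standardize(X) * np.asarray(M)  # keep sentinel at 0
        H, states = encode(X, M, A, self.encoder, mode=mode, rng=rng,
                           no_gate=cfg.no_gate, no_skip=cfg.no_skip,
                           no_graph=cfg.no_graph, constrained=cfg.constrained)
        if isinstance(self.decoder, PbdParams):
            Yhat = pbd_forward(H, self.decoder)
        else:
            Yhat = self.decoder(H)
        return Yhat, states

    __call__ = forward


def save_checkpoint(path, model: ImputationModel, extra: dict | None = None
                    ) -> None:
    """Single-file .npz: all parameter arrays + JSON config + schema tag."""
    payload = {f"param/{k}": v for k, v in model.state().items()}
    if isinstance(model.decoder, PbdParams) and \
            not model.decoder.bank.P.requires_grad:
        payload["param/decoder.bank.P"] = model.decoder.bank.P.data
    meta = {"schema": CHECKPOINT_SCHEMA, "config": asdict(model.config),
            "norm": [float(model.norm_mu), float(model.norm_sd)],
            "extra": extra or {}}
    payload["meta_json"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **payload)


def load_checkpoint(path) -> tuple[ImputationModel, dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta_json"].tobytes()).decode())
        if meta.get("schema") != CHECKPOINT_SCHEMA:
            raise ValueError(f"unsupported checkpoint schema: "
                             f"{meta.get('schema')}")
        cfg = ModelConfig(**meta["config"])
        bank = None
        state = {k[len("param/"):]: data[k] for k in data.files
                 if k.startswith("param/")}
    if cfg.decoder in ("kmeans", "sample"):
        bank = state["decoder.bank.P"]
    model = ImputationModel(cfg, seed=0, bank_values=bank)
    model.load_state(state)
    model.norm_mu, model.norm_sd = meta.get("norm", [0.0, 1.0])
    return model, meta.get("extra", {})
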