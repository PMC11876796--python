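"""Loss, optimization loop, early stopping and the imputation entry point.

Training follows the masked-reconstruction protocol: for every batch an
artificial mask hides a fraction p ∈ {0.2, 0.5, 0.8} of the currently
observed cells, the model sees the thinned series, and the loss is the MAE on
exactly the hidden cells plus an l1 penalty on the causal-gate probabilities:

    L = ( Σ m|y − ŷ| + λ Σ_Φ ρ ) / max(Σ m, 1)

Both terms share the masked-cell normalizer: this is the sum-form objective
rescaled by a common constant, so the per-gate penalty gradient stays λ — the
threshold the gate-convergence analysis compares message gradients against —
while the loss remains batch-size invariant.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np

from .autodiff import Tensor
from .core_types import SpatioTemporalSeries
from .model import ImputationModel, ModelConfig
from .nn import Adam, cosine_lr
from .sca import GateState, edges_from_adjacency
from .synthetic import training_mask_sampler

__all__ = ["TrainConfig", "TrainingReport", "masked_mae_loss", "train",
           "impute", "split_windows", "mean_imputer", "locf_imputer",
           "masked_mae"]


@dataclass
class TrainConfig:
    """Optimization hyperparameters (Adam + cosine schedule)."""

    lambda_l1: float = 0.001
    lambda_delay: float = 0.5    # fraction of max_epochs before the l1 starts
    lambda_warmup: float = 0.25  # fraction of max_epochs to ramp the l1 in
    lr: float = 0.0008
    gate_lr: float = 5.0         # plain-SGD rate of the gate scorer (see nn.Adam)
    max_epochs: int = 300
    patience: int = 40
    batch_size: int = 8
    window_T: int = 24
    training_rates: tuple[float, ...] = (0.2, 0.5, 0.8)
    val_fraction: float = 0.1
    precision: str = "float32"   # parameter/activation dtype while training
    seed: int = 0

    def __post_init__(self):
        if self.lambda_l1 < 0:
            raise ValueError("lambda_l1 must be nonnegative")
        if self.patience > self.max_epochs:
            self.patience = self.max_epochs


@dataclass
class TrainingReport:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    rho_fraction: list[float] = field(default_factory=list)
    lr_trace: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val: float = float("inf")
    stopped_epoch: int = -1
    final_gate_stats: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def masked_mae(Y: np.ndarray, Yhat: np.ndarray, mask: np.ndarray) -> float:
    """Plain masked mean absolute error (numpy, no gradient)."""
    m = np.asarray(mask, dtype=bool)
    if m.sum() == 0:
        return 0.0
    return float(np.abs(Y - Yhat)[m].mean())


def masked_mae_loss(Y: np.ndarray, Yhat: Tensor, loss_mask: np.ndarray,
                    rho_values: list[Tensor] | None = None,
                    lambda_l1: float = 0.0,
                    rho_valid: list[np.ndarray] | None = None) -> Tensor:
    """Differentiable training loss; see module docstring for the form."""
    dt = Yhat.data.dtype
    m = np.asarray(loss_mask, dtype=dt)
    n = max(float(m.sum()), 1.0)
    if m.sum() == 0:
        warnings.warn("empty loss mask: data term is zero", stacklevel=2)
    data = ((Yhat - np.asarray(Y, dtype=dt)).abs() * m).sum() * (1.0 / n)
    if not rho_values or lambda_l1 == 0.0:
        return data
    penalty = None
    for i, rho in enumerate(rho_values):
        term = rho if rho_valid is None or rho_valid[i].all() else \
            rho * rho_valid[i].astype(rho.data.dtype)
        s = term.sum()
        penalty = s if penalty is None else penalty + s
    return data + penalty * (lambda_l1 / n)


def split_windows(series: SpatioTemporalSeries, window_T: int
                  ) -> list[dict]:
    """Non-overlapping windows of length window_T (tail shorter than a
    window is dropped)."""
    N, T = series.X.shape
    if T < window_T:
        raise ValueError(f"series length {T} shorter than window {window_T}")
    windows = []
    for start in range(0, T - window_T + 1, window_T):
        sl = slice(start, start + window_T)
        windows.append({"X": series.X[:, sl], "M": series.M[:, sl],
                        "start": start})
    return windows


def _gate_stats(states: list[GateState]) -> dict:
    rhos = np.concatenate([s.rho_values() for s in states]) if states else \
        np.array([])
    if rhos.size == 0:
        return {"n_gates": 0}
    return {"n_gates": int(rhos.size),
            "mean_rho": float(rhos.mean()),
            "frac_open": float((rhos >= 0.5).mean()),
            "frac_converged": float(((rhos <= 0.1) | (rhos >= 0.9)).mean())}


def train(series: SpatioTemporalSeries, model_config: ModelConfig,
          train_config: TrainConfig, log=None
          ) -> tuple[ImputationModel, TrainingReport]:
    """Fit the model on one incomplete series; returns the best-validation
    model (parameters restored) and the epoch-by-epoch report."""
    from .autodiff import tune_allocator
    tune_allocator()
    tc = train_config
    seeds = np.random.SeedSequence(tc.seed).spawn(4)
    init_seed = int(seeds[0].generate_state(1)[0] % (2 ** 31))
    rng_split = np.random.default_rng(seeds[1])
    rng_batch = np.random.default_rng(seeds[2])
    rng_gumbel = np.random.default_rng(seeds[3])

    model = ImputationModel(model_config, seed=init_seed, dtype=tc.precision)
    obs = series.X[series.M.astype(bool)]
    model.norm_mu = float(obs.mean()) if obs.size else 0.0
    model.norm_sd = float(max(obs.std(), 1e-8)) if obs.size else 1.0
    edges = edges_from_adjacency(
        np.eye(series.n_series) if model_config.no_graph else series.A)
    windows = split_windows(series, tc.window_T)
    order = rng_split.permutation(len(windows))
    n_val = max(1, int(round(tc.val_fraction * len(windows)))) \
        if len(windows) > 1 else 0
    val_idx, train_idx = order[:n_val], order[n_val:]

    # fixed validation masking so the early-stopping metric is stable
    val_batches = []
    for i in val_idx:
        w = windows[i]
        m_in, m_loss, _ = training_mask_sampler(w["X"], w["M"],
                                                tc.training_rates, rng_split)
        val_batches.append({"X": w["X"] * m_in, "M": m_in,
                            "target": w["X"], "loss_mask": m_loss})

    params = model.parameters()
    gate_params = {k for k in params
                   if ".Wqc" in k or ".Wkc" in k or ".wc_" in k}
    opt = Adam(params, lr=tc.lr, sgd_group=gate_params, sgd_lr=tc.gate_lr)
    report = TrainingReport()
    best_state = model.state()
    # model selection happens under the final objective: epochs before the
    # gate penalty is fully active are not candidates for the best model
    track_from = 0 if tc.lambda_l1 == 0 else min(
        int(np.ceil((tc.lambda_delay + tc.lambda_warmup) * tc.max_epochs)),
        tc.max_epochs - 1)

    delay = tc.lambda_delay * tc.max_epochs
    warm = max(tc.lambda_warmup * tc.max_epochs, 1e-12)
    for epoch in range(tc.max_epochs):
        lr = cosine_lr(tc.lr, epoch, tc.max_epochs)
        # two-phase gate penalty: off while the model fits the data, then
        # ramped to its full value — gates judged before attention has
        # concentrated would all close on start-up noise and never reopen
        lam = tc.lambda_l1 * min(1.0, max(0.0, (epoch - delay) / warm))
        perm = rng_batch.permutation(train_idx)
        epoch_losses, epoch_rhos = [], []
        for b0 in range(0, len(perm), tc.batch_size):
            idx = perm[b0:b0 + tc.batch_size]
            Xb = np.stack([windows[i]["X"] for i in idx])
            Mb = np.stack([windows[i]["M"] for i in idx])
            m_in, m_loss, _ = training_mask_sampler(Xb, Mb, tc.training_rates,
                                                    rng_batch)
            Yhat, states = model.forward(Xb * m_in, m_in, edges,
                                         mode="train", rng=rng_gumbel)
            rho_tensors = [s.rho_tensor for s in states]
            rho_valid = [np.broadcast_to(s.valid, s.rho.shape)
                         for s in states]
            loss = masked_mae_loss(model.standardize(Xb), Yhat, m_loss,
                                   rho_tensors, lam, rho_valid=rho_valid)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"divergent loss at epoch {epoch}, batch {b0 // tc.batch_size}: "
                    f"{loss.data}")
            opt.zero_grad()
            loss.backward()
            opt.step(lr=lr)
            epoch_losses.append(float(loss.data))
            epoch_rhos.append(np.concatenate([s.rho_values() for s in states]))

        report.train_loss.append(float(np.mean(epoch_losses)))
        report.lr_trace.append(lr)
        rhos = np.concatenate(epoch_rhos)
        report.rho_fraction.append(
            float(((rhos <= 0.1) | (rhos >= 0.9)).mean()))

        if val_batches:
            val_errs = []
            for vb in val_batches:
                Yhat, _ = model.forward(vb["X"][None], vb["M"][None], edges,
                                        mode="eval")
                val_errs.append(masked_mae(model.standardize(vb["target"]),
                                           Yhat.data[0], vb["loss_mask"]))
            val_loss = float(np.mean(val_errs))
        else:
            val_loss = report.train_loss[-1]
        report.val_loss.append(val_loss)
        if log:
            log(f"epoch {epoch:3d} lr {lr:.2e} train {report.train_loss[-1]:.4f} "
                f"val {val_loss:.4f} rho-conv {report.rho_fraction[-1]:.3f}")

        if epoch >= track_from and val_loss < report.best_val:
            report.best_val = val_loss
            report.best_epoch = epoch
            best_state = model.state()
        if report.best_epoch >= 0 and epoch - report.best_epoch >= tc.patience:
            break
    report.stopped_epoch = epoch

    model.load_state(best_state)
    # gate statistics of the restored model on the training windows (eval mode)
    Xa = np.stack([windows[i]["X"] for i in train_idx]) if len(train_idx) \
        else np.stack([w["X"] for w in windows])
    Ma = np.stack([windows[i]["M"] for i in train_idx]) if len(train_idx) \
        else np.stack([w["M"] for w in windows])
    _, states = model.forward(Xa, Ma, edges, mode="eval")
    report.final_gate_stats = _gate_stats(states)
    return model, report


def impute(model: ImputationModel, series: SpatioTemporalSeries) -> np.ndarray:
    """Fill missing cells; observed values pass through untouched.

    The series is processed in windows of the model's window_T; a trailing
    remainder is covered by one final window aligned to the series end.
    Evaluation-mode gates make repeated calls identical.
    """
    wT = model.config.window_T
    N, T = series.X.shape
    if T < wT:
        raise ValueError(f"series length {T} < model window {wT}")
    edges = edges_from_adjacency(
        np.eye(N) if model.config.no_graph else series.A)
    Yhat = np.zeros((N, T))
    starts = list(range(0, T - wT + 1, wT))
    if starts[-1] + wT < T:
        starts.append(T - wT)
    for start in starts:
        sl = slice(start, start + wT)
        pred, _ = model.forward(series.X[:, sl][None], series.M[:, sl][None],
                                edges, mode="eval")
        Yhat[:, sl] = model.destandardize(pred.data[0])
    M = series.M.astype(bool)
    return np.where(M, series.X, Yhat)


# ------------------------------------------------------------ reference rules
def mean_imputer(X: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Fill each series' missing cells with its own observed mean."""
    M = np.asarray(M, dtype=bool)
    out = X.astype(np.float64).copy()
    global_mean = X[M].mean() if M.any() else 0.0
    for i in range(X.shape[0]):
        mean_i = X[i, M[i]].mean() if M[i].any() else global_mean
        out[i, ~M[i]] = mean_i
    return out


def locf_imputer(X: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Last observation carried forward; leading gaps are back-filled."""
    M = np.asarray(M, dtype=bool)
    out = X.astype(np.float64).copy()
    N, T = X.shape
    for i in range(N):
        last = np.nan
        for t in range(T):
            if M[i, t]:
                last = out[i, t]
            else:
                out[i, t] = last
        holes = np.isnan(out[i])
        if holes.any():  # leading gap: back-fill with the first observation
            obs = np.flatnonzero(M[i])
            out[i, holes] = out[i, obs[0]] if obs.size else 0.0
    return out
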