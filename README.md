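# stgate

Causality-aware spatiotemporal graph attention for **imputing missing values**
in multivariate sensor / gene-expression time series while **discovering a
sparse Granger-causal graph** among the series.

## Who this is for

Sensor networks (air quality, traffic) and gene-expression panels produce
matrices `X ∈ R^{N×T}` — N series over T steps — riddled with gaps from
outages and dropouts, plus a distance-based adjacency `A` that inevitably
contains non-causal "shortcut" edges and shared background noise. `stgate`
fills the gaps and, as a by-product of the same training run, reports which
series actually drive which.

## The model

An encoder embeds every cell (missing cells get a learned token `m`), runs a
per-series temporal transformer, and then **spatiotemporal causal attention**:
each query point `(i, t)` attends over the full time range of its graph
neighbors with

    h_out(i,t) = (1/Z) Σ_{i'∈N(i)} Σ_{t'}  β_{i',t'} · α_{i',t'} · v_{i',t'},
    Z = Σ β·α,

where `α` are multi-head scaled-dot-product attention weights,
`v = MLP([h_q; h_k])` are messages, and `β ~ Bernoulli(ρ)` is a **causal
gate** with learned probability

    ρ = σ( w_c · [W_Qc h_q ; W_Kc h_k] ),

reparameterized by binary Gumbel-Softmax during training. The decoder attends
from each embedding over a bank of learnable prompts (a frontdoor-adjusted
readout) to produce one prediction per cell. Training minimizes

    L = ( Σ m_{i,t} |y − ŷ| + λ Σ_Φ ρ ) / max(Σ m, 1),

masked MAE on artificially hidden cells plus an l1 penalty on all gate
probabilities. Under frozen-model gradient descent each ρ converges to 1 when
its message gradient exceeds λ and to 0 otherwise, so trained gates are a
sparse Granger verdict per point pair. Max-pooling the gate probabilities
over both time axes (÷T²) yields an N×N causal-weight matrix.

Everything runs on a small numpy reverse-mode autodiff engine bundled with
the package — no deep-learning framework required.

## Worked example

```bash
python examples/impute_and_discover.py
```

builds a 10-series synthetic study (planted VAR graph, shared background
confounder, shortcut edges, 25% point missing), trains for 50 epochs on one
CPU (~2 minutes), and prints:

```
best validation MAE (standardized): 0.557 at epoch 31
gate convergence at the selected epoch: 1.00

imputation MAE on held-out cells: 13.224
series-mean baseline:             18.327

planted-graph AUC from pooled gate probabilities: 0.916
(0.5 = random ranking; the max-pooled gate probabilities should rank
planted causal edges above non-causal and shortcut pairs)
```

Reading: the trained model reconstructs held-out cells with ~28% less error
than a per-series mean fill; every gate probability has committed to 0 or 1
under the l1 penalty; and ranking node pairs by pooled gate probability
recovers the planted causal edges at AUC 0.92 against 0.5 for chance.

The other examples are single-capability walkthroughs:
`examples/simulate_and_inspect.py` (the synthetic study and its self-checks)
and `examples/gate_convergence_oracle.py` (the gate-probability dynamics as a
standalone gradient iteration).

## Command line

```bash
stgate simulate --seed 7 --out-dir runs/sim
stgate train    --series runs/sim/series.csv --adjacency runs/sim/adjacency.csv \
                --seed 7 --out-dir runs/fit
stgate impute   --checkpoint runs/fit/checkpoint.npz --series runs/sim/series.csv \
                --adjacency runs/sim/adjacency.csv --out imputed.csv
stgate discover --checkpoint runs/fit/checkpoint.npz --series runs/sim/series.csv \
                --adjacency runs/sim/adjacency.csv --truth runs/sim/truth_edges.tsv \
                --out causal_matrix.csv
stgate eval     --imputed imputed.csv --truth runs/sim/complete.csv \
                --eval-mask runs/sim/eval_mask.csv
```

Series are CSV (rows = nodes, header = time labels, empty cell = missing) or
HDF5; adjacency is a dense CSV or a 3-column edge-list TSV; every run writes
a JSON manifest with its config, seeds and input checksums. Ablation flags
(`--no-gate`, `--no-pbd`, `--no-graph`, `--no-skip`, `--constrained`) switch
off individual components.

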