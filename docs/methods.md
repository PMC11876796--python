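# Methods

## Problem and model

`stgate` imputes missing values in a multivariate sensor (or gene-expression)
time series `X ∈ R^{N×T}` observed through a binary mask `M`, with a sensor
adjacency `A` built from pairwise distances by a thresholded Gaussian kernel
`A_ij = exp(-D_ij²/σ²)·1[· ≥ κ]`. While imputing, it learns which series
drive which: a Granger-causal graph over the N series.

The network is an encoder–decoder:

* **Input / skip projection.** Every observed scalar is embedded by a 1→d→d
  perceptron; missing cells receive a shared learned token `m ∈ R^d`. Each of
  the `L` encoder layers re-injects this embedding (skip projection), so raw
  values reach every depth.
* **Temporal transformer.** A post-norm transformer encoder layer runs along
  each series' own time axis (no cross-series mixing), with sinusoidal
  positional codes added first — nothing else orders the steps.
* **Spatiotemporal causal attention (SCA).** Each query point `(i, t)`
  attends over its graph neighborhood's entire time range,
  `{(i', t') : A_{i,i'} ≠ 0}`. Two scorers act side by side:
  multi-head scaled-dot-product weights `α` (softmax over the query's whole
  context), and a causal gate — a Bernoulli probability
  `ρ = σ(w_c·[W_Qc h_q ; W_Kc h_k])` per point pair, reparameterized with
  binary Gumbel-Softmax noise at temperature `τ` during training and hardened
  to `1[ρ ≥ 0.5]` at evaluation. Messages are an MLP of the concatenated
  query/key embeddings. The output is the gated, renormalized sum
  `h_out = (1/Z) Σ β·α·v` with `Z = Σ β·α` floored at `1e-8`; `Z = 1` exactly
  when every gate is open, recovering plain neighbor attention.
* **Prompt decoder.** Each cell embedding attends (multi-head) over a bank of
  `N_P` learnable prompt vectors — a trainable stand-in for the marginal over
  dataset contexts in a frontdoor-adjusted readout — followed by a linear
  projection, LayerNorm and a scalar head.

Training minimizes the masked MAE on artificially hidden cells plus an l1
penalty on the gate probabilities,

    L = ( Σ m |y − ŷ| + λ Σ_Φ ρ ) / max(Σ m, 1),

i.e. the sum-form objective rescaled by the masked-cell count: the per-gate
penalty gradient remains exactly λ — the threshold the gate-convergence
analysis compares message gradients against — while the loss stays
batch-size invariant. Under frozen-model gradient descent each gate's ρ
converges to 1 when its message gradient `g = (∂ŷ/∂h_out)(α/Z)v` exceeds λ
and to 0 otherwise; `theorem1_oracle` iterates that closed-form update
independently of the network code and is used as its test oracle.

## Causal-graph readout

For each window, gate values between query `(i,t)` and key `(i',t')` form a
4-way array; max-pooling over both time axes and dividing by `T²` gives a
node-level weight matrix `W[i, i']` (target row, source column), averaged
over windows. The pooled value is ρ, the noise-free expectation of the
reparameterized gate: the l1 term shrinks the entire ρ field toward zero, so
the fixed 0.5 hardening threshold usually erases a ranking that ρ itself
retains almost perfectly (on the synthetic study: area under the ROC curve
≈ 0.9 from ρ pooling versus 0.5 from hard pooling once every gate is below
threshold). Hardened-gate pooling stays available (`soft=False`). Diagonal
entries are excluded from AUC evaluation.

## What the synthetic generator emulates

`stgate.synthetic` plants ground truth so every stage is testable offline:

* **Dynamics.** A stationary VAR(1): nodes are placed uniformly in the unit
  square; the adjacency keeps the top ~25% of Gaussian-kernel weights
  (bandwidth = median distance); directed causal edges are sampled from
  adjacency-supported pairs at density 0.15 of all ordered pairs, with
  coefficient magnitudes 0.25–0.45 and random signs; self-persistence 0.8
  with the companion spectral radius capped at 0.95 — real sensor series are
  strongly autocorrelated, and this is also what makes masked imputation
  learnable at small training budgets. Innovation sd 10 (sensor-like units;
  immaterial after standardization). 100 burn-in steps are discarded.
* **Confounding.** One shared AR(1) latent (coefficient 0.5, marginal sd 5)
  added to every series, and 5 directed "shortcut" edges inserted into the
  adjacency between pairs with no causal edge in either direction.
* **Missingness.** 25% independent point missing for evaluation; block modes
  (per-node temporal runs, whole-node outages) for robustness tests; during
  training a fraction p ∈ {0.2, 0.5, 0.8}, drawn per batch, of the observed
  cells is hidden and used as loss targets.

A generator self-check requires lagged ridge regression on the clean complete
series to rank planted edges at AUC > 0.9 — structure that no method could
recover otherwise is never used in tests. What the generator does *not*
emulate: seasonality, heteroscedastic sensors, non-Gaussian noise, missing-
not-at-random mechanisms, and nonlinear couplings; passing results here show
the machinery works under linear-VAR conditions, not that real-data accuracy
is matched.

## Numerical and optimization choices

* **Standardization.** Series are z-scored inside the trainer from observed
  cells and de-standardized at imputation. This is standard for neural
  imputers and makes the fixed gate threshold λ = 0.001 meaningful across
  data scales.
* **Optimizer.** Adam (lr 3e-3, cosine schedule over the epoch budget) for
  all parameters except the gate scorer. The gate scorer (`W_Qc`, `W_Kc`,
  `w_c`) uses plain SGD at a constant rate (5.0): the convergence analysis is
  a statement about gradient *magnitudes* relative to λ, and Adam's
  per-coordinate normalization erases magnitudes — under Adam the constant λ
  pressure closes every gate at full speed regardless of the data gradient.
  ρ is clamped to `[1e-4, 1−1e-4]` so saturated gates keep finite Gumbel
  logits and remain recoverable.
* **Penalty schedule.** λ is zero for the first 40% of epochs, ramps linearly
  to its full value by 60%, and stays constant; early stopping considers only
  full-penalty epochs. Gates judged before attention has concentrated close
  on start-up noise and cannot reopen (dβ/dρ vanishes at the boundary).
* **Default study size.** N = 15 series, 48 windows of T = 24 steps, batch 8,
  50 epochs (patience 40), d = 32, L = 2, 2 attention heads, N_P = 256
  prompts, τ = 0.5 fixed. These sizes keep the full pipeline at roughly two
  minutes per run on one CPU core; the reference configuration for real
  datasets (d = 32, L = 2–4, lr 8e-4, batch 8, 300 epochs, N_P = 1000)
  remains the package default outside the study helpers.
* **Degenerate inputs.** Queries whose gates all close produce a zero vector
  and are flagged; empty loss masks warn and contribute zero; uniform draws
  are clamped to `[1e-6, 1−1e-6]` before the double logarithm; non-stationary
  VAR specifications and malformed series/adjacency files raise with the
  offending quantity named.
* **Precision.** Training runs in float32 (memory-bound CPU throughput);
  evaluation and all oracle comparisons run in float64. The autodiff engine
  preserves whichever float width it is given.

## Ablation switches

`no_gate` (β ≡ 1, gateless neighbor attention), `decoder="mlp"` (prompt
decoder → per-cell perceptron), `no_graph` (adjacency → identity, killing
cross-series attention), `no_skip` (skip projection → identity), and
`constrained` (keys restricted to t' ≤ t in both the temporal transformer
and SCA, so nothing downstream of time t can read the future). These
reproduce the standard component-removal comparisons; the unconstrained
default is intentional — for imputation, future context is legitimate
evidence, and the time-resolved gate indices still let a past-only graph be
read off afterwards.

## Known limitations

* The desk-scale training budget (~300 optimizer steps) is far from the
  regime the reference configuration assumes; imputation accuracy is
  demonstrated against series-mean and last-observation-carried-forward
  imputers, not against tuned deep baselines.
* Hard-gate sparsification and imputation accuracy compete at this scale:
  with λ at its default, the trained ρ field commits almost entirely to the
  closed side and graph recovery rests on the ρ ranking (see the extraction
  section above).
* The gate is one verdict per point pair shared across attention heads;
  per-head gates would multiply the penalty bookkeeping and are not
  implemented.
* Only dense in-memory series are supported (N×T in RAM); no streaming.
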