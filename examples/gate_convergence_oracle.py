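"""The causal gate as a gradient threshold: standalone convergence dynamics.

With every other parameter frozen, the gate probability rho = sigmoid(w'h)
evolves under gradient descent on the l1-regularized loss as

    w <- w - eta * (lambda - g) * rho(1-rho) * h,

where g is the product of the prediction gradient, the attention weight over
its normalization, and the message value.  The sign of (g - lambda) alone
decides the limit: informative pairs (g > lambda) converge to rho = 1, noise
pairs to rho = 0.
"""

import numpy as np

from stgate import Theorem1Config, theorem1_oracle

rng = np.random.default_rng(0)
h = rng.normal(size=8)
lam = 1e-3

for ratio in (0.25, 0.5, 2.0, 4.0):
    cfg = Theorem1Config(
        lambda_l1=lam, dy_dhout=1.0, alpha=1.0, Z=1.0, v=ratio * lam,
        h_in=h, w0=rng.normal(scale=0.1, size=8),
        eta=0.05 / (abs(lam * (ratio - 1)) * (h @ h) * 0.25),
        n_steps=4000)
    traj = theorem1_oracle(cfg)
    print(f"g = {ratio:>4}*lambda : rho {traj[0]:.3f} -> {traj[-1]:.4f}")

print("\nGates whose message gradient exceeds the l1 coefficient open fully;")
print("all others close — the mechanism that makes trained gates a sparse,")
print("binary Granger-causality verdict.")
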