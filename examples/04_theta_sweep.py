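"""Sensitivity of the ensemble to the soft-voting weight theta.

Each theta is evaluated on identical cross-validation folds, so the
curve isolates the weight's effect: theta -> 0 is the pure random-walk
ranking, large theta approaches the pure LRLS ranking.
"""

import logging

from cda_netfuse import HyperParams, generate, small_preset, theta_sweep

logging.disable(logging.WARNING)

Y, sem, _ = generate(small_preset(seed=17))
thetas = [round(0.1 * i, 1) for i in range(1, 10)]
curve = theta_sweep(Y, sem, HyperParams(), thetas, k=5, repeats=3, seed=17)
for theta, auc in curve:
    bar = "#" * int((auc - 0.5) * 100)
    print(f"theta={theta:.1f}  mean AUC {auc:.4f}  {bar}")
best = max(curve, key=lambda t: t[1])
print(f"best weight on this benchmark: theta={best[0]} (AUC {best[1]:.4f})")
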