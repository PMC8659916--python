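"""Metric-driven checkpoint selection.

Shows the selection rule on characteristic training curves: validation TSM
that falls then plateaus, and background STD with a clear minimum a couple
of epochs after the plateau begins.
"""

from holophase.cgan import EpochMetrics, select_best_epoch

tsm_vals = [0.50, 0.40, 0.32, 0.25, 0.19, 0.14, 0.10, 0.065, 0.042, 0.030,
            0.028, 0.027, 0.028, 0.029, 0.030]
std_vals = [0.90, 0.80, 0.70, 0.62, 0.55, 0.48, 0.42, 0.36, 0.31, 0.27,
            0.24, 0.21, 0.23, 0.26, 0.29]

metrics = [
    EpochMetrics(epoch=i + 1, mean_tsm_train=t, mean_tsm_val=t,
                 mean_std_train=s, mean_std_val=s)
    for i, (t, s) in enumerate(zip(tsm_vals, std_vals))
]

best = select_best_epoch(metrics, tsm_plateau_tol=0.02)
print(f"TSM plateaus at epoch 10 (first |delta TSM| <= 0.02)")
print(f"background STD is minimal at epoch {min(metrics, key=lambda m: m.mean_std_val).epoch}")
print(f"selected checkpoint: epoch {best}")

# The TSM plateau says the model has stopped fixing phase discontinuities;
# among those converged epochs, the lowest background noise wins. Training
# longer after the STD minimum tends to overfit.
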