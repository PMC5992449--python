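"""Learn compressed pair representations with the stacked auto-encoder.

Greedy layer-wise pretraining minimises reconstruction error plus an L1
sparsity penalty on hidden activations; supervised fine-tuning appends a
soft-max head and updates all weights on the labels.  The deepest hidden
activations are the learned features handed to the random forests.
"""

import numpy as np

from rpistack import (
    SimulationConfig, TrainConfig, build_pair_features, fine_tune,
    pretrain, simulate, transform,
)

ds = simulate(SimulationConfig(n_pairs=150, n_rna=50, n_protein=50,
                               noise=0.05, seed=1))
X_pair, _ = build_pair_features(ds.pairs, ds.rnas, ds.proteins)
y = np.array([p.label for p in ds.pairs])

# min-max scale into [0,1] before the sigmoid encoder
lo, hi = X_pair.min(axis=0), X_pair.max(axis=0)
X = (X_pair - lo) / np.where(hi > lo, hi - lo, 1.0)

cfg = TrainConfig(hidden_dims=[64, 32], epochs=25, batch_size=50, seed=0)
model = pretrain(X, cfg)
for i, losses in enumerate(model.pretrain_losses):
    print(f"layer {i}: reconstruction loss {losses[0]:.3f} -> {losses[-1]:.3f} "
          f"over {cfg.epochs} epochs")

H = transform(model, X)
print(f"deepest hidden features: {H.shape[0]} x {H.shape[1]}, "
      f"activations in ({H.min():.3f}, {H.max():.3f})")

ft = fine_tune(model, X, y, cfg)
print(f"fine-tuning cross-entropy: {ft.fine_tune_losses[0]:.3f} -> "
      f"{ft.fine_tune_losses[-1]:.3f} (lower = better fit to labels)")
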