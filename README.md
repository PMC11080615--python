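# perseclock

DNA-methylation age prediction with a channel-attention perceptron
(PerSEClock), for researchers working with Illumina methylation arrays who
want a single clock that accepts samples from the 27K, 450K and 850K (EPIC)
platforms.

## The problem and the model

An epigenetic clock predicts chronological age from beta values — per-CpG
methylation fractions β ∈ [0, 1] — at a fixed panel of loci. To serve all
three Illumina platforms at once, the clock operates on the 24,516 CpG loci
the platforms share.

The model combines a squeeze-and-excitation (SE) channel-attention block
with a multilayer perceptron:

1. **Reshape.** The length-L beta vector (reference L = 24,516) is arranged
   as a block tensor of shape 3 × 6 × C with C = L/18 channels
   (C = 1,362 at reference size); consecutive loci land in consecutive
   channels.
2. **Squeeze.** Global average pooling reduces each channel to the mean of
   its 18 beta values: s_c = (1/18) Σ β.
3. **Excitation.** Two fully connected layers with a ReLU bottleneck of
   width max(1, C/r) and a sigmoid output turn the channel means into gates
   g ∈ (0, 1)^C.
4. **Scale.** Every value in channel c is multiplied by g_c, up-weighting
   age-informative channels and down-weighting noise channels.
5. **Regression head.** The rescaled, flattened vector feeds a 4-layer MLP
   (32 units per layer; Linear → LeakyReLU → BatchNorm1d(32) →
   Dropout(0.1)) ending in one linear output: the predicted age in years.

Training minimizes MSE with Adam (learning rate 0.05, batch size 512, at
most 150 epochs) on raw, unstandardized beta values, monitors validation
MSE, and restores the parameters of the epoch with the lowest validation
loss. A plain-MLP baseline (the identical head without the attention block)
quantifies what the attention mechanism adds. Accuracy is summarized by
R² = 1 − SSE/SST, MAE, MSE and the median absolute error (Med), plus
per-tissue mean signed error (predicted − actual age).

The package also covers the surrounding pipeline: GEO-style beta-matrix
I/O, the “more than 50 % missing” sample filter, locus-panel intersection,
regression-based imputation of missing beta values, and a synthetic-cohort
generator with known age-informative loci so everything is testable without
downloading array data.

## Worked example

```python
import numpy as np
from perseclock import (SyntheticSpec, generate_cohort, split_dataset,
                        PerSEClockRegressor, PredictionResult, compute_metrics)

spec = SyntheticSpec(seed=0)            # 2,000 samples x 432 loci, 40 age-informative
bm, meta, truth = generate_cohort(spec)
ages = meta["age"].to_numpy()
tr, va, te = split_dataset(bm.n_samples, seed=0)

clock = PerSEClockRegressor(channels=None, random_state=0)
clock.fit(bm.values[tr], ages[tr], X_val=bm.values[va], y_val=ages[va])
print(f"stopped at epoch {clock.history_.n_epochs}, "
      f"best epoch {clock.best_epoch_}, val MSE {clock.best_val_loss_:.2f}")

pred = PredictionResult([bm.sample_ids[i] for i in te],
                        clock.predict(bm.values[te]), ages[te])
m = compute_metrics(pred)
print(f"test R^2 {m.r_squared:.3f}  MAE {m.mae:.2f}  MSE {m.mse:.2f}  Med {m.med:.2f}")

gates = clock.channel_gates(bm.values[te]).mean(axis=0)
informative = np.isin(np.arange(clock.channels_), truth.informative_channels)
print(f"mean gate: informative channels {gates[informative].mean():.3f}, "
      f"noise channels {gates[~informative].mean():.3f}")
```

Output:

```
stopped at epoch 55, best epoch 35, val MSE 3.04
test R^2 0.997  MAE 1.24  MSE 2.65  Med 0.90
mean gate: informative channels 0.515, noise channels 0.332
```

Training stopped 20 epochs after the validation minimum (epoch 35) and
restored that checkpoint. On held-out samples the clock recovers age to
about one year (MAE 1.24, Med 0.90) on this synthetic cohort, and the
excitation gates are on average higher on channels containing
age-informative loci (0.515) than on pure-noise channels (0.332) — the
attention block has learned which channels carry signal.

The same pipeline is available from the shell:

```bash
perseclock simulate  --out-dir run/
perseclock preprocess --beta run/beta.tsv --panel run/panel.txt --out run/clean.tsv
perseclock train     --beta run/clean.tsv --meta run/meta.tsv --out-dir run/model/
perseclock predict   --beta run/clean.tsv --checkpoint run/model/checkpoint.npz \
                     --meta run/meta.tsv --out run/preds.tsv
perseclock evaluate  --predictions run/preds.tsv --meta run/meta.tsv \
                     --group-by tissue --out run/metrics.tsv
perseclock compare-baseline --beta run/clean.tsv --meta run/meta.tsv --out run/compare.tsv
```

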