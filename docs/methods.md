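# Methods

## Model

PerSEClock is a nonlinear regression of chronological age on CpG beta
values. A length-L input (L = 24,516 at reference size, the CpG set shared
by the Illumina 27K/450K/850K platforms) is reshaped into a
`block_rows × block_cols × channels` tensor (3 × 6 × 1,362 by default) with
the *interleaved* index map: locus i goes to channel `i mod C` at
within-channel position `i div C`, so adjacent loci occupy different
channels. The only architectural constraint the blocking must satisfy is
divisibility (L = rows · cols · C); within-channel placement is irrelevant
to the rest of the network because both pooling and scaling are invariant
to it (this is covered by a property test).

The squeeze-and-excitation block follows the SENet convention: squeeze =
per-channel mean over the 18 block values; excitation = two fully
connected layers, ReLU on a bottleneck of width `max(1, C // r)` with
reduction ratio r (default 16), sigmoid output; scale = per-channel
multiplication by the resulting gate. The regression head is a 4-layer MLP,
each hidden layer `Linear → LeakyReLU(0.01) → BatchNorm1d(32) →
Dropout(0.1)`, then a single linear output unit. Inputs are raw beta
values; no standardization is applied anywhere, since a beta value's
absolute level is itself the biological quantity.

The network is implemented directly on numpy arrays with hand-derived
backpropagation (including the two-path gradient through the excitation
block: the direct scaling path plus the gate path through
sigmoid → FC → ReLU → FC → pooling). Analytic gradients are verified
against central finite differences in the test suite. The optimizer is
Adam with framework-default moments (β₁ = 0.9, β₂ = 0.999, ε = 1e-8).

## Training and evaluation

Data are shuffled and split train/validation/test by fractions
0.81/0.09/0.10 (floor, floor, remainder), which maps 10,589 samples to the
reference 8,577/953/1,059 partition. Training minimizes MSE (years²) in
batches of 512 for at most 150 epochs at learning rate 0.05; after every
epoch the validation MSE is computed in evaluation mode. "Stop at the
lowest validation loss" is operationalized as patience-based early
stopping (default patience 20 epochs) with best-checkpoint restore: the
returned parameters are exactly those of the epoch with minimum validation
MSE, and a test asserts the restored model reproduces that loss to 1e-6.
The last partial batch is kept; a batch of size 1 is skipped with a warning
because batch normalization is undefined there. At prediction time
batch-norm uses running statistics and dropout is off, so predictions are
independent of inference batch size and single-sample prediction works.

Metrics: R² = 1 − SSE/SST, MAE, MSE and Med. Med is the **median of
absolute** deviations |preAge − chrAge|; the even-count median is the mean
of the two central order statistics. Per-group summaries report the mean
*signed* error (preAge − chrAge) together with within-group Med and MAE.

## Preprocessing

Beta matrices are plain delimited text (tab default, comma accepted) in the
GEO series-matrix orientation (loci as rows, first column CpG IDs, header
sample IDs); empty cells and "NA" (case-insensitive) are missing, and "NA"
is written out. Samples with strictly more than 50 % missing beta values
are removed (a sample at exactly the threshold is kept). Locus-panel
intersection reorders columns to the panel, inserts fully missing columns
for absent loci, and logs a warning when more than 10 % of the panel is
absent. The panel itself is user-supplied (one CpG ID per line); no
Illumina manifests ship with the package.

Imputation is regression-based: for each locus with missing entries, an
ordinary-least-squares model on the `max_predictors` (default 5) fully
observed loci most correlated with it (Pearson correlation over the
samples where the target is observed) predicts the missing entries,
clamped to [0, 1]. Ties in |correlation| break by column order (stable
sort). When no regression is feasible (fewer than 2 observations, or no
correlated complete predictor) the locus's observed mean is used; a locus
missing everywhere is filled with the global observed mean and logged.
This is deliberately a simple, transparent scheme in the spirit of
linear-regression imputation for methylation arrays, not a port of any
specific package; its accuracy is quantified by mask-and-recover
experiments rather than assumed.

## Synthetic cohorts

The generator emulates the structure that matters for an epigenetic clock:
a minority of age-informative loci and a majority of noise loci. Ages are
uniform on [age_low, age_high] (default 0–100 years — the age span of
large multi-tissue methylation compendia). An informative locus j follows
β_ij = clamp₀₁( inv-logit(a_j + b_j z_i) + ε_ij ), where z is age
standardized by the theoretical moments of the uniform (so the slope scale
is comparable across age windows), a_j ~ U(−1, 1), |b_j| ~
U(effect_scale/2, effect_scale) with random sign, and ε ~ N(0, noise_sd).
The logistic trajectory keeps values in [0, 1] and mimics the saturating
methylation drift of real clock CpGs; a linear mode exists for testing.
Noise loci draw from Beta(m_j κ, (1−m_j) κ) around a per-locus baseline
m_j ~ U(0.1, 0.9) with concentration κ = 50 (per-locus sd ≈ 0.06 at
β = 0.5, a typical inter-individual spread), plus the same ε. Tissue
labels rotate through 8 tissue names, platform through the three array
types, dataset IDs through 5 synthetic accessions — enough structure to
exercise per-group reports.

Defaults define the package's standard experimental cohort, fixed once:
2,000 samples, 432 loci in a 3 × 6 × 24 geometry, 40 informative loci,
noise_sd 0.03, effect_scale 2.0 (a strong-clock-CpG slope on the logit
scale, of the order seen at the most age-predictive CpGs). This trains in
a few seconds on one CPU, which is what makes three-seed comparisons in
the test suite practical. What passing tests on this cohort do **not**
show: robustness to batch effects, platform chemistry differences,
cell-composition confounding, or non-monotone age trajectories — none of
which the generator simulates.

`inject_missingness` masks an exact count of uniformly chosen observed
entries and keeps the true values under the mask, enabling imputation
scoring.

## Numerical and design choices

- Excitation bottleneck, inner ReLU and output sigmoid follow SENet's
  published defaults; the reduction ratio r = 16 is configurable and must
  not exceed the channel count (small test geometries pass r = 2–5).
- Hidden-layer ordering Linear → activation → batch-norm → dropout mirrors
  the architecture's stated layer list.
- Weight init is the uniform ±1/√fan_in scheme common to deep-learning
  frameworks, drawn from a generator seeded by `random_state`, so runs are
  bit-reproducible (pure-numpy execution is deterministic).
- Input lengths not divisible by rows · cols (· channels) are a hard
  error; `channels=None` infers the channel count from the input length.
- Improvement in early stopping means strictly lower validation MSE; the
  first epoch attaining the minimum is kept on ties.
- Checkpoints are `.npz` archives holding a JSON config plus parameter and
  batch-norm running-stat arrays; loading refuses a checkpoint whose saved
  config conflicts with explicitly requested parameters.
- Degenerate inputs: R² is refused when all actual ages are identical
  (SST = 0); prediction refuses matrices with missing values (impute
  first) and locus orders that differ from the training panel.

## Problem sizes

The test suite and `scripts/acceptance.py` use the standard 2,000 × 432
cohort for training experiments (three seeds, both variants; ~15 s total),
a 400 × 72 cohort for unit-level training tests, and 300 × 36 cohorts for
imputation experiments. Geometry checks run at the full 24,516-locus
reference size, which costs nothing because no training is involved.

## Limitations

- The comparison between the attention clock and the plain MLP is run on
  synthetic cohorts where both models approach the noise floor, so the gap
  between them is small; the ordering (attention ≤ baseline in median Med
  over seeds) is the claim under test, not the margin.
- The imputation scheme requires fully observed predictor loci; cohorts
  where every locus has at least one missing value degrade to per-locus
  mean imputation.
- Single-threaded numpy training is practical up to ~10⁴ samples × ~10³
  loci; the reference 24,516-locus problem at GEO scale would want a GPU
  framework, which is outside this package's scope.
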