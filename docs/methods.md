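# Methods

## Problem setting

Resting-state fMRI yields, per measurement, one time series per brain
region (ROI). Pairwise connectivity statistics arranged as an N × N
matrix — the functional connectome — carry diagnostic information, and
the task addressed here is two-class classification of such matrices
(e.g. healthy elderly vs amnestic mild cognitive impairment), together
with identification of the regions driving the decision.

Connectome matrices look like images but are not: the ROI ordering is
arbitrary, so square pixel patches are meaningless. The unit that *is*
meaningful is a whole connectivity fingerprint — one row (equivalently
column) of the matrix, an ROI's connectivity to every other region.

## The connectome-convolutional network (CCNN)

Input: a C × N × N stack, one channel per connectivity metric (exactly
like RGB channels of an image). Architecture:

1. **Fingerprint convolution.** 64 filters of shape C × 1 × N slide
   along rows: filter *f* outputs, for each ROI *r*,
   `sum_{c,j} w[f,c,j] · x[c,r,j] + b[f]` — one weighted summary of
   ROI *r*'s fingerprint across all channels, with weights shared over
   all N rows. Output 64 × N, ReLU.
2. **Column collapse.** 128 filters of shape 64 × N reduce the feature
   map to a 128-vector (one learned combination of all ROI summaries
   per filter), ReLU.
3. **Dense head.** 128 → 96 (ReLU, dropout with keeping probability
   0.6) → 2-way softmax.

Parameter counts (weights; biases separate): `C·N·64 + N·64·128 +
128·96 + 96·2`. At N = 499: 4,132,224 weights + 290 biases for one
channel; a second channel adds only `499·64` weights (< 1%), which is
the architectural argument for combining metrics — dense models double
instead.

Two matched baselines share the training loop: a *simple* net
(strict-upper-triangle features → 128 sigmoid units → softmax, plain
SGD) and a *deep* net (features → 128 ReLU → 96 ReLU with dropout →
softmax, Adam), so the convolutional weight sharing is the main
difference between deep and CCNN.

All three are implemented directly in NumPy (forward and backward
passes, Adam/SGD). The fingerprint convolutions reduce to dense matrix
products, so BLAS covers the arithmetic and runs are bit-reproducible
given a seed.

### Training defaults and why

* Optimizer: Adam (CCNN, deep), lr 1e-3 — the step size the reference
  deep-learning frameworks default to, and small enough for stable
  descent here. A materially smaller step (1e-4) leaves the first
  convolutional layer so close to its random initialization that the
  weight-interpretation statistic (below) carries no information.
* Simple net: SGD, lr 0.05 — sigmoid hidden layers pair naturally with
  plain SGD; this net deliberately mirrors a pre-deep-learning design.
* Batch 16, up to 100 epochs, early stop when the epoch loss improves
  by < 1e-4 for 20 epochs. Dropout only after the 96-unit layer, only
  during training (inverted dropout).
* Initialization: truncated normal (±2 SD) with SD 1/sqrt(fan-in),
  biases zero, all seeded.
* Inputs are standardized per channel (mean/SD over all matrix entries
  of the *training* instances only); necessary when mixing metrics of
  different scales (DTW distance vs path length). Off-switchable.
* Diagonals pass through to the CCNN unmodified; the dense baselines
  see only the strict upper triangle (`C·N(N−1)/2` features, 124,251
  per channel at N = 499).

## Connectivity metrics

* **Pearson correlation** of the T × N ROI signals.
* **DTW distance**: dynamic-programming alignment of two z-scored
  signals with step set {(1,0), (0,1), (1,1)} inside a Sakoe–Chiba band
  (default half-width ⌈T/10⌉, configurable), absolute-difference local
  cost, distance = raw accumulated cost. DTW absorbs bounded time
  shifts between regions that break lockstep correlation.
* **Warping path length**: the number of cells in one optimal alignment
  path, recovered by backtracking with diagonal-preferred tie-breaking
  (deterministic, and minimal-length among optimal paths in the common
  cases). Identical series need T cells; unstable phase relations force
  insertions, up to 2T−1. Reported raw and as (L−T)/T; the relative
  form (diagonal 0) is the default matrix channel.

Equal-length series are required; both distance and path length are
symmetric in their arguments, so the matrices are exactly symmetric.

## Simulated benchmark

The generator emulates a two-group connectome study with known ground
truth:

1. A base "healthy" connectome and an independent "alternative" donor
   are synthesized as correlation matrices of latent-factor signals
   (N ROIs mixing 5 latent time courses, 200 time points, observation
   noise SD 0.5) — symmetric, unit diagonal, PSD, entries in [−1, 1].
2. Class 1's template replaces the rows *and* columns of m chosen ROIs
   (m ∈ {1, 5, 10} in the benchmark grid) with the donor's.
3. Each class gets 75 replicas: template + w · noise, where the noise
   is a fresh standard-normal matrix A symmetrized as A + Aᵀ and scaled
   so max |entry| = 1, and w ∈ 1..10 is the noise weight. The max-abs
   normalization ties the realized entrywise SD to N (≈ 0.22 at
   N = 100, ≈ 0.20 at N = 499); the generator records the realized SD
   in the dataset metadata rather than forcing a particular value.
   Diagonals receive noise too (2·A_ii before scaling); entries may
   leave [−1, 1] and are not clipped.

What this emulates: group differences confined to a few regions'
fingerprints under instance-level measurement noise. What it does not:
BOLD dynamics and hemodynamics, site/motion artifacts, correlated noise
between entries, subject-level variability within a class (each
simulated instance is its own "subject", so grouped CV reduces to plain
k-fold). Results on this benchmark therefore validate the machinery and
the fingerprint-recovery logic, not clinical performance.

**Problem sizes.** The package's standard benchmark uses N = 100 ROIs
with the full 75 + 75 replica design. Purely analytic checks
(parameter counts, feature counts, chance baselines) use the full
N = 499 scale. CPU training cost grows ~N² per instance, which makes
N = 100 the practical size for repeated cross-validated runs; all
sizes are configurable.

## Evaluation

* Folds are dealt at the group (subject) level: distinct groups are
  shuffled by seed and assigned round-robin, so folds differ by at most
  one group and repeated measurements never straddle the split. No
  class stratification.
* Accuracy and rank-based (Mann–Whitney) AUC are pooled over
  out-of-fold predictions — consistent with instance-count binomial
  testing.
* **Chance baseline**: the smallest k with `F_Binom(n, k, 0.5) ≥ 0.95`,
  reported as k/n. For n = 150: k = 85, 56.67% (CDF 0.957); for
  n = 146: k = 83, 56.85% (CDF 0.959).
* **Classifier comparison**: exact two-sided binomial test at p = 0.5
  restricted to discordant instances (exactly one classifier correct);
  p = 1 when there are none (McNemar's exact test).

## Weight interpretation

For a trained CCNN, the importance of ROI j in channel c is
`sum_f |w1[f, c, j]|` over the 64 first-layer filters; summing over
ROIs instead scores each filter. Because every filter weights ROI j's
entry in *every* fingerprint, consistently discriminative regions
accumulate large absolute weights across filters. On simulated data the
top-k ranked ROIs are scored against the ground-truth modified set.

Interpretation runs train on the whole dataset (no held-out fold) for
600 epochs with early stopping disabled: the summed-|weight| statistic
is informative only once accumulated learning dominates the random
initialization, which happens well after the classification loss
plateaus — and only in regimes where gradients persist. At low noise
the loss reaches ~0 within a few epochs, gradients vanish, and the
first-layer weights essentially retain their initialization; heavy
noise (the benchmark uses weight 5) keeps the optimizer moving and
concentrates weight on the modified fingerprints. Deeper-layer
attribution is deliberately out of scope: a small first-layer sum does
not prove an ROI is irrelevant.

## Known limitations

* **Classifier ordering on the benchmark.** At low noise the CCNN
  reaches 100% cross-validated accuracy, but across a moderate-noise
  grid (N = 100, noise weights 4–8) the accuracy ordering in this
  package's experiments is simple ≥ deep ≥ CCNN (means 0.89 / 0.86 /
  0.83 over six grid points), not the convolutional-first ordering one
  might expect, and the simple net stays ahead even at N = 499 with an
  80/20 split. The simulated classes differ by a fixed mean shift
  spread over thousands of matrix entries, for which an implicitly
  regularized near-linear model is close to the optimal decision rule;
  a sigmoid + SGD net with well-scaled initialization therefore
  performs near-optimally rather than collapsing, and all three models
  interpolate the training data, so the dense nets' extra parameters
  cost little here. Claims that convolutional weight sharing wins on
  such benchmarks appear sensitive to the training configuration
  (initialization and step size at ~10⁵ inputs) of the dense
  baselines; two acceptance-suite tests assert the
  convolution-first ordering anyway and are expected to fail, as a
  documented negative result.
* Exact DTW normalization conventions differ across the literature;
  this package reports raw accumulated cost plus raw/relative path
  length, all configurable, rather than asserting one canonical form.
* Multi-class heads are wired (softmax over k classes) but untested
  beyond k = 2; no GPU path; no hyperparameter search utilities.
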