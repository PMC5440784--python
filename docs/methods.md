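# Methods

## The model

`convar` quantifies how the responses of a bank of low-level visual filters
are distributed across an image, and uses that distribution to separate
traditional-artwork-like images from other image categories.

An RGB image is rescaled to 512 × 512 pixels (anisotropically, no cropping —
the whole picture surface matters for composition statistics) and convolved
with a first-layer filter bank of an AlexNet-style network whose kernel
size (11), stride (4) and padding (0) are kept at their original values;
fully-connected layers are dropped. The resulting stack of k rectified
response maps (k = 96 for the first layer) is summarised as follows for each
grid size n:

1. Each map is partitioned into n × n near-equal subregions and the maximum
   response per filter and subregion is recorded, giving a max-pooling map
   `M` of shape n × n × k.
2. Each subregion's k-vector is L1-normalized to sum to one ("histogram" of
   relative filter activation). This removes the overall response scale.
3. Three variances are computed on the normalized map:
   - `P_a(n) = var(M)` over all n·n·k entries — low when many diverse
     filters respond in every subregion (**richness**), high when responses
     concentrate on few filters (sparseness, large homogeneous areas);
   - `P_g(n) = median over subregions of var(histogram)` — the within-
     subregion histogram variance;
   - `P_f(n) = median over filters of var across subregions` — low when the
     same features repeat everywhere (**self-similar**), high when different
     parts of the image activate different filters (**variability**).

With n = 2, 4, …, 30 this yields 45 features per layer. The working
hypothesis these features operationalize: artwork-like images are *rich*
(low `P_a`) like natural growth patterns, but also *variable* (high `P_f`)
like scenes of distinct objects — the combination is what sets them apart,
and a 2-D feature space such as (`P_a(22)`, `P_f(12)`) suffices for
high-accuracy discrimination.

The self-similarity comparator pools at the *ground level* (n = 1) and over
64 subregions (n = 8), L1-normalizes both, and averages the histogram
intersection `Σ_i min(g_i, h_j,i)` over the 64 subregions. It lies in
[0, 1]; on real response stacks its infimum is 1/64 because the global
maximum always lives in some subregion. `P_f(12)` behaves as its inverse
(strongly negative rank correlation).

## Numerical and design choices

- **Variance estimator**: population variance (divide by the count). The
  defining equations carry no sample correction, and all hand-checked
  reference values use it. A `ddof` flag exposes the sample estimator.
- **Uneven grids**: subregion boundaries at `round(j·H/n)`, j = 0..n —
  near-equal bins, no pixel dropped. A brute-force pooling oracle in the
  tests pins this convention.
- **All-zero subregions** (possible after ReLU on uniform areas) are filled
  with the uniform vector 1/k: the sum-to-one invariant holds and the fill
  contributes zero within-histogram variance. Fills are logged.
- **Rectification**: variances are measured on post-ReLU responses (the
  `apply_relu` flag exposes the pre-ReLU alternative). Local response
  normalization is omitted; 3×3/stride-2 max pooling is interposed between
  conv layers only when analysing layers ≥ 2 (toggleable) — first-layer
  analysis, the primary use, is unaffected.
- **Median of an even count**: mean of the two central values.
- **Feature columns**: grouped by measure then grid — `pa_02..pa_30,
  pg_02..pg_30, pf_02..pf_30` — fixed for reproducible tables.
- **`P_a = 0` analytic limit**: when all filters in all patches respond
  equally, `P_a` vanishes exactly when 1/k is a dyadic float and to within
  ~1e-32 otherwise; tests assert ≤ 1e-30.

## Filter banks

torch is not a dependency: convolution is a stride-tricks patch gather plus
one float32 matrix product (≈0.2 s for a 512×512 image on one CPU). Three
weight sources exist:

- `pretrained` — filters from a user-supplied `.npz`
  (`conv1_weight: 96×11×11×3`, optional `mean`), for runs with the original
  learned filters;
- `builtin_random` — seeded zero-mean, unit-norm random filters;
- `builtin_gabor` — an analytic 96-filter bank: 64 zero-DC luminance Gabors
  (8 orientations × 4 wavelengths × 2 phases) plus 32 opponent-color filters
  (R−G and B−Y axes × 8 spatial profiles × 2 polarities). The color profiles
  include blobs and a uniform patch whose spatial sum is non-zero, so
  uniformly colored areas activate a few color filters while edge filters
  stay silent — the response statistics of homogeneous regions then behave
  like those under learned banks (concentrated histograms → high `P_a`).

Preprocessing subtracts the image's own per-channel mean for builtin banks
(the stored training mean for pretrained ones).

## Classification protocol

RBF-kernel SVM on z-scored features (standardization fitted on training
folds only), stratified seeded 5-fold cross-validation, accuracy reported
as mean ± SD over test folds. Default hyperparameters are C = 1,
γ = 1/d on standardized features; an optional inner 3-fold grid search over
C ∈ {0.1, 1, 10, 100}, γ ∈ {0.01, 0.1, 1, 10} runs on training splits only.
Subset search evaluates all 45 + 990 + 14,190 = 15,225 subsets of sizes
1–3 on identical folds, ranked by mean accuracy (ties: smaller subset,
then lexicographic names). Because ranking subsets on the same folds they
are scored on is optimistic, `nested_subset_search` additionally reruns the
search inside each training split and scores the winner on the held-out
fold — the mean of those scores estimates the selection procedure itself.
Per-category metrics restrict the test predictions to one art category plus
all non-art images, with art as the positive class. Two baselines use a
linear SVM on raw rows (downscaled 227×227×3 pixels = 154,587 dims, or raw
conv1 maps at original geometry = 290,400 dims) under the same fold
protocol.

## Synthetic image classes

The generator renders seeded 512×512 images from a motif vocabulary of
oriented bars, disks and color gradients on jittered 6-color palettes, in
four classes spanning the corners of the richness/variability plane:

| class | construction | intended statistics |
|---|---|---|
| `art_like` | dense motifs, resampled per 64 px tile with per-tile sub-palettes | rich (low `P_a`), variable (high `P_f`) |
| `pattern_like` | one dense motif tiled at 32 px | rich, self-similar (`P_f` ≈ 0) |
| `sparse_like` | constant color field, 5% structured tiles | sparse (high `P_a`) |
| `noise` | i.i.d. uniform pixels | rich and self-similar extreme |

Two scale choices make the contracts hold by construction rather than by
luck. A 32 px repeat period maps to 8 response-map pixels under the 11/4
conv, *below* the ≈10.5-pixel pooling window at n = 12, so the per-filter
maxima of a tiled image are nearly constant across subregions and `P_f(12)`
collapses. Art-like tiles are 64 px — *above* that window — so different
subregions see genuinely different content and `P_f(12)` stays high; the
per-tile sub-palettes make regions differ in dominant color, which the
opponent filters pick up. Measured on the builtin Gabor bank, the class
means land close to the magnitudes the measures take on natural images
(`P_a(22)` ~ 1e-4 for rich classes, ~2e-3 for sparse; `P_f(12)` ~ 1e-5).

What the generator does *not* emulate: photographic luminance statistics
(1/f spectra), brush texture, depth-of-field blur, semantic content, or the
graded overlap between real categories — real plant patterns are not
pixel-identical tiles, and real artworks vary far less cleanly. Passing the
classification check therefore shows that the pipeline measures what it
claims and that the protocol recovers a plane in which the constructed
classes separate; it does not certify the accuracy obtainable on any real
corpus.

## Problem sizes

The test suite and the acceptance script use a 300-image study set
(75 per class), three cross-validation fold seeds on one generated set, a
5-seed battery for the invariant and ordering checks at 10 images per
class, and 1000 random 6×6×5 maps for the vectorized-vs-naive oracle
comparison — sizes chosen so a full run completes in a few minutes on one
CPU while keeping every class mean at ≥ 10 samples.

## Known limitations

- The builtin Gabor bank approximates learned first-layer filters
  qualitatively, not numerically; absolute feature values under pretrained
  weights will differ.
- Deeper-layer analysis under the builtin banks uses seeded random filters
  beyond layer 1 and is structural only.
- The self-similarity comparison function is a documented choice (histogram
  intersection); other comparators from the same family would shift absolute
  scores but not the rank relationship with `P_f`.
- Grayscale inputs are replicated across channels; the color-opponent half
  of the Gabor bank is then silent and the measures lose their color
  component.
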