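# Methods

## The analysis in one paragraph

A labelled corpus of non-figurative drawings (one class per season of
production) is analysed three ways with one frozen convolutional
backbone: (1) a small trained head measures how much season signal the
whole network carries; (2) per-layer *content* probes (PCA + linear SVM
on flattened activations, RGB vs NTSC grayscale) locate that signal in
depth and ask how much of it is colour; (3) per-layer *style* probes
(PCA + SVM on flattened Gram matrices G = FᵀF) ask whether the texture
of the drawing, rather than its content, tracks the season, and whether
style information deepens (regression of accuracy on layer index). All
model-vs-baseline comparisons use the 5×2cv paired t-test.

## Backbone

The canonical 16-conv-layer VGG19 trunk: widths
(64, 64, 128, 128, 256×4, 512×4, 512×4), 3×3 kernels, padding 1, 2×2
max-pool after each block, followed by two hidden fully connected stages
of width 4096. Probed activations are taken **post-ReLU** (the standard
convention; the alternative is pre-activation and nothing downstream
depends on the choice beyond it being fixed). Inputs are scaled to
[0, 1]; no channel-mean subtraction is applied because the shipped weight
mode is `seeded_random` (He-initialised, zero biases, reproducible from an
integer seed) for which no canonical preprocessing mean exists. The
`pretrained` source refers to the published ImageNet weights; since no
weight file can be bundled or fetched in an offline run it raises an
explicit error. Random convolutional features are a well-established
linear-probing baseline; the recovery experiments below show they carry
the planted colour/shape/texture signals, but they are *not* a substitute
for trained features where absolute accuracies matter (see Limitations).

The forward pass is numpy (im2col + BLAS sgemm, float32): the backbone is
never trained, so an autodiff framework buys nothing. Full 16-layer
forward of one 224×224 image ≈ 1–1.5 s on one CPU core; all experiment
sizes below were chosen around that unit cost.

## Synthetic scribbles

Each image is a near-white board (245, 245, 245) — not pure white, so
ink/board thresholding has no ties — on which strokes are drawn as
constant-speed random walks (step 2.5 px, 30–90 steps) with Gaussian
turning angles; the turning-angle spread `curvature_scale` is the shape
dial: 0 gives straight sweeps, ≳2 tight jitter. Strokes are painted as
hard disks along the path (no anti-aliasing), so every pixel is exactly a
crayon colour or the board and coverage is exactly countable. Colour and
width are sampled per stroke (crayon-like). Per-image seeds derive from
`SeedSequence([dataset_seed, index])`, so datasets are bit-reproducible
and any single image can be regenerated alone.

All five crayons are luminance-matched: each RGB triple rounds to NTSC
grey 130. This is the load-bearing design choice for the colour
experiments — a preset whose seasons differ *only* in palette produces
grayscale images that are statistically identical across seasons, so a
grayscale probe must fall to chance, and any residual grayscale accuracy
would indicate leakage in the pipeline rather than in the data.

Presets (the real corpus has no published quantitative stroke statistics,
so magnitudes are free parameters of the generator, fixed once):

- `paperlike`: green-dominant palettes in summer/winter, pink-dominant in
  spring/autumn (0.65 dominant weight, distinct secondaries), plus
  per-season stroke count/width/curvature differences.
- `color-only`: the four palettes differ, stroke statistics shared.
- `shape-only`: one shared palette, per-season stroke statistics.
- `style-only`: one shared palette, shared counts and widths, a shared
  ink-coverage target of 0.30, and *only* curvature differing —
  geometrically spaced (0.03, 0.2, 0.8, 2.4) so that each successive pair
  becomes distinguishable at a larger spatial scale: σ = 2.4 vs 0.8 at a
  few pixels, 0.8 vs 0.2 at tens of pixels, 0.2 vs 0.03 only over ~100 px
  of stroke. The coverage target pins the ink budget, so shallow
  local statistics match across seasons and the signal must emerge with
  receptive-field size.
- `null`: all four seasons identical; the negative control every
  downstream stage must respect.

Default class counts are the corpus's printed 374/269/284/372
(autumn/spring/summer/winter). The generator emulates class-conditional
colour, stroke-shape and coverage statistics; it does **not** emulate
crayon texture, pressure, paper grain, compositional intent, or temporal
drift within a season, so green tests certify the pipeline's causal
logic (signals planted are recovered, absent ones are not), not any claim
about real orangutan drawings.

## Image preparation

Resize to 224×224 by bilinear resampling of both axes independently
(stretch); a centre-crop mode is provided since the original protocol's
"reshaped to squares" is ambiguous. NTSC grayscale uses
Y = 0.299R + 0.587G + 0.114B rounded half away from zero, clamped, and
replicated to three channels (idempotent to ±1 grey level). Coverage is
the fraction of pixels whose max-channel distance from the board colour
exceeds a tolerance (default 8). The binary-coverage task thresholds at
the dataset median by rank, so the classes differ by at most one image
even with ties. Splits are stratified by season via seeded
`train_test_split`, keeping each class share within one image.

## Transfer head

Global average pooling of the last conv layer's maps (512 values) →
batch-norm → FC 2048 (L2 0.1) → dropout 0.2 → softmax; SGD lr 0.1, batch
16, categorical cross-entropy, horizontal+vertical flip augmentation of
the training stream only, early stopping on validation accuracy with the
best-epoch weights restored. Because the backbone is frozen, pooled
features (including the four flip variants — flips do not commute with
convolution, so each variant is extracted, not mirrored) are computed
once and cached; training then touches only head parameters and is
mathematically identical to training on top of the network.

Batch-norm uses batch statistics in training and running statistics
(momentum 0.9) at evaluation; the backward pass goes through the batch
statistics. Gradients are verified against finite differences in the
test-suite.

One scale-dependent knob: early-stopping patience counts *epochs*, but
its effective meaning is gradient steps. The original protocol (patience
3) tolerates ≈170 steps at its 907-image training set; a 40-image
synthetic run has 3 steps per epoch, so the package's small-scale
experiments use patience 15 (≈45 steps) with the same lr/L2/dropout.
`HeadConfig` defaults remain the protocol values.

## Probes

Content probe per layer: activations flattened channel-major; conv1 and
conv2 first reduced to 50% of their columns by random subsampling — one
index set per repeat, shared across images because the subsequent PCA
needs feature correspondence — with a one-sample t-test comparing the 50
repeat means of the reduced matrix against the original grand mean
(`SubsampleReport.passed` at α = 0.05). PCA retains the smallest number
of components reaching 80% explained variance and is computed through the
dual n×n eigenproblem (images ≪ features); it is checked against a
brute-force covariance eigendecomposition and sklearn in the tests. The
SVM is a standardise + linear one-vs-rest pipeline (cost 1), scored by
seeded stratified 10-fold CV (leave-one-out when folds equal samples).
PCA is fitted on all images before CV — the study protocol — with an
optional `leakage_free` mode refitting PCA inside each training fold.

Slope test: OLS of mean accuracy on depth index (conv1…conv16 → 1…16,
FC1 → 17, FC2 → 18), two-sided t-test on the slope, n−2 df; a degenerate
zero-residual fit returns p = 1 for zero slope and p → 0 otherwise.

Style probe per conv layer: G = FᵀF with maps as columns of F (C×C
output), flattened in full (C²; no upper-triangle deduplication), same
PCA+SVM machinery. FC layers are rejected — they have no feature maps.
Gram normalisation options: none (default, the plain protocol), `size`
(divide by map size N, style-transfer convention), and `unit` (per-image
L2-normalised Gram vector). The `unit` option matters: the largest
variance direction of raw Gram vectors is overall activation energy
(≈ ink budget), and when an experiment deliberately pins the ink budget
(the `style-only` preset) the 80%-variance PCA on raw Gram vectors keeps
mostly that nuisance direction. Unit normalisation removes the energy
magnitude and probes the relative co-activation structure — texture in
the proper sense. The depth-slope recovery experiment therefore probes
unit-normalised Gram vectors; the pipeline's descriptive style curves use
the plain protocol.

## Statistics

Dummy baseline = modal-class share. 5×2cv paired t-test: five seeded
2-fold stratified CVs; both procedures fit/predict on identical splits;
t = d₁₁ / √((1/5) Σᵣ sᵣ²) with sᵣ² the variance of the two fold
differences of replication r, 5 df, two-sided. The statistic depends on
replication order, so the order is seed-determined and the full 5×2
accuracy tables are recorded. Degenerate cases are explicit contracts:
identical procedures give t = 0, p = 1; zero denominator with nonzero
numerator gives p = 0 with a degeneracy flag. The same conventions hold
for the one-sample t-test. Calibration is tested empirically: across 200
null simulations (two logistic regressions reading two exchangeable,
equally informative features) the rejection rate at α = 0.05 must lie in
[0.02, 0.10]; null one-sample p-values must pass a KS uniformity check.
No multiple-testing correction is applied to the per-layer tests (the
protocol applies none), but every comparison table carries a
Holm-adjusted column.

## Pipeline

`RunConfig` is a flat, fully-seeded YAML document; unknown keys are
errors (a silently ignored typo in a seed field would corrupt any
reproducibility claim). Stages write under `out/<stage>/` with a
`.stage_key` fingerprint hashing the stage-relevant config plus all
upstream fingerprints: re-runs resume from the first changed stage, and
changing the dataset seed invalidates everything downstream. Each stage
logs one structured line (stage, key, wall time). Every report figure
(confusion heat map, layer accuracy curves, gram scatters) has a CSV twin
with exactly the plotted numbers.

## Problem sizes

The packaged experiments use 15 images per season for probe/head
recoveries and 20 per season (×3 dataset seeds, pooled OLS over the
3×16 layer accuracies) for the style depth slope; the tiny end-to-end
determinism run uses 4 per season. These sizes are where the qualitative
contracts (beats dummy / at chance / slope sign) are stable across seeds
while a full study remains a desk-scale computation; absolute accuracies
at these sizes are not comparable to a 1299-image corpus.

## Known limitations

- With random backbone weights, probe accuracy does not increase
  monotonically into the deepest block: at 14×14 resolution a 512×512
  Gram matrix is estimated from 196 spatial samples and is noisy, and
  deep random features mix rather than abstract. The style depth slope is
  therefore a statement about the overall trend (pooled OLS over all 16
  conv layers), not about conv16 being the best layer.
- The 80%-variance rule can keep a single nuisance component (see the
  Gram energy discussion above); this is a faithful property of the
  protocol, surfaced here because synthetic data make it visible.
- The generator's stroke model is a random walk; it does not produce
  loops, fans, or figurative structure, and palette weights/stroke
  magnitudes are package choices, not measured values.
- Reported accuracies on synthetic data say nothing quantitative about
  the original corpus; the headline numbers of the motivating study
  (41.6% season accuracy etc.) require the undeposited drawings.
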