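# Methods

This note records the modelling choices behind `ptxmode`: what the
synthetic generator does and does not emulate, the exact semantics of each
pipeline operator, the numerical conventions, and the places where the
design was genuinely open and a choice had to be made.

## The synthetic image model

The generator renders the *signs* a sonographer reads, not the physics
that produces them. An M-mode image is assembled in three vertical zones:

- **Chest wall** (rows above the pleural line): a depth-only intensity
  profile with `chest_band_count` smooth quasi-periodic bands, broadcast
  across time — perfectly laminar, like the muscle striations of a layered
  phantom or real chest wall.
- **Pleural line**: a 2–3-row band at intensity 0.97, by construction at
  or above the image's 90th intensity percentile.
- **Sub-pleural zone**: the class-defining texture. PTX-negative renders
  isotropic granular speckle — uniform noise blurred with a Gaussian of
  sigma `speckle_grain_px / 2`, rescaled to [0.05, 0.80] — with a gentle
  (±12 %) sinusoidal column-intensity modulation at the respiratory rate.
  PTX-positive renders a second laminar depth profile: the barcode.

B-mode frames add rib-shadow attenuation columns (gain 0.12 below the
superficial layer), B-line streaks anchored to the sub-pleural texture,
and, for PTX-negative clips only, a sinusoidal lateral texture shift
(lung sliding) sampled from a wider speckle strip.

Appearance is applied last, per pixel:
`clip(contrast_gain · (x − 0.5) + 0.5 + brightness_offset + ε, 0, 1)` with
`ε ~ N(0, noise_sd²)`. Because texture and appearance are factored, the
same seed rendered in two domains differs *only* in its intensity map —
the controlled appearance-only domain shift the ablation needs.

What this emulates well: the texture dichotomy (a threshold on the mean
absolute lag-1 column difference below the pleura separates the classes
essentially perfectly), global appearance shifts, and the segment-level
data flow. What it does not: acoustic propagation (attenuation with
depth, beam geometry, reverberation), anatomical variability, probe
motion, or annotation noise. Passing tests therefore demonstrate that the
pipeline and classifier behave correctly on imagery with the right
*sign structure*, not that the trained weights would transfer to clinical
images.

### Domain parameters

| parameter | phantom | swine | units / meaning |
|---|---|---|---|
| `brightness_offset` | 0.00 | −0.30 | additive, [0,1] intensity scale |
| `contrast_gain` | 1.0 | 2.0 | gain about mid-gray |
| `speckle_grain_px` | 1.5 | 3.0 | speckle blob size (blur sigma ×2) |
| `noise_sd` | 0.02 | 0.05 | additive Gaussian sd |
| `pleural_depth_frac` | 0.35 | 0.42 | pleural line depth / image height |
| `chest_band_count` | 4 | 6 | laminar chest-wall bands |
| `ptx_brightness_bias` | +0.15 | 0.00 | extra brightness on positives |

The swine values were calibrated once, against the no-augmentation
ablation condition, to produce the qualitative cross-domain collapse the
experiment is about, and then frozen.

`ptx_brightness_bias` deserves its own paragraph. Positive and negative
captures come from different acquisition sessions (the lung is halted and
the apparatus re-adjusted between them), so their global brightness can
differ systematically. A purely global domain shift turns out to be
insufficient to break a texture classifier: convolutional features of the
laminar/granular distinction are fairly robust to monotone intensity
changes, and in exploratory runs an unaugmented model still reached
~0.65–0.75 cross-domain accuracy however hard the global shift was pushed
— while pushing it far enough to hurt also destroyed the recovery under
histogram matching. The collapse mechanism is instead *shortcut
learning*: with a class-correlated brightness confound in the source
domain, the unaugmented model learns "brighter ⇒ positive", and on the
uniformly darker target domain predicts nearly everything negative
(accuracy ≈ 0.5 with an all-negative confusion matrix). Histogram
matching and brightness/contrast jitter delete exactly this shortcut,
forcing the model onto the texture features that do transfer. With the
confound at +0.15 the four-condition ablation reproduces the expected
pattern robustly across master seeds: ≈0.55 (none), 0.50 (flip/zoom),
≈0.9 (histogram matching), ≈0.93+ (jitter) on the swine test, with
same-domain accuracy ≈1.0 throughout.

### Seeding

Dataset seeds derive per image as `seed + 2·i + is_positive`, so growing
`n_per_class` extends a dataset without re-rendering earlier images. All
other consumers (splits, augmentation draws, weight init, dropout, batch
order) take explicit seeds; two runs with the same seeds are bitwise
identical in single-threaded execution.

## Preprocessing conventions

- Rolling-window offsets are equally spaced and endpoint-inclusive:
  `offset_i = round(i · (span − w) / (n − 1))`. This is the only reading
  of "evenly split into a fixed count via a rolling window" in which the
  first window starts at 0 and the last ends flush with the span; with
  the defaults (5-s capture, 1-s window, 100 segments) consecutive
  windows overlap by ~96 %. Splitting is an exact crop; resampling
  happens only at the final resize.
- Resizing is plain bilinear to a square; aspect ratio is not preserved.
  The single gray channel is replicated ×3 to fit the model input.
- Settings-bar crop coordinates are per-device configuration, never
  auto-detected.
- Split sizes use `floor(fraction · n)` per class for validation and
  test with the remainder assigned to training (10 per class at 70/15/15
  → 8/1/1). Assigning the remainder to training is the only convention
  consistent with "rounded, remainder to training" at these set sizes.

## Augmentation semantics

- Levels are cumulative. Geometric operators (reflections, zoom) and
  jitter touch training images only; histogram matching, being a
  preprocessing step against a fixed target-domain reference, is applied
  to every image of every role.
- Zoom is center-anchored; shrinking pads reflectively rather than with
  zeros so that border fill cannot correlate with class.
- Histogram matching is the binned CDF-specification rule: 64 equal-width
  bins on [0, 1]; source bin *j* maps to the center of the first
  reference bin whose cumulative mass reaches the source CDF at *j*. The
  mapping is monotone, idempotent up to bin quantization, and never
  increases the 64-bin earth-mover distance to the reference. One
  reference image (a designated swine-domain PTX-negative segment) is
  fixed per experiment and recorded in the manifest.
- "Doubling" at level 3 means each training image is *replaced* by one
  brightness-jittered copy (`x + b`, `b ~ U(−0.5, 0.5)`) and one
  contrast-jittered copy (`0.5 + g·(x − 0.5)`, `g ~ U(0.7, 1.4)`), i.e.
  output count = 2 × input count. Keeping the originals as well would
  triple the set; doubling is the declared contract.
- Augmentation is pre-generated with recorded draws rather than applied
  on the fly per epoch, trading a little regularization diversity for
  exact reproducibility.

## Architecture and optimization

The declared contract is six convolution blocks with max pooling, 36 %
dropout, a 214-node dense layer and a 2-way softmax. The remaining
details are design choices exposed in `ArchitectureConfig`: 3×3 kernels
throughout, filter counts doubling 8 → 256, ReLU activations, He
initialization for conv/hidden layers and Glorot for the output layer.
"Sparsely connected" is read as ordinary local convolution (as opposed to
the dense layers), with no custom sparsity mask. The optimizer is Adam at
the stated learning rate 0.001 with categorical cross-entropy; neither
optimizer nor loss is part of the contract, so both are configuration.

The network runs on a small numpy engine written for this package:
im2col + BLAS matrix products for stride-1 same-padded convolution, 2×2
max pooling with tie-split gradients, inverted dropout, and analytic
backpropagation verified against finite differences in the test suite.
Arithmetic is float32; the input image needs no gradient, so the first
conv layer skips its input-gradient computation.

## Training protocol numerics

- Early stopping: strict improvement of validation loss resets the
  patience counter; an epoch merely equalling the best loss does not.
  Training stops after `patience` (default 5) consecutive non-improving
  epochs or at the epoch cap, and the returned weights are those of the
  minimum-validation-loss epoch, not the final one. The rule is factored
  into a pure function (`early_stopping_trace`) so it can be tested
  against scripted loss sequences.
- Replicates share one data split by default and differ only in
  initialization, dropout and batch order — so replicate spread isolates
  seed-driven training variance. Re-splitting per replicate would mix in
  partition variance.
- Divergence (non-finite loss) raises an error naming the epoch; a
  failing replicate is recorded and never aborts the remaining ones.

## Evaluation conventions

"Positive" is PTX-present everywhere. Metrics with a zero denominator
(precision under an all-negative predictor, and F1 with it) are reported
as absent — never coerced to 0, which would corrupt replicate means.
Replicate aggregation averages row-normalized percent matrices (mean
percent per confusion cell across models) and averages each metric over
the models where it is defined; on balanced test sets the overall
accuracy equals the mean of the two per-class rates. Mean metrics print
with 3 decimals and percent matrices with 1; CSVs keep full precision.
Metrics are averaged per-model rather than computed from pooled counts;
for equal test sizes the percent-matrix aggregation is identical either
way, but per-model metric means preserve the absent-metric convention.

## Problem sizes

The package's default experiment sizes are a desk-scale rendition chosen
so a full run completes in minutes on a single CPU core: 64-px model
input for the ablation (15 captures per class × 10 segments, three
replicate seeds, ≤10 epochs; ~90 s), 128-px input with 200 segments per
class for the same-domain benchmark (three replicates, ≤20 epochs;
~4 min). Every stage scales to the full-size setting (512-px input, 100
segments per capture) through configuration alone; nothing in the code
depends on the reduced sizes.

## Known limitations

- The generator's separability is by construction much cleaner than
  clinical imagery; absolute accuracies on synthetic data say nothing
  about clinical performance, only the *relative* ablation pattern is
  meaningful.
- The domain gap is purely an intensity-map difference (plus the
  class-brightness confound); real phantom-to-animal gaps also involve
  anatomy, probe handling and depth-dependent attenuation that
  histogram-level remedies cannot address — the geometry-shift probe
  during calibration showed exactly that failure mode.
- The numpy engine is single-threaded and CPU-only by design; it is not
  intended for inputs beyond a few hundred pixels or datasets beyond a
  few thousand segments.
- B-mode clips are generated and preprocessed but not classified; the
  classification experiments are M-mode only.
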