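# Methods

This note describes the models and procedures implemented in `viaphase`,
the choices made where the design was open, and what the bundled
synthetic experiments do and do not demonstrate.

## Phase reconstruction and dry mass

Spatial light interference microscopy records four intensity frames
while stepping the phase delay between the incident and scattered
fields by θ ∈ {0, π/2, π, 3π/2}.  Under the common-path two-beam model

I_k(x) = I₀ (1 + b² + 2b·cos(φ(x) + θ_k)),

the frame differences isolate the quadratures:
I(3π/2) − I(π/2) = 4bI₀·sin φ and I(0) − I(π) = 4bI₀·cos φ, so the
four-step estimator

Δφ = atan2(I₃ − I₁, I₀ − I₂)

recovers φ exactly for any b > 0 in the noise-free case.  The library's
default ("identity") mode returns Δφ; a second mode composes the total
object phase as φ_tot = atan[b·sin Δφ / (1 + b·cos Δφ)] for a
user-supplied amplitude ratio b.  Identity mode is the default because
estimating b from data (and correcting the halo artifact) is outside
the package's scope, and because the bundled simulator uses exactly the
forward model above, making forward + inverse a self-consistent,
testable pair (round trip < 1e-6 rad, in practice ~1e-15).

Pixels where both atan2 arguments fall below 1e-12 of the stack's
intensity scale carry no phase information; they are set to 0 and
counted, and the reconstruction is rejected if they exceed half the
image (e.g. a flat field).

Phase is proportional to the non-aqueous ("dry") mass surface density
through the refractive increment α of cellular matter, so the mass of a
segmented region is

m = λ/(2πα) · Σ_{x∈mask} φ(x) · (pixel size)².

Defaults: λ = 0.55 µm (centre of a broadband LED spectrum, not stated
by the instrument), α = 0.2 µm³/pg (the standard protein value),
pixel size 0.1625 µm (6.5 µm camera pixel behind a 40× objective);
after the customary 2× downsampling the working pixel is 0.325 µm.
All three are configurable.

## Fluorescence-derived ground truth

The dual-reagent viability stain gives a blue channel (all nuclei) and
a green channel (nuclei with compromised membranes).  Ground truth is
generated by:

1. Gaussian presmoothing of the blue channel (σ = 2 px), global Otsu
   threshold, 8-connected components, minimum area 50 px, optional
   removal of border-touching objects (kept by default).
2. Per nucleus n, the relative intensity r(n) = mean(green|n) /
   (mean(blue|n) + 1e-9); the nucleus is called dead iff
   r(n) ≥ 0.5, with the tie resolving to dead.  The ratio of means is
   invariant to a common gain on both channels.

The exact statistic and threshold used for "relative intensity" in the
original assay are not published; the per-nucleus mean ratio with a 0.5
threshold is the simplest monotone rule with one interpretable
parameter, and every parameter above is exposed in `GtConfig`.

## The segmentation network

The segmenter is a U-Net-shaped encoder–decoder mapping a normalized
phase image to per-pixel probabilities over {live, dead, background}
(class codes 0/1/2), with the label taken by softmax + argmax.  Two
encoder families are provided:

* **tiny** — four plain conv–BN–ReLU downsampling stages
  (8→16→24→32→48 channels, ~0.11 M parameters, /16 total
  downsampling).  This is the desk profile used by the test suite.
* **b0…b7** — EfficientNet-style encoders of MBConv inverted-bottleneck
  blocks (1×1 expand by 1 or 6 → depthwise 3×3/5×5 → 1×1 project, ReLU
  for expansion 1 and ReLU6 for expansion 6, residual skip omitted in
  the first block of each stage), scaled by the usual compound
  width/depth coefficients, /32 downsampling and a five-stage decoder.

The decoder upsamples by nearest-neighbour ×2, concatenates the
matching encoder feature map and fuses with conv–BN–ReLU; the head is
a 1×1 projection to 3 logits.  Everything — layers, losses, Adam — is
implemented directly in numpy with hand-written backpropagation, and
gradient correctness is asserted against central differences in the
test suite.  Encoders can be initialized from externally supplied
weights by parameter name (`load_encoder_weights`); by default all
weights are He-normal from the run's seed, and no pretraining is
performed or downloaded.

### Loss

Training minimises α·L_focal + β·L_dice with binary indicators
(α, β ∈ {0,1}, not both 0; defaults [1, 0]):

L_focal = −(1/B) Σ_i (1/MN) Σ_x [1 − yᵢ(x)ᵀpᵢ(x)]^γ · yᵢ(x)ᵀ log₂ pᵢ(x)

with γ = 2 and the **base-2** logarithm retained exactly as the loss is
defined for this assay (a constant 1/ln 2 factor versus the natural-log
convention of common libraries).  Probabilities are clipped to
[1e-7, 1] before the log.

L_dice = 1 − (1/3) Σ_c (2TP_c + ε)/(2TP_c + FP_c + FN_c + ε), ε = 1e-6,

with TP/FP/FN counted over all pixels of the whole batch (micro).  The
ε-smoothing makes a class absent from both target and prediction score
a perfect 1 (so an all-background frame has zero loss); a class absent
from the target but present in the prediction scores ≈ 0, i.e. pure
false positives are fully penalised.  Two modes are exposed: hard
(argmax labels — used for reporting) and soft (probability mass — used
inside the training gradient, where argmax is not differentiable).

### Input normalization

Phase is a quantitative modality: the same cell produces the same
radian values regardless of what else is in the field of view.  Inputs
are therefore normalized by a **fixed affine map**,
(φ − 0.75)/0.75 rad, chosen once to centre the typical cellular phase
range.  Per-image z-scoring is available as an option
(`TrainConfig.normalization="zscore"`) for inputs of unknown scale,
but it is deliberately not the default: a frame's mean and standard
deviation change as cells die, so per-image statistics shift every
nucleus relative to the live/dead decision boundary.  In desk-scale
experiments this produced a systematic error mode — live nuclei in
low-variance (mostly-live) frames amplified into the brightness range
of dead nuclei and voted dead — which the fixed map eliminates.

### Schedule

Adam with β₁ = 0.9, β₂ = 0.999, ε = 1e-7; initial learning rate
5×10⁻⁴, multiplied by 0.8 whenever the validation loss (computed on the
whole validation partition at the end of every epoch) has not decreased
for 10 epochs; the weights with the lowest validation loss are kept.
Augmentation on the fly: random crop to the patch size, independent
horizontal/vertical flips (p = 0.5), integer shifts up to ±10% with
reflect padding (applied identically to labels, which therefore stay
exactly categorical), Gaussian noise at 1% of the image range and a
brightness offset within ±5% (image only).

The full-scale profile of the assay (512² patches, batch 14 with the
B3-like encoder or 4 with B7-like, 100 epochs) is configurable but not
exercised by the tests; the desk profile is the tiny encoder, 128²
patches, batch 8, ≤ 30 epochs, which trains in a few minutes on one
CPU and is the problem size used by the reference experiments.

### Data splitting

Datasets are split **by time-lapse sequence**, never by frame, in the
ratio 6:1:1 (train/validation/test) with largest-remainder rounding and
at least one sequence per partition, so frames from one recording can
never leak across partitions.

## Object-level evaluation

Pixel-wise scores under-weight biologically meaningful errors, so the
headline metric is object-based: each ground-truth nucleus (8-connected
component of non-background pixels, minimum area shared with the
ground-truth generator) is scored by the **dominant non-background
predicted class inside its own pixel set**.  If background covers more
than half of the object it is "missed" and tallied separately — the
2×2 live/dead confusion matrix contains only voted objects, and missed
counts are reported alongside.  Live/dead ties resolve to dead
(deterministic and conservative for viability).  The matrix is
normalised per ground-truth class (columns sum to 100%), which makes
the per-class recall equal to the diagonal.  Precision, recall and F1
are reported per class in percent with half-up rounding to one decimal,
plus their unweighted (macro) mean.  This ground-truth-anchored voting
needs no bipartite matching; how nuclei predicted entirely as
background should enter a published 2×2 table is ambiguous, hence the
explicit separate tally.

## Tracking and group statistics

Nuclei are linked across frames by greedy nearest-neighbour matching
on centroids: candidate pairs between consecutive frames are sorted by
ascending distance and accepted one-to-one while the displacement is
within `max_disp_px` (default 30 px — generous for adherent cells at
30–60 min intervals); unmatched objects open new tracks and tracks
shorter than `min_len` (default 5) are dropped.  The linker is
deterministic, needs no seed, and keeps one identity through a
live→dead transition (the class is recorded per timepoint).  No gap
closing or division detection is attempted.

Per timepoint, area = pixel count × pixel size² and dry mass is the
phase integral over the object mask.  Trajectories are normalised to
their value at t = 0 (so every series starts at exactly 1.0), and
groups are compared per timepoint by mean ± SEM and a **two-sided
Welch** t-test (the unequal-variance form; with equal group sizes its
statistic coincides with Student's t).  When both groups are exactly
degenerate at a timepoint — e.g. every normalised series is 1.0 at
t = 0 — the comparison is defined as t = 0, p = 1.

A power caveat documented deliberately: a true group shift of three
standard errors of the mean difference gives a noncentrality of 3, so
the two-sided test at α = 0.05 detects it in ≈ 85% of replicates — not
more.  The Monte-Carlo experiment in `experiments.welch_shift_detection`
measures exactly this (~0.82–0.85 observed).

## The synthetic time-lapse generator

`simulate.simulate_experiment` emulates the structure of the assay's
acquisitions: non-overlapping elliptical nuclei (semi-axes 7–11 px,
random orientation) with a smooth (1 − d²)^1.5 phase profile of peak
1.5 rad (±10% per cell) plus a fainter cytoplasm halo (1.8× axes, 15%
amplitude); a per-frame Bernoulli death hazard (geometric death frame,
frame 0 always observed live); necrotic morphology after death — area
swells to 1.3× over ~2 frames then shrinks to 0.7×, while the peak
phase steps up immediately and settles at 1.5× the live level
(chromatin condensation makes dead nuclei denser, hence brighter in
phase — this is the contrast the network learns); blue fluorescence on
every nucleus and green fluorescence ramping to the blue level within
`fluor_dead_ramp_frames` (default 1: the reagent equilibrates within
one 30–60 min frame interval; slower kinetics are configurable);
four-frame interferograms from the forward model with b = 0.3 and
Gaussian camera noise of σ = 0.5% of full scale (optional uint16
camera quantization).  Identical configs produce byte-identical
datasets, death is monotone, and the per-nucleus truth table records
death frame, footprint area and dry mass measured from the rendered
phase.

What the simulator does **not** model: diffraction and the SLIM halo
artifact, subcellular texture, apoptotic fragmentation, cell motility,
detachment/defocus, confluence, and edge-of-field truncation.  Passing
the bundled experiments therefore demonstrates that the pipeline's
machinery is correct and that the network can learn a genuine
phase-contrast viability signature end-to-end — it does not certify
accuracy on real microscope data, where those unmodelled effects are
the dominant error sources.

## Numerical choices

* Probability clip before logs: 1e-7.  Dice ε: 1e-6.  Reconstruction
  contrast floor: 1e-12 of the stack scale.
* BatchNorm momentum 0.99, eps 1e-5; batch statistics in training,
  running statistics at inference.
* He-normal initialisation seeded per run; Adam exactly as configured
  above; all randomness flows from explicit seeds (sub-seeds are
  derived linearly and kept below 2³¹).
* Ties: nucleus ratio at threshold → dead; object-vote tie → dead;
  split rounding by largest remainder with first-index preference.
* Inference pads to the model's downsampling divisor with reflection
  and crops back; images larger than the optional tile size are
  processed in half-overlapping tiles whose logits are averaged.
* Reference problem sizes: 20 sequences × 10 frames of 128² px for the
  learning experiment (split 15/3/2), 540 nuclei for ground-truth
  recovery, 100 random 64² maps for the optical round trip, 300
  Monte-Carlo replicates for the Welch power measurement.

## Known limitations

* The numpy implementation trains small models on small images; the
  B3/B7-like configurations exist for architectural fidelity and weight
  loading, not for full-scale training.
* Identity-mode reconstruction returns the interferometric phase
  difference; quantitative agreement with a b-corrected instrument
  requires the configurable b ratio.
* The ground-truth ratio rule and the simulator's death morphology are
  plausible stand-ins for unpublished procedures and real biophysics
  respectively; both are parameterised so they can be refit to data.
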