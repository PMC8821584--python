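# viaphase

Label-free live/dead viability assessment from quantitative phase
imaging (QPI).

Chemical viability assays stain cells to distinguish live from dead,
which takes time, biases the measurement and ultimately kills the
culture.  QPI measures the optical path-length delay φ(x) through an
unlabeled specimen — a quantity that is both morphologically rich and
directly proportional to the cell's dry mass — so a segmentation model
trained once against fluorescence-derived labels can afterwards read
viability from the label-free phase image alone.  `viaphase`
implements that pipeline end to end:

1. **Phase reconstruction** (`viaphase.optics`) — from four
   phase-shifted interferograms I_k = I₀(1 + b² + 2b cos(φ + θ_k)),
   θ_k ∈ {0, π/2, π, 3π/2}, via Δφ = atan2(I₃ − I₁, I₀ − I₂), with an
   optional b-ratio phase composition, block-mean downsampling and the
   dry-mass integral m = λ/(2πα) Σ φ · px².
2. **Ground truth** (`viaphase.ground_truth`) — nuclei segmented on
   the "live" fluorescence channel (Otsu + connected components), each
   called dead when mean(green)/mean(blue) ≥ 0.5, giving per-pixel
   classes {0 live, 1 dead, 2 background}.
3. **Segmentation network** (`viaphase.net`) — U-Net-style
   encoder–decoders (a tiny desk profile and EfficientNet-like MBConv
   encoders b0–b7) trained with the combined loss
   L = α·L_focal + β·L_dice, where the focal term uses
   [1 − yᵀp]^γ · yᵀlog₂ p with γ = 2 and the dice term averages
   per-class overlap over the batch; Adam (β₁ 0.9, β₂ 0.999, ε 1e-7),
   lr 5×10⁻⁴ with ×0.8 plateau decay, sequence-level 6:1:1 splits and
   on-the-fly augmentation.  Implemented in pure numpy with
   hand-written, gradient-checked backpropagation.
4. **Object-level evaluation** (`viaphase.evaluate`) — each
   ground-truth nucleus is scored by the dominant predicted class in
   its own footprint; the 2×2 live/dead confusion is normalised per
   ground-truth class and summarised as per-class precision/recall/F1
   and macro-F1.
5. **Tracking** (`viaphase.tracking`) — deterministic greedy
   nearest-neighbour linking, per-timepoint relative area and dry-mass
   series (normalised to t = 0) and two-sided Welch comparisons
   between cell groups.
6. **Simulator** (`viaphase.simulate`) — a seeded synthetic time-lapse
   generator (elliptical nuclei, Bernoulli death hazard,
   swell-then-shrink death morphology, dual-channel fluorescence,
   interferograms from the forward model) that provides exact
   per-nucleus truth for every test in the suite.

See `docs/methods.md` for the model details, defaults and limitations.

## Worked example

The `viaphase` CLI chains all stages on a simulated experiment:

```bash
viaphase run-all --config pipeline.json --seed 1 --out demo/
```

with `pipeline.json` selecting the desk profile (20 simulated
sequences of ten 128×128 frames, tiny encoder, 30 epochs):

```json
{
  "sim": {"image_px": 128, "n_cells": 6, "n_frames": 10},
  "training": {"epochs": 30, "patch_px": 128, "batch_size": 8},
  "n_sequences": 20
}
```

It prints (about eight minutes on one CPU):

```
{"macro_f1": 98.67710285525301, "best_epoch": 30, "n_tracks": 6, "report": "demo/report.json"}
```

meaning: the segmenter trained on the 15 training sequences reached its
lowest validation loss at epoch 30, its object-level macro-F1 on the
held-out test sequences is 98.7% (the report shows the underlying 2×2
confusion: 96/96 live nuclei and 23/24 dead nuclei voted correctly,
none missed — per-class F1 99.5% live / 97.9% dead), and 6 nuclei were
tracked through the predicted test maps.  `demo/` contains
the training history (`history.csv`), network weights
(`weights.npz`), per-frame predicted label maps, the track table
(`tracks.csv`) and a JSON report with the full confusion matrix and
per-class scores.

The same stages are available individually (`simulate`,
`reconstruct`, `make-gt`, `split`, `train`, `predict`, `evaluate`,
`track`), and everything is importable as a library:

```python
from viaphase.optics import reconstruct_phase, compute_dry_mass
from viaphase.simulate import SimConfig, simulate_experiment

exp = simulate_experiment(SimConfig(seed=1))
pm = reconstruct_phase(exp.stacks[0])          # identity-mode phase map
```

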