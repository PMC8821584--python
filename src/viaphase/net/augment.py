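"""On-the-fly training augmentation.

Geometric transforms (crop, flips, integer shift with reflect padding)
are applied identically to image and label map; labels move by integer
offsets only, so nearest-neighbour resampling is exact and label values
stay in {0, 1, 2}.  Photometric perturbations (Gaussian noise at 1% of
the image range, brightness offset within +-5%) touch the image only.
"""

from __future__ import annotations

import numpy as np


def augment_patch(image: np.ndarray, label_map: np.ndarray, cfg,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Crop to ``cfg.patch_px`` and apply the enabled augmentations.

    With all augmentations disabled this reduces to a centre crop.
    """
    image = np.asarray(image, dtype=np.float64)
    label_map = np.asarray(label_map)
    if image.shape != label_map.shape:
        raise ValueError("image and label map shapes differ")
    h, w = image.shape
    p = cfg.patch_px
    if p > h or p > w:
        raise ValueError(f"patch {p} larger than image {h}x{w}")
    augs = set(cfg.augmentations)

    if "crop" in augs:
        r0 = int(rng.integers(0, h - p + 1))
        c0 = int(rng.integers(0, w - p + 1))
    else:
        r0, c0 = (h - p) // 2, (w - p) // 2
    img = image[r0:r0 + p, c0:c0 + p].copy()
    lab = label_map[r0:r0 + p, c0:c0 + p].copy()

    if "flip" in augs:
        if rng.random() < 0.5:
            img, lab = img[::-1], lab[::-1]
        if rng.random() < 0.5:
            img, lab = img[:, ::-1], lab[:, ::-1]

    if "shift" in augs:
        max_shift = max(1, int(0.1 * p))
        dr = int(rng.integers(-max_shift, max_shift + 1))
        dc = int(rng.integers(-max_shift, max_shift + 1))
        img = _shift_reflect(img, dr, dc)
        lab = _shift_reflect(lab, dr, dc)

    rng_range = float(np.ptp(img)) or 1.0
    if "noise" in augs:
        img = img + rng.normal(0.0, 0.01 * rng_range, img.shape)
    if "brightness" in augs:
        img = img + rng.uniform(-0.05, 0.05) * rng_range

    return np.ascontiguousarray(img), np.ascontiguousarray(lab)


def _shift_reflect(arr: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Integer shift with reflect padding (exact for label maps)."""
    if dr == 0 and dc == 0:
        return arr
    pr, pc = abs(dr), abs(dc)
    padded = np.pad(arr, ((pr, pr), (pc, pc)), mode="reflect") if (pr or pc) else arr
    h, w = arr.shape
    return padded[pr - dr:pr - dr + h, pc - dc:pc - dc + w]
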