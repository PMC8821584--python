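"""Fluorescence-derived semantic ground truth for live/dead segmentation.

A dual-reagent viability stain produces two co-registered channels: a
"live" channel (NucBlue-like, stains every nucleus) and a "dead" channel
(NucGreen-like, stains only nuclei with compromised membranes).  Nuclei
are segmented on the blue channel, and each nucleus is called dead when
the mean green-to-blue intensity ratio over its pixels exceeds a
threshold.  The result is a three-class per-pixel map with the encoding
0 = live nucleus, 1 = dead nucleus, 2 = background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure, segmentation

LIVE, DEAD, BACKGROUND = 0, 1, 2

#: guards the ratio denominator on (theoretically) zero-blue nuclei
_RATIO_EPS = 1e-9


class SegmentationError(RuntimeError):
    """Raised when a fluorescence channel yields no usable foreground."""


@dataclass
class FluorescencePair:
    """Co-registered live (blue) and dead (green) fluorescence channels."""

    blue: np.ndarray
    green: np.ndarray

    def __post_init__(self) -> None:
        self.blue = np.asarray(self.blue, dtype=np.float64)
        self.green = np.asarray(self.green, dtype=np.float64)
        if self.blue.ndim != 2 or self.blue.shape != self.green.shape:
            raise ValueError("blue and green must be 2-D arrays of identical shape")
        if np.any(self.blue < 0) or np.any(self.green < 0):
            raise ValueError("fluorescence intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.blue.shape


@dataclass
class SemanticMap:
    """Per-pixel class map, values in {0 live, 1 dead, 2 background}."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("SemanticMap.labels must be 2-D")
        vals = np.unique(self.labels)
        if not np.isin(vals, (LIVE, DEAD, BACKGROUND)).all():
            raise ValueError(f"labels must be in {{0,1,2}}, got values {vals}")
        self.labels = self.labels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


@dataclass(frozen=True)
class GtConfig:
    """Knobs of the ground-truth generator.

    smoothing_sigma_px : Gaussian presmoothing of the blue channel.
    min_area_px        : nuclei smaller than this are dropped.
    ratio_threshold    : mean(green)/mean(blue) above which (or equal to
                         which; ties are dead) a nucleus is called dead.
    edge_policy        : "keep" or "drop" objects touching the border.
    """

    smoothing_sigma_px: float = 2.0
    min_area_px: int = 50
    ratio_threshold: float = 0.5
    edge_policy: str = "keep"

    def __post_init__(self) -> None:
        if self.smoothing_sigma_px < 0:
            raise ValueError("smoothing_sigma_px must be >= 0")
        if self.min_area_px < 1:
            raise ValueError("min_area_px must be >= 1")
        if self.ratio_threshold <= 0:
            raise ValueError("ratio_threshold must be > 0")
        if self.edge_policy not in ("keep", "drop"):
            raise ValueError("edge_policy must be 'keep' or 'drop'")


def segment_nuclei(blue: np.ndarray, cfg: GtConfig = GtConfig()) -> np.ndarray:
    """Segment nuclei on the live channel.

    Gaussian smooth, global Otsu threshold, 8-connected components,
    minimum-area filter, optional removal of border-touching objects.
    Returns an integer label image (0 = background, 1..K = nuclei with
    consecutive ids).
    """
    blue = np.asarray(blue, dtype=np.float64)
    if blue.ndim != 2:
        raise ValueError("blue must be 2-D")
    if np.ptp(blue) == 0:
        raise SegmentationError("no foreground: channel is constant")
    smooth = filters.gaussian(blue, sigma=cfg.smoothing_sigma_px, preserve_range=True) \
        if cfg.smoothing_sigma_px > 0 else blue
    thr = filters.threshold_otsu(smooth)
    fg = smooth > thr
    if not fg.any():
        raise SegmentationError("no foreground above the Otsu threshold")
    lab = measure.label(fg, connectivity=2)
    if cfg.edge_policy == "drop":
        lab = segmentation.clear_border(lab)
    # drop small components, relabel consecutively
    ids, counts = np.unique(lab[lab > 0], return_counts=True)
    keep = ids[counts >= cfg.min_area_px]
    out = np.zeros_like(lab)
    for new_id, old_id in enumerate(keep, start=1):
        out[lab == old_id] = new_id
    return out


def classify_nuclei(nuclei: np.ndarray, pair: FluorescencePair,
                    cfg: GtConfig = GtConfig()) -> SemanticMap:
    """Assign live/dead to every nucleus from the green/blue ratio.

    Per nucleus n: r(n) = mean(green | n) / (mean(blue | n) + eps); the
    nucleus is dead iff r(n) >= ratio_threshold (ties -> dead).  All
    non-nucleus pixels are background.  The ratio of per-nucleus means is
    invariant to a common positive gain on both channels.
    """
    nuclei = np.asarray(nuclei)
    if nuclei.shape != pair.shape:
        raise ValueError("nuclei label map and fluorescence pair shapes differ")
    labels = np.full(nuclei.shape, BACKGROUND, dtype=np.uint8)
    ids = np.unique(nuclei[nuclei > 0])
    if ids.size == 0:
        return SemanticMap(labels)
    mean_green = ndimage.mean(pair.green, labels=nuclei, index=ids)
    mean_blue = ndimage.mean(pair.blue, labels=nuclei, index=ids)
    for nid, g, b in zip(ids, np.atleast_1d(mean_green), np.atleast_1d(mean_blue)):
        sel = nuclei == nid
        if not sel.any():  # pragma: no cover - ids come from the map itself
            raise RuntimeError(f"nucleus id {nid} has no pixels")
        r = g / (b + _RATIO_EPS)
        labels[sel] = DEAD if r >= cfg.ratio_threshold else LIVE
    return SemanticMap(labels)


def make_semantic_map(pair: FluorescencePair, cfg: GtConfig = GtConfig()) -> SemanticMap:
    """Full ground-truth generation: segment on blue, classify by ratio."""
    try:
        nuclei = segment_nuclei(pair.blue, cfg)
    except SegmentationError:
        # an empty scene is a legal all-background map
        return SemanticMap(np.full(pair.shape, BACKGROUND, dtype=np.uint8))
    return classify_nuclei(nuclei, pair, cfg)


def nucleus_table(pair: FluorescencePair, cfg: GtConfig = GtConfig()) -> pd.DataFrame:
    """Per-nucleus summary (id, centroid, area, green/blue ratio, class)."""
    try:
        nuclei = segment_nuclei(pair.blue, cfg)
    except SegmentationError:
        nuclei = np.zeros(pair.shape, dtype=int)
    rows = []
    for nid in np.unique(nuclei[nuclei > 0]):
        sel = nuclei == nid
        rr, cc = np.nonzero(sel)
        g, b = pair.green[sel].mean(), pair.blue[sel].mean()
        r = g / (b + _RATIO_EPS)
        rows.append({
            "id": int(nid),
            "centroid_row": float(rr.mean()),
            "centroid_col": float(cc.mean()),
            "area_px": int(sel.sum()),
            "ratio": float(r),
            "class": "dead" if r >= cfg.ratio_threshold else "live",
        })
    return pd.DataFrame(rows, columns=["id", "centroid_row", "centroid_col",
                                       "area_px", "ratio", "class"])
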