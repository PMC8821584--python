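"""Object-level and pixel-wise evaluation of viability segmentations.

The headline metric is object-based: each ground-truth nucleus (an
8-connected component of non-background pixels) is scored by the
dominant non-background predicted class inside its own pixel set.  A
nucleus whose footprint is predicted mostly background is "missed" and
tallied separately, outside the 2x2 live/dead confusion matrix.  The
confusion matrix is normalised per ground-truth class (columns sum to
100%), so the per-class recall equals the matrix diagonal.  Live/dead
ties inside an object resolve to dead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

import numpy as np
from skimage import measure

from .ground_truth import BACKGROUND, DEAD, LIVE, SemanticMap

MISSED = "missed"


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal round-half-up (table formatting; numpy rounds half-even)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class NucleusRecord:
    """One segmented nucleus extracted from a semantic map."""

    id: int
    pixels: np.ndarray          # (n, 2) array of (row, col) indices
    centroid: tuple[float, float]
    area_px: int
    cls: int                    # LIVE or DEAD
    dry_mass_pg: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.pixels) == 0:
            raise ValueError("nucleus must have a non-empty pixel set")
        if self.cls not in (LIVE, DEAD):
            raise ValueError("nucleus class must be live or dead")

    def mask(self, shape) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.pixels[:, 0], self.pixels[:, 1]] = True
        return m


@dataclass
class ViabilityConfusion:
    """2x2 object counts, counts[gt][pred] with 0=live, 1=dead.

    Missed objects (predicted mostly background) are tallied separately
    and excluded from the matrix.
    """

    counts: np.ndarray
    missed: np.ndarray = field(default_factory=lambda: np.zeros(2, dtype=int))

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        self.missed = np.asarray(self.missed, dtype=int)
        if self.counts.shape != (2, 2) or np.any(self.counts < 0):
            raise ValueError("counts must be a non-negative 2x2 matrix")

    @property
    def n_live(self) -> int:
        return int(self.counts[LIVE].sum())

    @property
    def n_dead(self) -> int:
        return int(self.counts[DEAD].sum())

    def __add__(self, other: "ViabilityConfusion") -> "ViabilityConfusion":
        return ViabilityConfusion(self.counts + other.counts,
                                  self.missed + other.missed)


@dataclass
class PRF1Report:
    """Per-class precision/recall/F1 in percent, plus their macro mean."""

    precision: dict
    recall: dict
    f1: dict
    macro_f1: float
    flags: list = field(default_factory=list)


def extract_objects(sem: SemanticMap, min_area_px: int = 50) -> list[NucleusRecord]:
    """Connected components of the non-background mask, majority class."""
    lab = measure.label(sem.labels != BACKGROUND, connectivity=2)
    records = []
    for nid in range(1, lab.max() + 1):
        sel = lab == nid
        area = int(sel.sum())
        if area < min_area_px:
            continue
        rr, cc = np.nonzero(sel)
        vals = sem.labels[sel]
        n_dead = int((vals == DEAD).sum())
        n_live = int((vals == LIVE).sum())
        cls = DEAD if n_dead >= n_live else LIVE
        records.append(NucleusRecord(
            id=len(records) + 1,
            pixels=np.column_stack([rr, cc]),
            centroid=(float(rr.mean()), float(cc.mean())),
            area_px=area,
            cls=cls,
        ))
    return records


def dominant_label(gt_obj: NucleusRecord, pred: SemanticMap):
    """Majority predicted class inside the ground-truth object's pixels.

    Returns LIVE, DEAD or ``"missed"`` (background strictly dominates,
    i.e. covers more than half of the object's pixels).  Live/dead ties
    resolve to DEAD.
    """
    vals = pred.labels[gt_obj.pixels[:, 0], gt_obj.pixels[:, 1]]
    n_bg = int((vals == BACKGROUND).sum())
    n_live = int((vals == LIVE).sum())
    n_dead = int((vals == DEAD).sum())
    if n_bg > (len(vals) - n_bg):
        return MISSED
    return DEAD if n_dead >= n_live else LIVE


def object_confusion(gt: SemanticMap, pred: SemanticMap,
                     min_area_px: int = 50) -> ViabilityConfusion:
    """Vote every ground-truth object and tally the 2x2 live/dead matrix."""
    if gt.shape != pred.shape:
        raise ValueError("ground truth and prediction shapes differ")
    counts = np.zeros((2, 2), dtype=int)
    missed = np.zeros(2, dtype=int)
    for obj in extract_objects(gt, min_area_px):
        vote = dominant_label(obj, pred)
        if vote == MISSED:
            missed[obj.cls] += 1
        else:
            counts[obj.cls, vote] += 1
    return ViabilityConfusion(counts, missed)


def normalize_confusion(cm: ViabilityConfusion) -> np.ndarray:
    """Percentages per ground-truth class; each class's entries sum to 100.

    Returned in the printed-table orientation: rows = prediction,
    columns = ground truth.  A class with zero ground-truth objects
    yields NaN in its column.
    """
    totals = cm.counts.sum(axis=1).astype(float)  # per gt class
    out = np.full((2, 2), np.nan)
    for g in (LIVE, DEAD):
        if totals[g] > 0:
            out[:, g] = 100.0 * cm.counts[g] / totals[g]
    return out


def prf1(cm: ViabilityConfusion) -> PRF1Report:
    """Precision/recall/F1 per class (percent) and their macro average."""
    names = {LIVE: "live", DEAD: "dead"}
    precision, recall, f1, flags = {}, {}, {}, []
    for c in (LIVE, DEAD):
        tp = cm.counts[c, c]
        fp = cm.counts[1 - c, c]   # other gt class predicted as c
        fn = cm.counts[c, 1 - c]
        p = 100.0 * tp / (tp + fp) if (tp + fp) > 0 else _flag(flags, f"precision[{names[c]}]")
        r = 100.0 * tp / (tp + fn) if (tp + fn) > 0 else _flag(flags, f"recall[{names[c]}]")
        precision[names[c]] = p
        recall[names[c]] = r
        f1[names[c]] = 2 * p * r / (p + r) if (p + r) > 0 else _flag(flags, f"f1[{names[c]}]")
    macro = float(np.mean([f1["live"], f1["dead"]]))
    return PRF1Report(precision=precision, recall=recall, f1=f1,
                      macro_f1=macro, flags=flags)


def _flag(flags: list, name: str) -> float:
    flags.append(f"zero denominator in {name}; value set to 0")
    return 0.0


def f1_from_pr(precision_pct: float, recall_pct: float) -> float:
    """Harmonic mean of precision and recall, both in percent."""
    for v in (precision_pct, recall_pct):
        if not (0.0 <= v <= 100.0):
            raise ValueError("precision/recall must be in [0, 100]")
    if precision_pct == 0.0 and recall_pct == 0.0:
        raise ValueError("precision and recall cannot both be 0")
    return 2.0 * precision_pct * recall_pct / (precision_pct + recall_pct)


def pixel_metrics(gt: SemanticMap, pred: SemanticMap) -> dict:
    """Standard per-class pixel precision/recall/F1/IoU over all 3 classes."""
    if gt.shape != pred.shape:
        raise ValueError("ground truth and prediction shapes differ")
    names = {LIVE: "live", DEAD: "dead", BACKGROUND: "background"}
    out = {}
    for c, name in names.items():
        tp = float(((pred.labels == c) & (gt.labels == c)).sum())
        fp = float(((pred.labels == c) & (gt.labels != c)).sum())
        fn = float(((pred.labels != c) & (gt.labels == c)).sum())
        p = 100.0 * tp / (tp + fp) if tp + fp else 0.0
        r = 100.0 * tp / (tp + fn) if tp + fn else 0.0
        f = 2 * p * r / (p + r) if p + r else 0.0
        iou = 100.0 * tp / (tp + fp + fn) if tp + fp + fn else 0.0
        out[name] = {"precision": p, "recall": r, "f1": f, "iou": iou}
    return out
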