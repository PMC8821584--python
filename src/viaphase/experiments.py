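"""Reference desk-scale experiments.

These routines bundle the package's end-to-end checks into seeded,
self-contained computations: the published-table F1 arithmetic, the
interferometric round trip, ground-truth recovery on noise-free scenes,
a scaled-down training run with object-level scoring, the simulator's
death-hazard statistics, and the power of the Welch comparison on
synthetic track groups.  They are used by the test suite and by
``scripts/acceptance.py``.

Problem sizes are chosen for a single CPU: 128 x 128 frames, the tiny
encoder and at most 30 epochs for the learning experiment; everything
else runs in seconds.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .evaluate import (ViabilityConfusion, f1_from_pr, normalize_confusion,
                       object_confusion, prf1, round_half_up)
from .ground_truth import make_semantic_map
from .net import TrainConfig, build_model, predict, split_sequences, train
from .optics import OpticsConfig, PhaseMap, reconstruct_phase
from .simulate import (SimConfig, forward_slim, simulate_experiment,
                       truth_match_fraction)
from .tracking import Track, TrackPoint, group_stats


def _subseed(seed: int, k: int) -> int:
    return int((seed * 10007 + k) % 2**31)


# -- published-table arithmetic ---------------------------------------------

#: object-level precision/recall (percent) reported for the full-scale
#: assay: HeLa (necrosis, focal loss) and CHO (apoptosis, focal+dice).
TABLE_PR = {
    "hela": {"live": (99.6, 98.8), "dead": (91.2, 97.6)},
    "cho": {"live": (94.6, 90.1), "dead": (96.8, 98.3)},
}


def table_f1_arithmetic() -> dict[str, float]:
    """F1 and macro-F1 recomputed from the reported precision/recall,
    rounded half-up to one decimal as in the published tables."""
    out = {}
    for line, classes in TABLE_PR.items():
        f1s = {cls: f1_from_pr(*pr) for cls, pr in classes.items()}
        for cls, v in f1s.items():
            out[f"f1_{cls}_{line}"] = round_half_up(v, 1)
        out[f"macro_f1_{line}"] = round_half_up(float(np.mean(list(f1s.values()))), 1)
    return out


# -- optics -----------------------------------------------------------------


def phase_roundtrip_error(seed: int, n_maps: int = 100, size: int = 64) -> float:
    """Max |reconstructed - true| phase over seeded random smooth maps."""
    worst = 0.0
    cfg = OpticsConfig()
    for k in range(n_maps):
        rng = np.random.default_rng(_subseed(seed, k))
        phi = ndimage.gaussian_filter(rng.normal(size=(size, size)), 4.0)
        phi -= phi.min()
        if phi.max() > 0:
            phi *= 1.5 / phi.max()
        b = float(rng.uniform(0.05, 1.0))
        rec = reconstruct_phase(forward_slim(PhaseMap(phi), b), cfg)
        worst = max(worst, float(np.abs(rec.phase - phi).max()))
    return worst


# -- ground truth -----------------------------------------------------------


def ground_truth_recovery(seed: int, n_scenes: int = 6, n_cells: int = 18,
                          n_frames: int = 5) -> tuple[float, int]:
    """Fraction of nuclei whose fluorescence-derived label matches the
    simulator truth on noise-free scenes; returns (fraction, n_nuclei)."""
    total_n, weighted = 0, 0.0
    for k in range(n_scenes):
        cfg = SimConfig(image_px=256, n_cells=n_cells, n_frames=n_frames,
                        death_hazard_per_frame=0.12, noise_sigma=0.0,
                        seed=_subseed(seed, k))
        exp = simulate_experiment(cfg)
        maps = [make_semantic_map(fp) for fp in exp.fluorescence]
        frac = truth_match_fraction(exp, maps)
        n = len(exp.truth.nuclei)
        total_n += n
        weighted += frac * n
    return weighted / total_n, total_n


# -- scaled-down learning ---------------------------------------------------


def desk_learning_experiment(seed: int, n_sequences: int = 20,
                             frames_per_seq: int = 10, image_px: int = 128,
                             epochs: int = 30) -> dict:
    """Train the tiny segmenter on simulated sequences and score it
    object-wise on the held-out test sequences.

    200 frames at the default sizes (20 sequences x 10 frames of
    128 x 128 px), split 6:1:1 by sequence.  Returns the training result,
    the pooled test confusion and the macro F1 (percent).
    """
    optics = OpticsConfig(pixel_size_um=0.325)
    dataset, recon, gt_maps = {}, {}, {}
    for i in range(n_sequences):
        cfg = SimConfig(image_px=image_px, n_cells=6, n_frames=frames_per_seq,
                        seed=_subseed(seed, i))
        exp = simulate_experiment(cfg)
        sid = f"seq{i:02d}"
        recon[sid] = [reconstruct_phase(st, optics) for st in exp.stacks]
        gt_maps[sid] = [make_semantic_map(fp) for fp in exp.fluorescence]
        dataset[sid] = [(recon[sid][f].phase, gt_maps[sid][f].labels)
                        for f in range(frames_per_seq)]

    split = split_sequences(sorted(dataset), seed=seed)
    train_cfg = TrainConfig(epochs=epochs, seed=seed, patch_px=image_px,
                            batch_size=8, encoder_name="tiny")
    model = build_model(train_cfg)
    result = train(model, dataset, split, train_cfg)

    total = ViabilityConfusion(np.zeros((2, 2), dtype=int))
    n_frames_test = 0
    for sid in split.test:
        for pm, gt in zip(recon[sid], gt_maps[sid]):
            _, pred = predict(model, pm)
            total = total + object_confusion(gt, pred)
            n_frames_test += 1
    report = prf1(total)
    return {
        "result": result,
        "split": split,
        "confusion": total,
        "normalized_pct": normalize_confusion(total),
        "prf1": report,
        "macro_f1_pct": report.macro_f1,
        "n_test_frames": n_frames_test,
        "n_train_frames": sum(len(dataset[s]) for s in split.train),
        "model": model,
    }


# -- simulator statistics ---------------------------------------------------


def simulator_dead_fraction(seed: int, hazard: float = 0.1, n_cells: int = 100,
                            n_trials: int = 10) -> dict:
    """Observed dead fraction after ``n_trials`` per-frame hazard draws
    versus the binomial expectation 1 - (1 - h)^n."""
    cfg = SimConfig(image_px=512, n_cells=n_cells, n_frames=n_trials + 1,
                    death_hazard_per_frame=hazard, seed=_subseed(seed, 0))
    exp = simulate_experiment(cfg)
    last = exp.truth.nuclei.query("frame == @cfg.n_frames - 1")
    observed = float((last["cls"] == 1).mean())
    expected = 1.0 - (1.0 - hazard) ** n_trials
    sd = float(np.sqrt(expected * (1.0 - expected) / n_cells))
    return {"observed": observed, "expected": expected, "binomial_sd": sd,
            "n_cells": n_cells}


# -- tracking statistics ----------------------------------------------------


def _value_track(v1: float) -> Track:
    from .evaluate import NucleusRecord
    rec = NucleusRecord(1, np.array([[0, 0]]), (0.0, 0.0), 1, 0)
    pts = [TrackPoint(0, rec, area_um2=1.0, dry_mass_pg=1.0),
           TrackPoint(1, NucleusRecord(1, np.array([[0, 0]]), (0.0, 0.0), 1, 0),
                      area_um2=float(v1), dry_mass_pg=float(v1))]
    return Track(0, pts)


def welch_shift_detection(seed: int, n_replicates: int = 300,
                          n_per_group: int = 25, sigma: float = 0.05) -> dict:
    """Monte-Carlo power of the per-timepoint Welch comparison.

    Each replicate draws two groups of normalised track values; group B
    is shifted by three standard errors of the mean difference,
    delta = 3 * sigma * sqrt(2 / n).  Returns the fraction of replicates
    with p < 0.05 at the shifted timepoint, and the identical-group
    p-value as a sanity check.
    """
    delta = 3.0 * sigma * np.sqrt(2.0 / n_per_group)
    hits = 0
    for k in range(n_replicates):
        rng = np.random.default_rng(_subseed(seed, 7000 + k))
        a = [_value_track(1.0 + rng.normal(0, sigma)) for _ in range(n_per_group)]
        b = [_value_track(1.0 + delta + rng.normal(0, sigma))
             for _ in range(n_per_group)]
        gs = group_stats(a, b, "area")
        if gs.loc[1, "welch_p"] < 0.05:
            hits += 1
    # identical groups
    rng = np.random.default_rng(_subseed(seed, 6999))
    vals = [1.0 + rng.normal(0, sigma) for _ in range(n_per_group)]
    same = group_stats([_value_track(v) for v in vals],
                       [_value_track(v) for v in vals], "area")
    return {"detection_rate": hits / n_replicates,
            "n_replicates": n_replicates,
            "shift": delta,
            "identical_p": float(same["welch_p"].iloc[1]),
            "identical_p_t0": float(same["welch_p"].iloc[0])}
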