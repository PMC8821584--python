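"""End-to-end orchestration: simulate -> reconstruct -> ground truth ->
split -> train -> predict -> evaluate -> track.

The pipeline mirrors the experimental workflow of the assay: phase maps
are reconstructed from the four-frame interferograms, the semantic
ground truth is derived from the fluorescence channels (not from the
simulator's hidden truth), the segmenter is trained on the training
sequences and scored object-wise on the held-out test sequences, and
nuclei are tracked on the predicted maps.  Every stochastic stage is
seeded from the single pipeline seed, so a rerun with the same config
reproduces the report exactly.
"""

from __future__ import annotations

import dataclasses
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io
from .evaluate import ViabilityConfusion, normalize_confusion, object_confusion, prf1
from .ground_truth import GtConfig, make_semantic_map
from .net import TrainConfig, build_model, predict, split_sequences, train
from .optics import OpticsConfig, reconstruct_phase
from .simulate import SimConfig, simulate_experiment, write_experiment
from .tracking import group_stats, link_tracks, measure_track, tracks_table


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    gt: GtConfig = field(default_factory=GtConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    optics: OpticsConfig = field(default_factory=OpticsConfig)
    n_sequences: int = 6
    max_disp_px: float = 30.0
    min_track_len: int = 5
    min_area_px: int = 50
    seed: int = 0
    write_dataset: bool = False

    def sequence_seed(self, i: int) -> int:
        return int((self.seed * 9973 + i) % 2**31)


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Execute all stages and write intermediates + a JSON report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed, "stages": [], "seeds": {}}
    t0 = time.time()

    def stage(name):
        report["stages"].append(name)

    # -- simulate ---------------------------------------------------------
    stage("simulate")
    try:
        experiments = {}
        for i in range(cfg.n_sequences):
            seq_seed = cfg.sequence_seed(i)
            sim_cfg = dataclasses.replace(cfg.sim, seed=seq_seed)
            exp = simulate_experiment(sim_cfg)
            sid = f"seq{i:02d}"
            experiments[sid] = exp
            report["seeds"][sid] = seq_seed
            if cfg.write_dataset:
                write_experiment(exp, outdir / "dataset" / sid)
    except Exception as exc:
        raise PipelineStageError("simulate", exc)

    # -- reconstruct + ground truth --------------------------------------
    stage("reconstruct")
    try:
        optics = dataclasses.replace(cfg.optics,
                                     pixel_size_um=cfg.sim.pixel_size_um,
                                     wavelength_um=cfg.sim.wavelength_um)
        recon = {sid: [reconstruct_phase(st, optics) for st in exp.stacks]
                 for sid, exp in experiments.items()}
    except Exception as exc:
        raise PipelineStageError("reconstruct", exc)

    stage("make-gt")
    try:
        gt_maps = {sid: [make_semantic_map(fp, cfg.gt) for fp in exp.fluorescence]
                   for sid, exp in experiments.items()}
    except Exception as exc:
        raise PipelineStageError("make-gt", exc)

    # -- split + train ----------------------------------------------------
    stage("split")
    try:
        split = split_sequences(sorted(experiments), seed=cfg.seed)
        report["split"] = {"train": list(split.train),
                           "validation": list(split.validation),
                           "test": list(split.test)}
    except Exception as exc:
        raise PipelineStageError("split", exc)

    stage("train")
    try:
        dataset = {sid: [(recon[sid][f].phase, gt_maps[sid][f].labels)
                         for f in range(len(recon[sid]))]
                   for sid in experiments}
        train_cfg = dataclasses.replace(cfg.training, seed=cfg.seed)
        model = build_model(train_cfg)
        result = train(model, dataset, split, train_cfg)
        result.history.to_csv(outdir / "history.csv", index=False)
        model.save(outdir / "weights.npz")
        report["training"] = {
            "encoder": train_cfg.encoder_name,
            "epochs": int(len(result.history)),
            "best_epoch": int(result.best_epoch),
            "best_val_loss": float(result.best_val_loss),
            "final_train_loss": float(result.history["train_loss"].iloc[-1]),
        }
    except Exception as exc:
        raise PipelineStageError("train", exc)

    # -- predict + evaluate ----------------------------------------------
    stage("predict")
    try:
        predictions = {}
        for sid in split.test:
            predictions[sid] = [predict(model, pm)[1] for pm in recon[sid]]
            for f, sem in enumerate(predictions[sid]):
                io.write_label_map(sem, outdir / f"pred_{sid}_{f:03d}.tif")
    except Exception as exc:
        raise PipelineStageError("predict", exc)

    stage("evaluate")
    try:
        total = ViabilityConfusion(np.zeros((2, 2), dtype=int))
        for sid in split.test:
            for gt_map, pred_map in zip(gt_maps[sid], predictions[sid]):
                total = total + object_confusion(gt_map, pred_map, cfg.min_area_px)
        rep = prf1(total)
        report["evaluation"] = {
            "confusion_counts": total.counts.tolist(),
            "missed": total.missed.tolist(),
            "normalized_pct": normalize_confusion(total).tolist(),
            "precision_pct": rep.precision,
            "recall_pct": rep.recall,
            "f1_pct": rep.f1,
            "macro_f1": rep.macro_f1,
        }
    except Exception as exc:
        raise PipelineStageError("evaluate", exc)

    # -- track ------------------------------------------------------------
    stage("track")
    try:
        sid = split.test[0]
        tracks = link_tracks(predictions[sid], cfg.max_disp_px,
                             cfg.min_track_len, cfg.min_area_px)
        for tr in tracks:
            measure_track(tr, recon[sid], predictions[sid], optics)
        table = tracks_table(tracks, cfg.sim.frame_interval_min)
        io.write_tracks_csv(table, outdir / "tracks.csv")
        report["tracking"] = {"sequence": sid, "n_tracks": len(tracks)}
        dying = [t for t in tracks if any(p.nucleus.cls == 1 for p in t.points)]
        surviving = [t for t in tracks if all(p.nucleus.cls == 0 for p in t.points)]
        if len(dying) >= 2 and len(surviving) >= 2:
            gs = group_stats(dying, surviving, "area")
            io.write_tracks_csv(gs, outdir / "group_stats.csv")
            report["tracking"]["area_welch_p"] = gs["welch_p"].tolist()
    except Exception as exc:
        raise PipelineStageError("track", exc)

    report["runtime_s"] = round(time.time() - t0, 2)
    io.write_report_json(report, outdir / "report.json")
    return report
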