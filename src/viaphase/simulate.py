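"""Seeded synthetic time-lapse generator for the viability pipeline.

Emulates the structure of a dual-modality live/dead imaging experiment:
adherent cells rendered as smooth elliptical nuclei (plus a fainter
cytoplasm) in a quantitative phase map, imaged through the four-step
interferometric forward model, together with two co-registered
fluorescence channels (a "live" stain covering every nucleus and a
"dead" stain ramping up after membrane compromise) and exact per-nucleus
viability truth.

Cell death follows a per-frame Bernoulli hazard.  After death a nucleus
swells to ``swell_factor`` of its area over a couple of frames and then
shrinks to ``shrink_factor`` (necrotic swelling followed by collapse),
while its peak phase rises towards ``dead_brightness`` times the live
level - chromatin condensation increases the local dry-mass density, so
dead nuclei appear brighter in phase.  The dead-channel fluorescence
ramps from zero to the live-channel level over
``fluor_dead_ramp_frames`` frames.

Everything is driven by a single seed: equal configs produce
byte-identical datasets.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from .ground_truth import BACKGROUND, DEAD, LIVE, FluorescencePair, SemanticMap
from .optics import IntensityStack, OpticsConfig, PhaseMap, compute_dry_mass


class OvercrowdError(RuntimeError):
    """Raised when ``n_cells`` cannot be placed without nucleus overlap."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of a synthetic experiment.

    Geometry is in pixels of the (already downsampled) phase image;
    ``pixel_size_um`` defaults to 0.325 um (0.1625 um camera pitch at
    40x, downsampled by 2).
    """

    image_px: int = 256
    n_cells: int = 20
    n_frames: int = 10
    frame_interval_min: int = 30
    death_hazard_per_frame: float = 0.08
    swell_factor: float = 1.3
    shrink_factor: float = 0.7
    swell_frames: int = 2
    shrink_frames: int = 4
    phase_amplitude_rad: float = 1.5
    amplitude_jitter: float = 0.1
    dead_brightness: float = 1.5
    cyto_scale: float = 1.8
    cyto_amp_frac: float = 0.15
    min_radius_px: float = 7.0
    max_radius_px: float = 11.0
    b_ratio: float = 0.3
    noise_sigma: float = 0.005
    camera_counts: Optional[int] = None
    fluor_dead_ramp_frames: int = 1
    pixel_size_um: float = 0.325
    wavelength_um: float = 0.55
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.death_hazard_per_frame <= 1.0):
            raise ValueError("death_hazard_per_frame must be in [0, 1]")
        if min(self.image_px, self.n_cells, self.n_frames) < 1:
            raise ValueError("image_px, n_cells, n_frames must be positive")
        for name in ("swell_factor", "shrink_factor", "phase_amplitude_rad",
                     "min_radius_px", "max_radius_px", "pixel_size_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.b_ratio < 0:
            raise ValueError("b_ratio must be >= 0")


@dataclass
class SimTruth:
    """Exact ground truth: per-frame semantic maps + per-nucleus table.

    ``nuclei`` has one row per (frame, nucleus) with columns
    frame, nucleus_id, death_frame (-1 = never dies within the movie),
    centroid_row, centroid_col, area_px, dry_mass_pg, cls (0 live / 1 dead).
    Once a nucleus is dead it stays dead.
    """

    semantic_maps: list[SemanticMap]
    nuclei: pd.DataFrame


@dataclass
class SimExperiment:
    """Complete output of :func:`simulate_experiment`."""

    config: SimConfig
    stacks: list[IntensityStack]
    fluorescence: list[FluorescencePair]
    phases: list[PhaseMap]
    truth: SimTruth


def forward_slim(pm: PhaseMap, b_ratio: float, noise_sigma: float = 0.0,
                 rng: Optional[np.random.Generator] = None,
                 i0: float = 1.0) -> IntensityStack:
    """Four-step interferometric forward model.

    I_k = i0 * (1 + b^2 + 2 b cos(phi + theta_k)), theta_k in
    {0, pi/2, pi, 3pi/2}, plus optional additive Gaussian camera noise
    with sigma = ``noise_sigma`` * full scale.  Noise-free mode is exact.
    """
    if b_ratio < 0:
        raise ValueError("b_ratio must be >= 0")
    thetas = np.array([0.0, np.pi / 2, np.pi, 3 * np.pi / 2])
    frames = np.stack([
        i0 * (1.0 + b_ratio**2 + 2.0 * b_ratio * np.cos(pm.phase + t))
        for t in thetas
    ])
    if noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng()
        full_scale = i0 * (1.0 + b_ratio) ** 2
        frames = frames + rng.normal(0.0, noise_sigma * full_scale, frames.shape)
        frames = np.clip(frames, 0.0, None)
    return IntensityStack(frames, pixel_size_um=pm.pixel_size_um)


def _elliptic_d2(shape, cy, cx, a, b, theta):
    """Squared normalized elliptical radius on a bounding box.

    Returns (slice_rows, slice_cols, d2) where d2 <= 1 is inside.
    """
    h, w = shape
    r = int(np.ceil(max(a, b))) + 2
    r0, r1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
    c0, c1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dy, dx = yy - cy, xx - cx
    u = (dx * np.cos(theta) + dy * np.sin(theta)) / a
    v = (-dx * np.sin(theta) + dy * np.cos(theta)) / b
    return slice(r0, r1), slice(c0, c1), u * u + v * v


def _bump(d2: np.ndarray) -> np.ndarray:
    """Smooth compact profile (1 - d^2)^1.5 inside the unit ellipse."""
    return np.clip(1.0 - d2, 0.0, None) ** 1.5


def _death_state(k_since_death: int, cfg: SimConfig) -> tuple[float, float]:
    """(area scale, amplitude multiplier) at k frames after death."""
    k = k_since_death
    peak_k = cfg.swell_frames - 1
    if k <= peak_k:
        s = 1.0 + (cfg.swell_factor - 1.0) * (k + 1) / cfg.swell_frames
    else:
        t = min(1.0, (k - peak_k) / cfg.shrink_frames)
        s = cfg.swell_factor + (cfg.shrink_factor - cfg.swell_factor) * t
    amp = 1.25 + (cfg.dead_brightness - 1.25) * min(1.0, k / max(1, peak_k)) \
        if cfg.dead_brightness >= 1.25 else cfg.dead_brightness
    return s, amp


def _place_cells(cfg: SimConfig, rng: np.random.Generator):
    """Rejection-sample non-overlapping nuclei (allowing for swelling)."""
    margin = cfg.max_radius_px * np.sqrt(cfg.swell_factor) + 2
    cells, tries = [], 0
    max_tries = 400 * cfg.n_cells
    while len(cells) < cfg.n_cells:
        tries += 1
        if tries > max_tries:
            raise OvercrowdError(
                f"could not place {cfg.n_cells} non-overlapping nuclei in a "
                f"{cfg.image_px}x{cfg.image_px} field after {max_tries} tries"
            )
        cy, cx = rng.uniform(margin, cfg.image_px - margin, size=2)
        a = rng.uniform(cfg.min_radius_px, cfg.max_radius_px)
        b = rng.uniform(cfg.min_radius_px, cfg.max_radius_px)
        rad = max(a, b)
        ok = True
        for c in cells:
            min_sep = (rad + c["rad"]) * np.sqrt(cfg.swell_factor) + 3.0
            if np.hypot(cy - c["cy"], cx - c["cx"]) < min_sep:
                ok = False
                break
        if ok:
            cells.append({
                "cy": cy, "cx": cx, "a": a, "b": b, "rad": rad,
                "theta": rng.uniform(0, np.pi),
                "amp": cfg.phase_amplitude_rad
                       * (1.0 + cfg.amplitude_jitter * rng.uniform(-1, 1)),
            })
    return cells


def simulate_experiment(cfg: SimConfig) -> SimExperiment:
    """Render a full seeded experiment (phases, interferograms, fluorescence, truth)."""
    rng = np.random.default_rng(cfg.seed)
    cells = _place_cells(cfg, rng)

    # death frames: one Bernoulli trial per frame transition, i.e. a cell
    # first observed dead at geometric frame k >= 1; frame 0 is all-live
    # unless the hazard is 1 and the movie is read from frame 1 onward.
    h = cfg.death_hazard_per_frame
    for c in cells:
        c["death_frame"] = int(rng.geometric(h)) if h > 0 else None

    optics = OpticsConfig(pixel_size_um=cfg.pixel_size_um,
                          wavelength_um=cfg.wavelength_um)
    shape = (cfg.image_px, cfg.image_px)
    stacks, fluors, phases, sem_maps, rows = [], [], [], [], []

    for f in range(cfg.n_frames):
        phi = np.zeros(shape)
        blue = np.zeros(shape)
        green = np.zeros(shape)
        labels = np.full(shape, BACKGROUND, dtype=np.uint8)
        masks = []
        for nid, c in enumerate(cells, start=1):
            dead = c["death_frame"] is not None and f >= c["death_frame"]
            if dead:
                k = f - c["death_frame"]
                s, amp_mult = _death_state(k, cfg)
                ramp = min(1.0, (k + 1) / cfg.fluor_dead_ramp_frames)
            else:
                s, amp_mult, ramp = 1.0, 1.0, 0.0
            ax, bx = c["a"] * np.sqrt(s), c["b"] * np.sqrt(s)
            # nucleus
            sr, sc, d2 = _elliptic_d2(shape, c["cy"], c["cx"], ax, bx, c["theta"])
            bump = _bump(d2)
            phi[sr, sc] += c["amp"] * amp_mult * bump
            blue[sr, sc] += bump
            green[sr, sc] += ramp * bump
            mask = d2 <= 1.0
            labels[sr, sc][mask] = DEAD if dead else LIVE
            masks.append((nid, sr, sc, mask, dead))
            # fainter cytoplasm halo around the nucleus
            sr2, sc2, d2c = _elliptic_d2(shape, c["cy"], c["cx"],
                                         ax * cfg.cyto_scale, bx * cfg.cyto_scale,
                                         c["theta"])
            phi[sr2, sc2] += cfg.cyto_amp_frac * c["amp"] * _bump(d2c)

        pm = PhaseMap(phi, pixel_size_um=cfg.pixel_size_um,
                      wavelength_um=cfg.wavelength_um)
        phases.append(pm)
        sem_maps.append(SemanticMap(labels))
        stacks.append(forward_slim(pm, cfg.b_ratio, cfg.noise_sigma, rng))

        if cfg.noise_sigma > 0:
            blue = np.clip(blue + rng.normal(0, cfg.noise_sigma, shape), 0, None)
            green = np.clip(green + rng.normal(0, cfg.noise_sigma, shape), 0, None)
        fluors.append(FluorescencePair(blue=blue, green=green))

        for nid, sr, sc, mask, dead in masks:
            full_mask = np.zeros(shape, dtype=bool)
            full_mask[sr, sc] = mask
            c = cells[nid - 1]
            rows.append({
                "frame": f,
                "nucleus_id": nid,
                "death_frame": -1 if c["death_frame"] is None
                               or c["death_frame"] >= cfg.n_frames
                               else int(c["death_frame"]),
                "centroid_row": float(c["cy"]),
                "centroid_col": float(c["cx"]),
                "area_px": int(full_mask.sum()),
                "dry_mass_pg": compute_dry_mass(pm, full_mask, optics),
                "cls": DEAD if dead else LIVE,
            })

    truth = SimTruth(semantic_maps=sem_maps, nuclei=pd.DataFrame(rows))
    if cfg.camera_counts is not None:
        for st in stacks:
            st.frames = np.clip(np.rint(st.frames * cfg.camera_counts /
                                        (1.0 + cfg.b_ratio) ** 2), 0, 65535)
    return SimExperiment(config=cfg, stacks=stacks, fluorescence=fluors,
                         phases=phases, truth=truth)


# ---------------------------------------------------------------------------
# disk layout


def write_experiment(exp: SimExperiment, directory: str | Path) -> Path:
    """Write a dataset directory: per-frame TIFFs + manifest + truth CSV.

    Layout (NNN = zero-padded frame index):
      interf_NNN.tif  4-page float32 (or uint16 when camera_counts is set)
      phase_NNN.tif   float32, with phase_NNN.json metadata sidecar
      blue_NNN.tif / green_NNN.tif  float32 fluorescence
      truth_NNN.tif   uint8 semantic labels {0,1,2}
      manifest.json   config + seed + frame count
      truth_nuclei.csv  per-(frame, nucleus) truth table
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    quantized = exp.config.camera_counts is not None
    for f in range(len(exp.phases)):
        tag = f"{f:03d}"
        frames = exp.stacks[f].frames
        tifffile.imwrite(directory / f"interf_{tag}.tif",
                         frames.astype(np.uint16 if quantized else np.float32),
                         photometric="minisblack")
        tifffile.imwrite(directory / f"phase_{tag}.tif",
                         exp.phases[f].phase.astype(np.float32))
        (directory / f"phase_{tag}.json").write_text(json.dumps({
            "pixel_size_um": exp.phases[f].pixel_size_um,
            "wavelength_um": exp.phases[f].wavelength_um,
        }))
        tifffile.imwrite(directory / f"blue_{tag}.tif",
                         exp.fluorescence[f].blue.astype(np.float32))
        tifffile.imwrite(directory / f"green_{tag}.tif",
                         exp.fluorescence[f].green.astype(np.float32))
        tifffile.imwrite(directory / f"truth_{tag}.tif",
                         exp.truth.semantic_maps[f].labels)
    exp.truth.nuclei.to_csv(directory / "truth_nuclei.csv", index=False)
    manifest = {
        "format": "viaphase-simulated-timelapse-v1",
        "seed": exp.config.seed,
        "n_frames": len(exp.phases),
        "config": dataclasses.asdict(exp.config),
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return directory


def read_experiment(directory: str | Path) -> SimExperiment:
    """Read back a dataset written by :func:`write_experiment`."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    cfg = SimConfig(**manifest["config"])
    stacks, fluors, phases, sem_maps = [], [], [], []
    for f in range(manifest["n_frames"]):
        tag = f"{f:03d}"
        stacks.append(IntensityStack(
            tifffile.imread(directory / f"interf_{tag}.tif").astype(np.float64),
            pixel_size_um=cfg.pixel_size_um))
        meta = json.loads((directory / f"phase_{tag}.json").read_text())
        phases.append(PhaseMap(
            tifffile.imread(directory / f"phase_{tag}.tif").astype(np.float64),
            **meta))
        fluors.append(FluorescencePair(
            blue=tifffile.imread(directory / f"blue_{tag}.tif").astype(np.float64),
            green=tifffile.imread(directory / f"green_{tag}.tif").astype(np.float64)))
        sem_maps.append(SemanticMap(tifffile.imread(directory / f"truth_{tag}.tif")))
    nuclei = pd.read_csv(directory / "truth_nuclei.csv")
    return SimExperiment(config=cfg, stacks=stacks, fluorescence=fluors,
                         phases=phases,
                         truth=SimTruth(semantic_maps=sem_maps, nuclei=nuclei))


def truth_match_fraction(exp: SimExperiment, produced: list[SemanticMap]) -> float:
    """Fraction of (frame, nucleus) truth entries whose dominant produced
    label matches the simulated viability class.

    A nucleus whose footprint is predominantly background in ``produced``
    counts as a mismatch.
    """
    total, matched = 0, 0
    for f, sem in enumerate(produced):
        truth_labels = exp.truth.semantic_maps[f].labels
        sub = exp.truth.nuclei[exp.truth.nuclei["frame"] == f]
        for _, row in sub.iterrows():
            # recover this nucleus' footprint from the truth map around its centroid
            mask = _nucleus_mask(truth_labels, row)
            total += 1
            if mask is None:
                continue
            got = sem.labels[mask]
            n_live = int((got == LIVE).sum())
            n_dead = int((got == DEAD).sum())
            n_bg = int((got == BACKGROUND).sum())
            if n_bg > n_live + n_dead:
                continue  # missed nucleus
            pred = DEAD if n_dead >= n_live else LIVE
            if pred == row["cls"]:
                matched += 1
    return matched / total if total else 1.0


def _nucleus_mask(truth_labels: np.ndarray, row) -> Optional[np.ndarray]:
    from scipy import ndimage
    fg = truth_labels != BACKGROUND
    lab, _ = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    r, c = int(round(row["centroid_row"])), int(round(row["centroid_col"]))
    r = np.clip(r, 0, truth_labels.shape[0] - 1)
    c = np.clip(c, 0, truth_labels.shape[1] - 1)
    if lab[r, c] == 0:
        return None
    return lab == lab[r, c]
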