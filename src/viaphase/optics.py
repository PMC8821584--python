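"""Quantitative phase reconstruction and dry-mass computation.

Spatial light interference microscopy (SLIM) modulates the phase delay
between the incident and scattered fields in four steps (0, pi/2, pi,
3*pi/2) and records one intensity image per step.  Under the two-beam
common-path model

    I_k = I0 * (1 + b**2 + 2*b*cos(phi + theta_k)),

where ``b`` is the scattered-to-incident amplitude ratio, the phase
difference between the two fields is recovered pixel-wise by the standard
four-step estimator

    dphi = atan2(I(3pi/2) - I(pi/2), I(0) - I(pi)),

which is exact for any ``b > 0`` in the noise-free case.  Optionally the
total object phase is composed from ``dphi`` and ``b`` as
``phi = atan(b*sin(dphi) / (1 + b*cos(dphi)))``.

The optical phase is proportional to the non-aqueous (dry) content of the
cell through the refractive increment ``alpha`` (~0.2 um^3/pg for
protein), so integrating phase over a segmented region yields the region's
dry mass in picograms:

    m = lambda / (2*pi*alpha) * sum(phi) * pixel_area.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

#: Pixels whose four-step numerator AND denominator both fall below this
#: fraction of the stack's intensity scale carry no phase information.
CONTRAST_FLOOR = 1e-12


class ReconstructionError(RuntimeError):
    """Raised when a stack is too degenerate to yield a phase map."""


@dataclass(frozen=True)
class OpticsConfig:
    """Optical constants of the imaging system.

    Parameters
    ----------
    b_ratio:
        Scattered-to-incident field amplitude ratio used to compose the
        total object phase from the measured phase difference.  ``None``
        (the default) selects *identity* mode: the four-step phase
        difference is returned directly, which is exact for the forward
        model used by the bundled simulator.
    wavelength_um:
        Central illumination wavelength in micrometres (broadband LED,
        taken as 0.55 um).
    pixel_size_um:
        Effective object-plane pixel pitch (6.5 um camera pixel behind a
        40x objective -> 0.1625 um).
    alpha_ri_um3_per_pg:
        Refractive increment of cellular dry matter, 0.2 um^3/pg.
    """

    b_ratio: Optional[float] = None
    wavelength_um: float = 0.55
    pixel_size_um: float = 0.1625
    alpha_ri_um3_per_pg: float = 0.2

    def __post_init__(self) -> None:
        if self.b_ratio is not None and self.b_ratio < 0:
            raise ValueError("b_ratio must be >= 0")
        for name in ("wavelength_um", "pixel_size_um", "alpha_ri_um3_per_pg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class IntensityStack:
    """Four co-registered intensity frames ordered by modulator shift.

    ``frames`` has shape (4, H, W) with the frames corresponding to phase
    shifts 0, pi/2, pi and 3*pi/2 in that order.
    """

    frames: np.ndarray
    pixel_size_um: float = 0.1625

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3 or self.frames.shape[0] != 4:
            raise ValueError("IntensityStack.frames must have shape (4, H, W)")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("intensities must be finite")
        if np.any(self.frames < 0):
            raise ValueError("intensities must be non-negative")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class PhaseMap:
    """2-D quantitative phase image in radians with pixel/wavelength metadata."""

    phase: np.ndarray
    pixel_size_um: float = 0.1625
    wavelength_um: float = 0.55

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=np.float64)
        if self.phase.ndim != 2:
            raise ValueError("PhaseMap.phase must be 2-D")
        if not np.all(np.isfinite(self.phase)):
            raise ValueError("phase must be finite everywhere")
        if self.pixel_size_um <= 0 or self.wavelength_um <= 0:
            raise ValueError("pixel_size_um and wavelength_um must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.phase.shape


def reconstruct_phase(stack: IntensityStack, cfg: OpticsConfig = OpticsConfig()) -> PhaseMap:
    """Recover a phase map from four phase-shifted intensity frames.

    Pixels where both atan2 arguments are below the contrast floor are set
    to zero phase; if more than half the pixels are degenerate the whole
    reconstruction is rejected.

    Returns a :class:`PhaseMap` inheriting ``pixel_size_um`` and
    ``wavelength_um`` from ``cfg``.
    """
    i0, i1, i2, i3 = stack.frames
    num = i3 - i1  # I(3pi/2) - I(pi/2)  = 4 b I0 sin(phi)
    den = i0 - i2  # I(0)    - I(pi)    = 4 b I0 cos(phi)

    scale = float(stack.frames.max())
    floor = CONTRAST_FLOOR * (scale if scale > 0 else 1.0)
    degenerate = (np.abs(num) < floor) & (np.abs(den) < floor)
    n_deg = int(degenerate.sum())
    if n_deg > 0.5 * degenerate.size:
        raise ReconstructionError(
            f"{n_deg}/{degenerate.size} pixels have no four-frame contrast; "
            "stack looks like a flat field"
        )

    dphi = np.arctan2(num, den)
    dphi[degenerate] = 0.0

    if cfg.b_ratio is None:
        phase = dphi
    else:
        b = cfg.b_ratio
        phase = np.arctan2(b * np.sin(dphi), 1.0 + b * np.cos(dphi))
    return PhaseMap(phase, pixel_size_um=cfg.pixel_size_um, wavelength_um=cfg.wavelength_um)


def downsample_phase(pm: PhaseMap, factor: int) -> PhaseMap:
    """Block-mean downsample a phase map by an integer factor.

    Trailing rows/columns not divisible by ``factor`` are cropped.  The
    pixel size is multiplied by ``factor``; full-scale processing uses
    factor 2.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return PhaseMap(pm.phase.copy(), pm.pixel_size_um, pm.wavelength_um)
    h, w = pm.shape
    hc, wc = (h // factor) * factor, (w // factor) * factor
    blocks = pm.phase[:hc, :wc].reshape(hc // factor, factor, wc // factor, factor)
    return PhaseMap(blocks.mean(axis=(1, 3)), pm.pixel_size_um * factor, pm.wavelength_um)


def compute_dry_mass(pm: PhaseMap, mask: np.ndarray, cfg: OpticsConfig = OpticsConfig()) -> float:
    """Integrate phase over ``mask`` and convert to dry mass in picograms.

    m = wavelength / (2 pi alpha) * sum_{x in mask} phi(x) * pixel_area,
    using the phase map's own pixel size and wavelength.  Empty masks give
    exactly 0.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.shape != pm.shape:
        raise ValueError(f"mask shape {mask.shape} != phase shape {pm.shape}")
    if not mask.any():
        return 0.0
    prefactor = pm.wavelength_um / (2.0 * np.pi * cfg.alpha_ri_um3_per_pg)
    return float(prefactor * pm.phase[mask].sum() * pm.pixel_size_um**2)
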