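"""Shared file I/O: TIFF images, label maps, phase maps, CSV and JSON.

All round trips are lossless: interferograms are stored as 16-bit
unsigned or 32-bit float TIFF exactly as provided, phase maps as 32-bit
float TIFF with a JSON metadata sidecar (pixel size, wavelength), label
maps as 8-bit TIFF restricted to the palette {0 live, 1 dead,
2 background}.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .ground_truth import SemanticMap
from .optics import IntensityStack, PhaseMap


class FormatError(ValueError):
    """A file exists but does not conform to the expected schema."""


def write_tiff_image(arr: np.ndarray, path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(arr))
    return path


def read_tiff_image(path) -> np.ndarray:
    try:
        return tifffile.imread(path)
    except Exception as exc:  # noqa: BLE001 - rewrap with format context
        raise FormatError(f"not a readable TIFF image: {path} ({exc})") from exc


def write_label_map(sem: SemanticMap, path) -> Path:
    return write_tiff_image(sem.labels.astype(np.uint8), path)


def read_label_map(path) -> SemanticMap:
    arr = read_tiff_image(path)
    vals = np.unique(arr)
    if not np.isin(vals, (0, 1, 2)).all():
        raise FormatError(
            f"label TIFF {path} contains values outside {{0,1,2}}: {vals}")
    return SemanticMap(arr.astype(np.uint8))


def write_phase_map(pm: PhaseMap, path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, pm.phase.astype(np.float32))
    path.with_suffix(".json").write_text(json.dumps({
        "pixel_size_um": pm.pixel_size_um,
        "wavelength_um": pm.wavelength_um,
    }))
    return path


def read_phase_map(path) -> PhaseMap:
    path = Path(path)
    arr = read_tiff_image(path).astype(np.float64)
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    else:
        meta = {}
    return PhaseMap(arr, pixel_size_um=meta.get("pixel_size_um", 0.1625),
                    wavelength_um=meta.get("wavelength_um", 0.55))


def write_stack(stack: IntensityStack, path, as_uint16: bool = False) -> Path:
    frames = stack.frames
    if as_uint16:
        if frames.max() > 65535 or np.any(frames != np.rint(frames)):
            raise FormatError("stack is not integer-valued in [0, 65535]; "
                              "cannot store as 16-bit without loss")
        frames = frames.astype(np.uint16)
    else:
        frames = frames.astype(np.float32)
    path = Path(path)
    tifffile.imwrite(path, frames, photometric="minisblack")
    return path


def read_stack(path, pixel_size_um: float = 0.1625) -> IntensityStack:
    arr = read_tiff_image(path).astype(np.float64)
    if arr.ndim != 3 or arr.shape[0] != 4:
        raise FormatError(f"interferogram TIFF {path} must have 4 pages")
    return IntensityStack(arr, pixel_size_um=pixel_size_um)


def write_tracks_csv(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_tracks_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"track_id", "frame"}
    if not required.issubset(df.columns):
        raise FormatError(f"tracks CSV {path} missing columns {required - set(df.columns)}")
    return df


def write_report_json(report: dict, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(_jsonify(report), indent=2, sort_keys=True))
    return path


def read_report_json(path) -> dict:
    try:
        return json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"not a valid JSON report: {path}") from exc


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
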