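"""Sequence and result I/O: float TIFF stacks, hashed CSVs, JSON sidecars."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import DEFAULT_FPS, ThermalSequence, ThermofaceError


class FormatError(ThermofaceError):
    pass


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_sequence(sequence: ThermalSequence, path: str | Path) -> None:
    """Write a sequence as a multi-page 32-bit-float TIFF plus JSON sidecar.

    Temperatures are stored as raw float32 °C matrices, one page per frame;
    fps and subject id travel in the sidecar.
    """
    path = Path(path)
    tifffile.imwrite(path, sequence.frames.astype(np.float32), photometric="minisblack")
    _sidecar_path(path).write_text(
        json.dumps({"fps": sequence.fps, "subject_id": sequence.subject_id})
    )


def read_sequence(path: str | Path) -> ThermalSequence:
    """Read a multi-page float TIFF sequence written by :func:`write_sequence`.

    Raises :class:`FormatError` for non-float dtypes (8-/16-bit thermograms
    lack temperature precision), inconsistent page shapes, or truncated
    files.
    """
    path = Path(path)
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # tifffile raises various internal errors
        raise FormatError(f"cannot read TIFF {path.name}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.dtype.kind != "f":
        raise FormatError(
            f"unsupported dtype {arr.dtype}: temperature stacks must be 32-bit float"
        )
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3 or arr.dtype == object:
        raise FormatError("pages must share one 2-D shape")
    fps, subject_id = DEFAULT_FPS, path.stem
    sc = _sidecar_path(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
        fps = float(meta.get("fps", fps))
        subject_id = meta.get("subject_id", subject_id)
    return ThermalSequence(frames=arr.astype(float), fps=fps, subject_id=subject_id)


def config_hash(config_dict: dict) -> str:
    """Stable short hash of a (JSON-serialisable) config; key order ignored."""
    payload = json.dumps(config_dict, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_result_csv(df: pd.DataFrame, path: str | Path, cfg_hash: str = "") -> None:
    """CSV with the run's config hash embedded as a leading comment line."""
    path = Path(path)
    with open(path, "w") as fh:
        if cfg_hash:
            fh.write(f"# config_hash: {cfg_hash}\n")
        df.to_csv(fh, index=False)


def read_result_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
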