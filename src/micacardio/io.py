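"""Readers and writers for every on-disk format the pipeline touches.

Volumes, masks, priors, component maps, label maps and stat maps are NIfTI-1
(via nibabel). Physiological traces and block designs are tab-separated text
with a ``#``-prefixed metadata header. Realignment matrices are plain-text
4-line blocks. A single nestable YAML config drives the CLI.

All writers round-trip bit-exactly with their readers for float32 payloads.
"""
from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .types import (
    DesignBlocks,
    Mask,
    PhysioTrace,
    RealignmentTrack,
    TissuePriors,
    VolumeSeries,
)

logger = logging.getLogger("micacardio")

__all__ = [
    "read_volume",
    "read_volume3d",
    "read_mask",
    "write_volume",
    "read_trace",
    "write_trace",
    "read_design",
    "write_design",
    "read_realign",
    "write_realign",
    "read_config",
    "write_config",
    "derive_seed",
]


class FormatError(ValueError):
    """Malformed file header or payload."""


class DimensionError(ValueError):
    """A file with the wrong number of dimensions or missing time metadata."""


# ---------------------------------------------------------------------------
# NIfTI volumes


def read_volume(path, tr: float | None = None, run_id: str | None = None) -> VolumeSeries:
    """Load a 4D NIfTI file as a :class:`VolumeSeries`.

    The repetition time is taken from the NIfTI header time-step field; a
    ``tr`` override exists for files with broken headers. A missing/zero
    header tr without an override raises :class:`DimensionError`.
    """
    img = _load_nifti(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise DimensionError(f"{path}: expected 4D volume, got {data.ndim}D")
    if tr is None:
        zooms = img.header.get_zooms()
        tr = float(zooms[3]) if len(zooms) > 3 else 0.0
        if tr <= 0:
            raise DimensionError(f"{path}: header has no usable time-step and no tr override given")
    if run_id is None:
        run_id = Path(path).name.split(".")[0]
    return VolumeSeries(data=np.asarray(data, dtype=float), tr=tr, affine=img.affine, run_id=run_id)


def read_volume3d(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a 3D NIfTI file; returns ``(data, affine)``."""
    img = _load_nifti(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise DimensionError(f"{path}: expected 3D volume, got {data.ndim}D")
    return np.asarray(data), img.affine


def read_mask(path) -> Mask:
    data, affine = read_volume3d(path)
    return Mask(data=data > 0, affine=affine)


def read_priors(gm_path, wm_path, csf_path) -> TissuePriors:
    gm, affine = read_volume3d(gm_path)
    wm, _ = read_volume3d(wm_path)
    csf, _ = read_volume3d(csf_path)
    return TissuePriors(gm=gm, wm=wm, csf=csf, affine=affine)


def _load_nifti(path):
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several incompatible types
        raise FormatError(f"{path}: not a readable NIfTI file ({exc})") from exc
    return img


def write_volume(obj, path) -> None:
    """Write a VolumeSeries, Mask, or bare array (with affine) to NIfTI-1.

    Float payloads are stored as float32 (lossless for float32 inputs);
    integer payloads (label maps) as int32; boolean masks as uint8.
    """
    if isinstance(obj, VolumeSeries):
        data, affine, tr = obj.data, obj.affine, obj.tr
    elif isinstance(obj, Mask):
        data, affine, tr = obj.data, obj.affine, None
    elif isinstance(obj, tuple) and len(obj) == 2:
        data, affine = obj
        tr = None
        if abs(np.linalg.det(np.asarray(affine, dtype=float))) < 1e-12:
            raise ValueError("affine is not invertible")
    else:
        raise TypeError("write_volume takes VolumeSeries, Mask, or (data, affine)")
    data = np.asarray(data)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    elif np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.int32)
    else:
        data = data.astype(np.float32)
    img = nib.Nifti1Image(data, np.asarray(affine, dtype=float))
    if tr is not None:
        zooms = list(img.header.get_zooms())
        zooms[3] = tr
        img.header.set_zooms(zooms)
        img.header["xyzt_units"] = 10  # mm + s
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Delimited-text physiological traces and designs

_FLOAT_FMT = "%.17g"  # exact round-trip for IEEE doubles


def write_trace(trace: PhysioTrace, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# kind: {trace.kind}\n")
        fh.write(f"# fs: {_FLOAT_FMT % trace.fs}\n")
        fh.write("sample\tvalid\n")
        for s, v in zip(trace.samples, trace.valid):
            fh.write(f"{_FLOAT_FMT % s}\t{int(v)}\n")


def read_trace(path) -> PhysioTrace:
    meta: dict[str, str] = {}
    samples: list[float] = []
    valid: list[bool] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line.lstrip("# ").partition(":")
                meta[key.strip()] = value.strip()
            elif line.startswith("sample"):
                continue
            else:
                parts = line.split("\t")
                samples.append(float(parts[0]))
                valid.append(bool(int(parts[1])) if len(parts) > 1 else True)
    if "fs" not in meta:
        raise FormatError(f"{path}: trace header does not declare fs")
    return PhysioTrace(
        samples=np.array(samples),
        fs=float(meta["fs"]),
        kind=meta.get("kind", "pulse"),
        valid=np.array(valid, dtype=bool),
    )


def write_design(design: DesignBlocks, path) -> None:
    with open(path, "w") as fh:
        fh.write("# design\n")
        fh.write("label\tstart\tend\n")
        for label, start, end in design.blocks:
            fh.write(f"{label}\t{_FLOAT_FMT % start}\t{_FLOAT_FMT % end}\n")


def read_design(path) -> DesignBlocks:
    blocks: list[tuple[str, float, float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("label"):
                continue
            label, start, end = line.split("\t")
            blocks.append((label, float(start), float(end)))
    return DesignBlocks(blocks=blocks)


# ---------------------------------------------------------------------------
# Realignment matrices (plain-text 4x4 blocks, blank-line separated)


def write_realign(track: RealignmentTrack, path) -> None:
    with open(path, "w") as fh:
        for mat in track.matrices:
            for row in mat:
                fh.write("  ".join(_FLOAT_FMT % x for x in row) + "\n")
            fh.write("\n")


def read_realign(path) -> RealignmentTrack:
    rows: list[list[float]] = []
    mats: list[np.ndarray] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                if rows:
                    mats.append(np.array(rows))
                    rows = []
                continue
            rows.append([float(x) for x in line.split()])
    if rows:
        mats.append(np.array(rows))
    if not mats:
        raise FormatError(f"{path}: no matrices found")
    arr = np.stack(mats)
    if arr.shape[1:] != (4, 4):
        raise FormatError(f"{path}: matrices are not 4x4")
    return RealignmentTrack(matrices=arr)


# ---------------------------------------------------------------------------
# Config and seeds


def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return cfg


def write_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def derive_seed(seed: int, *labels) -> int:
    """Derive a stable sub-seed (< 2**31) from a master seed and stage labels.

    Uses SHA-256 so derivation is independent of the interpreter hash seed;
    every pipeline stage draws its randomness from a seed derived this way,
    which makes reruns with the same config and master seed bit-identical.
    """
    h = hashlib.sha256()
    h.update(str(int(seed)).encode())
    for lab in labels:
        h.update(b"/")
        h.update(str(lab).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)
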