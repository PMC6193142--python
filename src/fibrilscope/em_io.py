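"""Readers and writers for the formats the pipeline touches.

* MRC2014 volumes and image stacks (mode 2, 32-bit float), voxel size in
  the header.  Axis order on disk is x fastest, z slowest, which maps to a
  C-ordered numpy array of shape ``(nz, ny, nx)``.
* EMAN-style ``.box`` particle coordinate files (whitespace-separated
  ``x y w h`` rows giving the left-top corner of each box).
* Tab-separated tables with a header row (UTF-8).

All writers are byte-deterministic: re-writing an unmodified object
reproduces an identical file body.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ParticleStack, Volume3D

__all__ = [
    "read_volume",
    "write_volume",
    "read_stack",
    "write_stack",
    "read_box",
    "read_table",
    "write_table",
]

_HEADER_BYTES = 1024
_MODE_FLOAT32 = 2


def _pack_header(nx: int, ny: int, nz: int, voxel_size: float, data: np.ndarray,
                 is_stack: bool) -> bytes:
    """Build a 1024-byte MRC2014 header for mode-2 data."""
    h = bytearray(_HEADER_BYTES)
    struct.pack_into("<3i", h, 0, nx, ny, nz)
    struct.pack_into("<i", h, 12, _MODE_FLOAT32)
    # nxstart/nystart/nzstart = 0; mx/my/mz mirror the grid
    struct.pack_into("<3i", h, 28, nx, ny, nz)
    cell = (nx * voxel_size, ny * voxel_size, nz * voxel_size)
    struct.pack_into("<3f", h, 40, *cell)
    struct.pack_into("<3f", h, 52, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", h, 64, 1, 2, 3)  # mapc, mapr, maps
    dmin, dmax, dmean = float(data.min()), float(data.max()), float(data.mean())
    struct.pack_into("<3f", h, 76, dmin, dmax, dmean)
    # ispg: 0 marks an image stack, 1 a volume (MRC2014 convention)
    struct.pack_into("<2i", h, 88, 0 if is_stack else 1, 0)
    h[208:212] = b"MAP "
    h[212:216] = bytes((0x44, 0x44, 0, 0))  # little-endian machine stamp
    struct.pack_into("<f", h, 216, float(data.std()))
    return bytes(h)


def _parse_header(raw: bytes, path: Path) -> tuple[tuple[int, int, int], float]:
    if len(raw) < _HEADER_BYTES:
        raise ValueError(f"{path}: truncated MRC header ({len(raw)} < {_HEADER_BYTES} bytes)")
    nx, ny, nz = struct.unpack_from("<3i", raw, 0)
    (mode,) = struct.unpack_from("<i", raw, 12)
    if mode != _MODE_FLOAT32:
        raise ValueError(f"{path}: unsupported MRC mode {mode} (only mode 2 float32)")
    mx = struct.unpack_from("<3i", raw, 28)[0]
    cella_x = struct.unpack_from("<3f", raw, 40)[0]
    voxel = cella_x / mx if mx > 0 and cella_x > 0 else 1.0
    (nsymbt,) = struct.unpack_from("<i", raw, 92)
    if nsymbt != 0:
        raise ValueError(f"{path}: extended headers are not supported")
    return (nx, ny, nz), voxel


def _read_mrc(path) -> tuple[np.ndarray, float]:
    path = Path(path)
    raw = path.read_bytes()
    (nx, ny, nz), voxel = _parse_header(raw, path)
    expected = _HEADER_BYTES + 4 * nx * ny * nz
    if len(raw) < expected:
        raise ValueError(
            f"{path}: truncated MRC file, expected {expected} bytes, got {len(raw)}"
        )
    data = np.frombuffer(raw[_HEADER_BYTES:expected], dtype="<f4").reshape(nz, ny, nx)
    return data.copy(), voxel


def _write_mrc(data: np.ndarray, voxel_size: float, path, is_stack: bool) -> None:
    data = np.ascontiguousarray(data, dtype="<f4")
    nz, ny, nx = data.shape
    with open(path, "wb") as fh:
        fh.write(_pack_header(nx, ny, nz, voxel_size, data, is_stack))
        fh.write(data.tobytes())


def read_volume(path) -> Volume3D:
    """Read an MRC volume (mode 2); z is the slowest axis."""
    data, voxel = _read_mrc(path)
    return Volume3D(data, voxel)


def write_volume(volume: Volume3D, path) -> None:
    _write_mrc(volume.data, volume.voxel_size, path, is_stack=False)


def read_stack(path) -> ParticleStack:
    """Read an MRC image stack as (n, h, w)."""
    data, voxel = _read_mrc(path)
    return ParticleStack(data, voxel, provenance=str(path))


def write_stack(stack: ParticleStack, path) -> None:
    _write_mrc(stack.data, stack.pixel_size, path, is_stack=True)


def read_box(path, image_height: int | None = None, flip_y: bool = False) -> np.ndarray:
    """Read EMAN .box coordinates and return particle centers, 0-based px.

    Each row is ``x y width height`` (left-top corner).  Centers are
    ``corner + box/2``.  With ``flip_y=True`` the y origin is taken as the
    image bottom and ``image_height`` must be given.

    Returns an ``(n, 2)`` array of ``(cx, cy)``; empty files give ``(0, 2)``.
    """
    if flip_y and image_height is None:
        raise ValueError("flip_y requires image_height")
    centers = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise ValueError(f"{path}: line {lineno}: expected >= 4 columns, got {len(parts)}")
            x, y, w, h = (float(v) for v in parts[:4])
            if w != h:
                raise ValueError(f"{path}: line {lineno}: box width != height ({w} x {h})")
            if x < 0 or y < 0:
                raise ValueError(f"{path}: line {lineno}: negative corner coordinates")
            cx = x + w / 2.0
            cy = y + h / 2.0
            if flip_y:
                cy = image_height - 1 - cy
            centers.append((cx, cy))
    return np.array(centers, dtype=float).reshape(-1, 2)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")
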