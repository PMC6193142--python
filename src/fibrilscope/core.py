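"""Core in-memory containers shared across the pipeline.

Conventions
-----------
* 3D rasters are numpy arrays indexed ``(z, y, x)`` with the filament axis
  along ``z``.  Voxel size is carried in Angstrom per voxel.
* 2D particle images are indexed ``(row, col)`` = ``(z, x)`` for projections
  of a filament: the filament axis is vertical in the image.
* Angles are degrees.  The azimuth ``phi`` is the rotation of the repeat
  about its own (z) axis; ``psi`` is the in-plane rotation of a particle
  image.  Both are stored reduced to [0, 360).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Volume3D",
    "ParticleStack",
    "TiltSeries",
    "AlignmentRecord",
    "FilamentTrace",
    "CorrelationCurve",
    "FSCCurve",
    "records_to_frame",
    "frame_to_records",
]


@dataclass
class Volume3D:
    """A 3D density raster with isotropic voxel size in Angstrom."""

    data: np.ndarray
    voxel_size: float  # Angstrom / voxel

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"Volume3D needs a 3D array, got shape {self.data.shape}")
        if self.voxel_size <= 0:
            raise ValueError("voxel size must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy(self) -> "Volume3D":
        return Volume3D(self.data.copy(), self.voxel_size)


@dataclass
class ParticleStack:
    """An ordered set of same-sized 2D images with pixel size in Angstrom."""

    data: np.ndarray
    pixel_size: float  # Angstrom / pixel
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"ParticleStack needs (n, h, w), got {self.data.shape}")
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")

    def __len__(self) -> int:
        return self.data.shape[0]

    @property
    def box(self) -> tuple[int, int]:
        return self.data.shape[1:]


@dataclass
class TiltSeries:
    """Single-axis tilt projections with their nominal tilt angles (deg).

    The tilt axis is the image row axis (y in the volume); images are
    indexed ``(tilt, y, x)``.
    """

    data: np.ndarray
    angles: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.data.ndim != 3 or self.data.shape[0] != self.angles.shape[0]:
            raise ValueError("tilt series images and angles disagree")

    def __len__(self) -> int:
        return self.data.shape[0]


@dataclass
class AlignmentRecord:
    """Per-particle alignment parameters.

    The generative convention is::

        particle ~ shift(rotate_inplane(projection(volume, phi), psi), (dx, dy))

    so inverting a record means un-shifting, then un-rotating.
    """

    psi: float = 0.0  # in-plane rotation, deg in [0, 360)
    dx: float = 0.0  # shift, px (column direction)
    dy: float = 0.0  # shift, px (row direction)
    phi: float = 0.0  # azimuth about the filament axis, deg in [0, 360)
    ref_index: int = 0
    score: float = 0.0  # normalized correlation in [-1, 1]
    flagged: bool = False

    def __post_init__(self) -> None:
        self.psi = float(self.psi) % 360.0
        self.phi = float(self.phi) % 360.0


RECORD_COLUMNS = ["psi", "dx", "dy", "phi", "ref_index", "score", "flagged"]


def records_to_frame(records: list[AlignmentRecord]) -> pd.DataFrame:
    """Tabulate alignment records (one row per particle, documented columns)."""
    return pd.DataFrame(
        [
            (r.psi, r.dx, r.dy, r.phi, r.ref_index, r.score, int(r.flagged))
            for r in records
        ],
        columns=RECORD_COLUMNS,
    )


def frame_to_records(frame: pd.DataFrame) -> list[AlignmentRecord]:
    return [
        AlignmentRecord(
            psi=row.psi,
            dx=row.dx,
            dy=row.dy,
            phi=row.phi,
            ref_index=int(row.ref_index),
            score=row.score,
            flagged=bool(row.flagged),
        )
        for row in frame.itertuples(index=False)
    ]


@dataclass
class FilamentTrace:
    """Ordered centerline points of one filament in voxel coordinates.

    ``points`` is ``(n, 3)`` in ``(z, y, x)`` order; unit tangents are
    computed by central differences on demand.  ``voxel_size_nm`` converts
    to physical units.
    """

    points: np.ndarray
    voxel_size_nm: float

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[0] >= 2:
            steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
            med = np.median(steps)
            if med > 0 and steps.max() > 3.0 * med:
                raise ValueError("trace has a gap > 3x the median point spacing")

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def tangents(self) -> np.ndarray:
        """Unit tangents by central differences, one per point."""
        p = self.points
        if len(p) < 2:
            raise ValueError("a trace needs at least 2 points")
        t = np.gradient(p, axis=0)
        n = np.linalg.norm(t, axis=1, keepdims=True)
        n[n == 0] = 1.0
        return t / n

    @property
    def mean_tangent(self) -> np.ndarray:
        t = self.tangents.mean(axis=0)
        return t / np.linalg.norm(t)


@dataclass
class CorrelationCurve:
    """Mean correlation versus rotation angle about the filament axis."""

    angles: np.ndarray  # deg, regular grid covering [0, 360)
    values: np.ndarray  # correlation per angle

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.angles.shape != self.values.shape:
            raise ValueError("angle grid and values disagree")

    @property
    def step(self) -> float:
        return float(self.angles[1] - self.angles[0])


@dataclass
class FSCCurve:
    """Fourier shell correlation: one value per concentric frequency shell."""

    frequencies: np.ndarray  # shell center spatial frequencies, 1/Angstrom
    values: np.ndarray  # correlation per shell
    shell_width_px: int = 1

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("shell frequencies must increase")
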