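"""Voxel-grid data model and MRC/CCP4 volume I/O.

The in-memory convention used throughout the package:

* ``data`` is indexed ``(i, j, k)`` which corresponds to physical ``(z, y, x)``.
* The physical position of the *center* of voxel ``(i, j, k)`` is
  ``origin + (i * vz, j * vy, k * vx)`` with ``origin`` and ``voxel_size``
  stored in the same ``(z, y, x)`` order, all in Angstrom.
* Files on disk may store the volume with any axis permutation
  (``mapc/mapr/maps``); reading always canonicalizes to the convention above.

Origin dialect: EMDB depositions either set the MRC2014 ``origin`` header
record or leave it zero and encode the offset via ``nxstart/nystart/nzstart``.
:func:`read_map` uses the origin record when any component is nonzero and
falls back to ``nstart * voxel_size`` otherwise.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "VoxelGrid",
    "MapMetadata",
    "MapFormatError",
    "UnsupportedGeometryError",
    "read_map",
    "write_map",
]


class MapFormatError(ValueError):
    """Raised for a malformed or unreadable volume file."""


class UnsupportedGeometryError(ValueError):
    """Raised for non-orthogonal unit cells (not produced by cryo-EM SPA)."""


@dataclass
class VoxelGrid:
    """A 3-D scalar field with physical origin and per-axis voxel size.

    Parameters
    ----------
    data:
        3-D array indexed ``(z, y, x)``.
    voxel_size:
        Edge lengths ``(vz, vy, vx)`` in Angstrom, all positive.
    origin:
        Physical position ``(oz, oy, ox)`` in Angstrom of the center of
        voxel ``(0, 0, 0)``.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    metadata: "MapMetadata | None" = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got ndim={self.data.ndim}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.voxel_size) != 3 or len(self.origin) != 3:
            raise ValueError("voxel_size and origin must have 3 components")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in cubic Angstrom."""
        vz, vy, vx = self.voxel_size
        return vz * vy * vx

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical coordinates of voxel centers along one (z=0, y=1, x=2) axis."""
        return self.origin[axis] + self.voxel_size[axis] * np.arange(self.shape[axis])

    def same_geometry(self, other: "VoxelGrid", tol: float = 1e-4) -> bool:
        """True if shape, voxel size and origin agree (within ``tol`` Angstrom)."""
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_size, other.voxel_size, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def with_data(self, data: np.ndarray) -> "VoxelGrid":
        """A new grid sharing this grid's geometry with different values."""
        if data.shape != self.shape:
            raise ValueError(f"data shape {data.shape} != grid shape {self.shape}")
        return VoxelGrid(data, self.voxel_size, self.origin, metadata=self.metadata)


@dataclass
class MapMetadata:
    """Optional descriptive metadata carried alongside a volume."""

    source_id: str = ""
    reported_resolution: float | None = None
    recommended_contour: float | None = None

    def __post_init__(self) -> None:
        if self.reported_resolution is not None and self.reported_resolution <= 0:
            raise ValueError("reported_resolution must be positive")


def read_map(path: str | os.PathLike) -> VoxelGrid:
    """Read an MRC/CCP4 volume, canonicalizing axis order to (z, y, x).

    The stored axis permutation (``mapc/mapr/maps`` header words) is undone so
    the returned field is always indexed ``(z, y, x)``; voxel size is
    ``cell length / sampling`` per axis; the origin follows the dialect rule
    described in the module docstring.

    Raises
    ------
    MapFormatError
        If the file cannot be parsed or a header field is invalid.
    UnsupportedGeometryError
        If the cell angles are not all 90 degrees.
    """
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise MapFormatError(f"cannot read MRC/CCP4 volume {path!r}: {exc}") from exc

    angles = [m.header_float(w) for w in (14, 15, 16)]
    if not np.allclose(angles, 90.0, atol=1e-3):
        raise UnsupportedGeometryError(
            f"non-orthogonal cell angles {angles}; only (90, 90, 90) supported"
        )
    # reorder stored data to x-fastest without resizing to the full cell
    m.setup(float("nan"), gemmi.MapSetup.ReorderOnly)

    sampling = [m.header_i32(w) for w in (8, 9, 10)]  # mx, my, mz
    cell = [m.header_float(w) for w in (11, 12, 13)]  # a, b, c in Angstrom
    for name, val in zip(("mx", "my", "mz"), sampling):
        if val <= 0:
            raise MapFormatError(f"invalid header field {name}={val}")
    for name, val in zip(("cella.a", "cella.b", "cella.c"), cell):
        if val <= 0:
            raise MapFormatError(f"invalid header field {name}={val}")

    voxel_xyz = [c / s for c, s in zip(cell, sampling)]
    origin_xyz = [m.header_float(w) for w in (50, 51, 52)]
    if not any(origin_xyz):
        nstart = [m.header_i32(w) for w in (5, 6, 7)]
        origin_xyz = [n * v for n, v in zip(nstart, voxel_xyz)]

    data_xyz = np.array(m.grid, copy=True)
    data = np.ascontiguousarray(data_xyz.transpose(2, 1, 0)).astype(np.float32)
    return VoxelGrid(
        data,
        voxel_size=(voxel_xyz[2], voxel_xyz[1], voxel_xyz[0]),
        origin=(origin_xyz[2], origin_xyz[1], origin_xyz[0]),
    )


def write_map(grid: VoxelGrid, path: str | os.PathLike) -> None:
    """Write a grid as an MRC mode-2 (32-bit float) volume.

    The file uses canonical axis mapping (mapc=1, mapr=2, maps=3) and records
    voxel size and origin such that :func:`read_map` inverts exactly (up to
    32-bit float representation of the data).
    """
    nz, ny, nx = grid.shape
    vz, vy, vx = grid.voxel_size
    oz, oy, ox = grid.origin

    data_xyz = np.ascontiguousarray(
        np.asarray(grid.data, dtype=np.float32).transpose(2, 1, 0)
    )
    g = gemmi.FloatGrid(data_xyz)
    g.unit_cell = gemmi.UnitCell(nx * vx, ny * vy, nz * vz, 90.0, 90.0, 90.0)
    g.spacegroup = gemmi.SpaceGroup("P1")

    m = gemmi.Ccp4Map()
    m.grid = g
    m.update_ccp4_header(2)
    for word, value in zip((50, 51, 52), (ox, oy, oz)):
        m.set_header_float(word, value)
    try:
        m.write_ccp4_map(str(path))
    except (RuntimeError, OSError) as exc:
        raise IOError(f"cannot write volume to {path!r}: {exc}") from exc
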