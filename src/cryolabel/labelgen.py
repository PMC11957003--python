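"""Voxel-wise training-label volumes from a structure and a reference grid.

Three aligned label volumes are produced on the experimental map's geometry:

* **regression** — the simulated (idealized, noise-free) density, kept inside
  a 6 A neighborhood of the atoms and zero elsewhere; the denoising target.
* **classification** — three classes: 1 at voxels containing an atom
  coordinate, 2 at remaining voxels within the neighborhood radius of any
  atom, 0 background.
* **atom_type** — atom-class values {1..5} (CA, CB, carbonyl C, O, N) only at
  the voxels containing the atom coordinates; no dilation, since the chemical
  identity of a neighboring voxel is ambiguous.

Labels depend only on the experimental map's *geometry*, never on its density
values, so two noisy observations of the same grid yield identical labels.

Coordinate-to-index conversion pairs i with z, j with y, k with x:
``i = floor((z - oz)/vz)`` etc., i.e. an atom belongs to the cell it falls in.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .grid_io import VoxelGrid
from .simulate import SimulationParams, simulate_on_map
from .structure_model import Structure, classify_atom

__all__ = [
    "NeighborhoodSpec",
    "LabelBundle",
    "AlignmentError",
    "coord_to_voxel",
    "coords_to_voxels",
    "dilated_mask",
    "make_regression_label",
    "make_classification_label",
    "make_atomtype_label",
    "generate_labels",
    "extract_subcubes",
    "reassemble_subcubes",
]

logger = logging.getLogger(__name__)


class AlignmentError(ValueError):
    """Raised when two volumes expected to share a geometry do not."""


@dataclass
class NeighborhoodSpec:
    """Dilation settings for the label neighborhoods.

    ``radius`` is the Euclidean distance in Angstrom from the atom's
    continuous coordinate to a voxel *center*; the boundary is inclusive
    (<= radius) by default.
    """

    radius: float = 6.0
    inclusive: bool = True

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError("radius must be >= 0")


@dataclass
class LabelBundle:
    """The three aligned label volumes sharing one grid geometry."""

    regression: VoxelGrid
    classification: VoxelGrid
    atom_type: VoxelGrid

    def validate(self) -> None:
        """Check the bundle invariants; raises ``AssertionError`` on violation."""
        assert self.regression.same_geometry(self.classification)
        assert self.regression.same_geometry(self.atom_type)
        cls = np.asarray(self.classification.data)
        at = np.asarray(self.atom_type.data)
        reg = np.asarray(self.regression.data)
        assert set(np.unique(cls)).issubset({0, 1, 2})
        assert set(np.unique(at)).issubset({0, 1, 2, 3, 4, 5})
        assert np.all(cls[at > 0] == 1), "atom-type voxels must be class-1 voxels"
        assert np.all(reg[cls == 0] == 0), "regression must vanish on background"
        assert np.all(reg >= 0)


def coord_to_voxel(
    coord: tuple[float, float, float], grid: VoxelGrid
) -> tuple[int, int, int]:
    """Convert one (x, y, z) coordinate to its (i, j, k) = (z, y, x) cell index.

    May return out-of-bounds indices; the caller decides how to treat atoms
    outside the grid.
    """
    x, y, z = coord
    oz, oy, ox = grid.origin
    vz, vy, vx = grid.voxel_size
    return (
        int(np.floor((z - oz) / vz)),
        int(np.floor((y - oy) / vy)),
        int(np.floor((x - ox) / vx)),
    )


def coords_to_voxels(coords_xyz: np.ndarray, grid: VoxelGrid) -> np.ndarray:
    """Vectorized :func:`coord_to_voxel`: (N, 3) xyz -> (N, 3) integer (i, j, k)."""
    coords_zyx = np.asarray(coords_xyz, dtype=float)[:, ::-1]
    rel = (coords_zyx - np.asarray(grid.origin)) / np.asarray(grid.voxel_size)
    return np.floor(rel).astype(int)


def dilated_mask(
    structure: Structure, grid: VoxelGrid, spec: NeighborhoodSpec | None = None
) -> np.ndarray:
    """Boolean volume: True where the voxel center lies within ``spec.radius``
    Angstrom of at least one atom coordinate.

    Computed by stamping a per-atom window, which is exact (no rasterization
    of the atom position: distances are measured from the continuous
    coordinate).
    """
    if len(structure) == 0:
        raise ValueError("empty structure")
    spec = spec or NeighborhoodSpec()
    out = np.zeros(grid.shape, dtype=bool)
    shape = grid.shape
    voxel = grid.voxel_size
    origin = grid.origin
    r = spec.radius
    r_sq = r * r
    for atom in structure:
        x, y, z = atom.coord
        pos_zyx = (z, y, x)
        lo, hi = [], []
        for ax in range(3):
            frac = (pos_zyx[ax] - origin[ax]) / voxel[ax]
            w = r / voxel[ax]
            lo.append(max(0, int(np.ceil(frac - w)) - 1))
            hi.append(min(shape[ax] - 1, int(np.floor(frac + w)) + 1))
        if any(a > b for a, b in zip(lo, hi)):
            continue
        d2 = 0.0
        for ax, newshape in zip(range(3), ((-1, 1, 1), (1, -1, 1), (1, 1, -1))):
            centers = origin[ax] + voxel[ax] * np.arange(lo[ax], hi[ax] + 1)
            d2 = d2 + ((centers - pos_zyx[ax]) ** 2).reshape(newshape)
        inside = d2 <= r_sq if spec.inclusive else d2 < r_sq
        out[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] |= inside
    return out


def _inbounds_atom_voxels(structure: Structure, grid: VoxelGrid) -> np.ndarray:
    """(M, 3) indices of in-bounds atom voxels, in file order; logs skips."""
    idx = coords_to_voxels(structure.coords(), grid)
    inb = np.all((idx >= 0) & (idx < np.asarray(grid.shape)), axis=1)
    n_out = int((~inb).sum())
    if n_out:
        logger.info("%d atom(s) fall outside the grid and are skipped", n_out)
    return idx[inb]


def make_regression_label(
    structure: Structure,
    reference: VoxelGrid,
    simulated: VoxelGrid,
    spec: NeighborhoodSpec | None = None,
) -> VoxelGrid:
    """Simulated density inside the dilated neighborhood; exact 0 elsewhere."""
    if not simulated.same_geometry(reference):
        raise AlignmentError("simulated map geometry differs from the reference map")
    mask = dilated_mask(structure, reference, spec)
    data = np.where(mask, np.asarray(simulated.data), 0).astype(np.float32)
    return reference.with_data(data)


def make_classification_label(
    structure: Structure,
    reference: VoxelGrid,
    spec: NeighborhoodSpec | None = None,
) -> VoxelGrid:
    """Three-class volume: atom voxels 1, neighborhood 2, background 0.

    Value 1 takes precedence over 2 regardless of atom order. If every atom
    falls outside the grid the result is all zero (with a warning).
    """
    if len(structure) == 0:
        raise ValueError("empty structure")
    data = np.zeros(reference.shape, dtype=np.uint8)
    data[dilated_mask(structure, reference, spec)] = 2
    idx = _inbounds_atom_voxels(structure, reference)
    if len(idx) == 0:
        warnings.warn("all atoms fall outside the grid; classification label is empty",
                      stacklevel=2)
        return reference.with_data(np.zeros(reference.shape, dtype=np.uint8))
    data[idx[:, 0], idx[:, 1], idx[:, 2]] = 1
    return reference.with_data(data)


def make_atomtype_label(structure: Structure, reference: VoxelGrid) -> VoxelGrid:
    """Atom-class values only at the atom voxels; no dilation.

    When two atoms map to the same voxel the later atom in file order wins
    (deterministic tie-break, logged).
    """
    if len(structure) == 0:
        raise ValueError("empty structure")
    data = np.zeros(reference.shape, dtype=np.uint8)
    seen: set[tuple[int, int, int]] = set()
    collisions = 0
    for atom in structure:
        cls = classify_atom(atom)
        if cls == 0:
            continue
        i, j, k = coord_to_voxel(atom.coord, reference)
        if not (0 <= i < reference.shape[0] and 0 <= j < reference.shape[1]
                and 0 <= k < reference.shape[2]):
            continue
        if (i, j, k) in seen:
            collisions += 1
        seen.add((i, j, k))
        data[i, j, k] = cls
    if collisions:
        logger.info("%d atom-type voxel collision(s); last atom in file order kept",
                    collisions)
    return reference.with_data(data)


def generate_labels(
    structure: Structure,
    experimental_map: VoxelGrid,
    params: SimulationParams,
    spec: NeighborhoodSpec | None = None,
) -> LabelBundle:
    """Run the full label workflow on one map/model pair.

    Simulates density on the experimental map's geometry and builds the three
    label volumes. The result is a function of the experimental map's
    geometry only, never of its density values.
    """
    spec = spec or NeighborhoodSpec()
    simulated = simulate_on_map(structure, experimental_map, params)
    regression = make_regression_label(structure, experimental_map, simulated, spec)
    classification = make_classification_label(structure, experimental_map, spec)
    atom_type = make_atomtype_label(structure, experimental_map)
    # class-1 voxels that carry no atom-type class still satisfy the bundle
    # invariants; the converse (atom_type > 0 outside class 1) cannot happen
    # because both use the same coord_to_voxel cells.
    return LabelBundle(regression, classification, atom_type)


def extract_subcubes(
    volume: np.ndarray | VoxelGrid,
    cube_edge: int = 64,
    stride: int | None = None,
) -> list[tuple[tuple[int, int, int], np.ndarray]]:
    """Tile a volume into sub-cubes for memory-efficient model training.

    Returns ``[(offset_ijk, cube), ...]`` where ``offset_ijk`` is the tile's
    position in the original volume. Tiles extending past the edge are
    zero-padded to ``cube_edge``; together the tiles cover the full volume.
    """
    if stride is None:
        stride = cube_edge
    if stride <= 0:
        raise ValueError("stride must be positive")
    if cube_edge <= 0:
        raise ValueError("cube_edge must be positive")
    data = volume.data if isinstance(volume, VoxelGrid) else np.asarray(volume)
    starts = [
        range(0, max(n - cube_edge, 0) + stride, stride) if n > cube_edge else [0]
        for n in data.shape
    ]
    # keep only starts that add coverage
    starts = [[s for s in ax if s < n] for ax, n in zip(starts, data.shape)]
    tiles = []
    for i in starts[0]:
        for j in starts[1]:
            for k in starts[2]:
                cube = np.zeros((cube_edge,) * 3, dtype=data.dtype)
                block = data[i : i + cube_edge, j : j + cube_edge, k : k + cube_edge]
                cube[: block.shape[0], : block.shape[1], : block.shape[2]] = block
                tiles.append(((i, j, k), cube))
    return tiles


def reassemble_subcubes(
    tiles: list[tuple[tuple[int, int, int], np.ndarray]],
    shape: tuple[int, int, int],
) -> np.ndarray:
    """Invert :func:`extract_subcubes` for non-overlapping tiles (padding trimmed)."""
    out = np.zeros(shape, dtype=tiles[0][1].dtype)
    for (i, j, k), cube in tiles:
        bi = min(cube.shape[0], shape[0] - i)
        bj = min(cube.shape[1], shape[1] - j)
        bk = min(cube.shape[2], shape[2] - k)
        out[i : i + bi, j : j + bj, k : k + bk] = cube[:bi, :bj, :bk]
    return out
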