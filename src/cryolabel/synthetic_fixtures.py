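"""Synthetic toy structures and matched noisy maps for fully offline testing.

The fixture is an idealized poly-alanine alpha-helix plus a simulated clean
map and a noisy "experimental-like" copy (clean + seeded Gaussian white
noise). It emulates the one property the label workflow depends on — a map
and a model occupying the same physical frame, with the map degraded by
background noise — and deliberately nothing else: no ice/carbon structural
noise, no CTF, no detector model, no conformational heterogeneity.

Helix geometry: CA trace on a cylinder of radius 2.3 A with 1.5 A rise and
100 degree twist per residue; N, C, O, CB sit at fixed offsets in each
residue's rotating local frame, so the construction is rigid and exactly
repeating.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .grid_io import VoxelGrid
from .labelgen import LabelBundle, NeighborhoodSpec, generate_labels
from .simulate import SimulationParams, simulate_density
from .standardize import resample
from .structure_model import AtomRecord, Structure

__all__ = ["FixtureSpec", "make_helix", "make_noisy_map", "make_fixture_bundle"]

# CA-trace helical parameters (Angstrom / degrees)
_HELIX_RADIUS = 2.3
_HELIX_RISE = 1.5
_HELIX_TWIST_DEG = 100.0

# local offsets of the other heavy atoms relative to CA, rotated per residue
_LOCAL_OFFSETS = {
    "N": (-0.95, 0.65, -1.00),
    "C": (1.20, 0.45, 0.70),
    "O": (1.45, 1.65, 0.95),
    "CB": (0.55, -1.40, 0.35),
}
_ATOM_ORDER = ("N", "CA", "C", "O", "CB")
_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}


@dataclass
class FixtureSpec:
    """Parameters of one synthetic map/model fixture."""

    n_residues: int = 10
    noise_sigma: float = 0.1
    resolution: float = 3.0
    voxel_size: float = 1.0
    box_pad: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise ValueError("n_residues must be >= 1")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def make_helix(n_residues: int) -> Structure:
    """Idealized poly-alanine alpha-helix with 5 heavy atoms per residue."""
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    atoms: list[AtomRecord] = []
    for i in range(n_residues):
        theta = math.radians(_HELIX_TWIST_DEG * i)
        cos_t, sin_t = math.cos(theta), math.sin(theta)
        ca = np.array(
            [_HELIX_RADIUS * cos_t, _HELIX_RADIUS * sin_t, _HELIX_RISE * i]
        )
        for name in _ATOM_ORDER:
            if name == "CA":
                pos = ca
            else:
                dx, dy, dz = _LOCAL_OFFSETS[name]
                # rotate the local offset with the residue about the helix axis
                pos = ca + np.array(
                    [dx * cos_t - dy * sin_t, dx * sin_t + dy * cos_t, dz]
                )
            atoms.append(
                AtomRecord(
                    element=_ELEMENTS[name],
                    atom_name=name,
                    residue_name="ALA",
                    chain_id="A",
                    coord=(float(pos[0]), float(pos[1]), float(pos[2])),
                )
            )
    return Structure(atoms=atoms, source_id=f"helix{n_residues}")


def make_noisy_map(
    structure: Structure, spec: FixtureSpec
) -> tuple[VoxelGrid, VoxelGrid]:
    """Simulate a clean map around a structure and add seeded white noise.

    The grid covers the structure's bounding box plus ``box_pad`` per side at
    ``spec.voxel_size``. Returns ``(noisy, clean)``; with ``noise_sigma == 0``
    the two are bitwise identical.
    """
    coords = structure.coords()
    lo_xyz = coords.min(axis=0) - spec.box_pad
    hi_xyz = coords.max(axis=0) + spec.box_pad
    v = spec.voxel_size
    shape = tuple(
        int(math.ceil((hi_xyz[ax] - lo_xyz[ax]) / v)) + 1 for ax in (2, 1, 0)
    )
    geometry = VoxelGrid(
        np.zeros(shape, dtype=np.float32),
        voxel_size=(v, v, v),
        origin=(float(lo_xyz[2]), float(lo_xyz[1]), float(lo_xyz[0])),
    )
    clean = simulate_density(
        structure, geometry, SimulationParams(resolution=spec.resolution)
    )
    if spec.noise_sigma == 0:
        return clean.with_data(clean.data.copy()), clean
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.noise_sigma, size=clean.shape)
    noisy = clean.with_data((clean.data + noise).astype(np.float32))
    return noisy, clean


def make_fixture_bundle(
    spec: FixtureSpec,
) -> tuple[Structure, VoxelGrid, VoxelGrid, LabelBundle]:
    """End-to-end fixture: helix, noisy/clean maps, and the label bundle.

    The noisy map is resampled to 1 A when the fixture voxel size differs,
    mirroring the standardization step of the real workflow; labels are
    generated on the standardized grid.
    """
    structure = make_helix(spec.n_residues)
    noisy, clean = make_noisy_map(structure, spec)
    standardized = noisy if spec.voxel_size == 1.0 else resample(noisy, 1.0)
    bundle = generate_labels(
        structure,
        standardized,
        SimulationParams(resolution=spec.resolution),
        NeighborhoodSpec(),
    )
    return structure, noisy, clean, bundle
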