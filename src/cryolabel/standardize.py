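"""Resampling of density maps onto an isotropic grid (default 1 Angstrom).

Deposited cryo-EM maps come with voxel sizes anywhere from ~0.7 to ~1.6 A;
voxel-wise learning needs a common sampling. Resampling is trilinear
interpolation of the input field at the new voxel centers: local,
deterministic, exact on affine fields, and bounded by the input value range
(every output value is a convex combination of input values). The physical
origin is preserved so the map stays aligned with its atomic model.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .grid_io import VoxelGrid

__all__ = ["resample"]


def resample(grid: VoxelGrid, target_voxel: float = 1.0) -> VoxelGrid:
    """Resample a map onto an isotropic grid of ``target_voxel`` Angstrom.

    The output covers the input's physical extent: per axis the new length is
    ``floor(extent / target_voxel) + 1`` with ``extent = (n - 1) * voxel``.
    Sample points outside the input support evaluate to 0 (solvent
    background). Resampling at the native voxel size of an already isotropic
    map is the identity.

    Raises
    ------
    ValueError
        If ``target_voxel <= 0`` or any input axis has length 1 (no extent to
        interpolate over).
    """
    if target_voxel <= 0:
        raise ValueError(f"target_voxel must be positive, got {target_voxel}")
    if any(n < 2 for n in grid.shape):
        raise ValueError(f"cannot resample a degenerate grid of shape {grid.shape}")

    new_shape = tuple(
        int(np.floor((n - 1) * v / target_voxel)) + 1
        for n, v in zip(grid.shape, grid.voxel_size)
    )
    if new_shape == grid.shape and np.allclose(grid.voxel_size, target_voxel):
        return VoxelGrid(
            grid.data.copy(), (target_voxel,) * 3, grid.origin, metadata=grid.metadata
        )

    # fractional input indices of the output voxel centers (shared origin)
    axes = [
        np.arange(n_out) * (target_voxel / v)
        for n_out, v in zip(new_shape, grid.voxel_size)
    ]
    coords = np.meshgrid(*axes, indexing="ij")
    out = ndimage.map_coordinates(
        np.asarray(grid.data, dtype=np.float64),
        np.stack(coords),
        order=1,
        mode="constant",
        cval=0.0,
    )
    return VoxelGrid(
        out.astype(np.float32),
        voxel_size=(target_voxel,) * 3,
        origin=grid.origin,
        metadata=grid.metadata,
    )
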