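"""Unmasked Fourier Shell Correlation (FSC) and resolution estimation.

FSC measures the normalized cross-correlation of two volumes as a function of
spatial frequency:

    FSC(s) = Re sum_{shell s} F_A F_B* /
             sqrt( sum_{shell s} |F_A|^2 * sum_{shell s} |F_B|^2 )

computed over spherical shells of the 3-D discrete Fourier transforms. The
resolution estimate is the reciprocal of the frequency where the curve first
drops below a threshold: 0.143 is the conventional map resolution criterion
and 0.5 the more stringent map-model agreement criterion. No mask is applied
anywhere (global, unmasked analysis).

Shells are one reciprocal-grid step wide (bin width ``1 / (N * voxel)`` for a
cubic grid; for anisotropic grids the physical frequency magnitude on the
anisotropic reciprocal lattice is binned with the coarsest axis's step). The
DC term is excluded, and shells run up to the most limiting axis's Nyquist
frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid_io import VoxelGrid
from .labelgen import AlignmentError
from .simulate import SimulationParams, simulate_on_map
from .structure_model import Structure

__all__ = [
    "FSCCurve",
    "ResolutionEstimate",
    "fsc_curve",
    "resolution_at_threshold",
    "map_model_fsc",
    "percent_improvement",
    "summarize_resolutions",
]


@dataclass
class FSCCurve:
    """Per-shell spatial frequency (1/Angstrom), correlation, and voxel count."""

    shell_freq: np.ndarray
    correlation: np.ndarray
    n_voxels: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.shell_freq = np.asarray(self.shell_freq, dtype=float)
        self.correlation = np.asarray(self.correlation, dtype=float)
        self.n_voxels = np.asarray(self.n_voxels, dtype=int)
        if not np.all(np.diff(self.shell_freq) > 0):
            raise ValueError("shell_freq must be strictly increasing")

    @property
    def nyquist_resolution(self) -> float:
        """2 x the largest voxel size, in Angstrom."""
        return 2.0 * max(self.voxel_size)


@dataclass
class ResolutionEstimate:
    """Threshold-crossing resolution in Angstrom.

    ``crossed`` is False when the curve never fell below the threshold before
    Nyquist; the estimate is then the Nyquist resolution itself.
    """

    threshold: float
    resolution: float
    crossed: bool


def _shell_bins(shape, voxel_size):
    """Physical |s| per Fourier voxel, bin indices, bin width, and shell count."""
    freqs = [
        np.fft.fftfreq(n, d=v) for n, v in zip(shape, voxel_size)
    ]
    s2 = 0.0
    for ax, f in enumerate(freqs):
        newshape = [1, 1, 1]
        newshape[ax] = -1
        s2 = s2 + (f**2).reshape(newshape)
    s = np.sqrt(s2)
    ds = max(1.0 / (n * v) for n, v in zip(shape, voxel_size))
    bins = np.rint(s / ds).astype(int)
    nyquist = min(1.0 / (2.0 * v) for v in voxel_size)
    n_shells = int(np.floor(nyquist / ds + 0.5))
    return bins, ds, n_shells


def fsc_curve(map_a: VoxelGrid, map_b: VoxelGrid) -> FSCCurve:
    """Unmasked FSC between two volumes of identical geometry.

    Raises
    ------
    AlignmentError
        If shapes or voxel sizes differ.
    ValueError
        If either map is identically zero (correlation undefined).
    """
    if map_a.shape != map_b.shape or not np.allclose(
        map_a.voxel_size, map_b.voxel_size
    ):
        raise AlignmentError("maps must share shape and voxel size for FSC")
    a = np.asarray(map_a.data, dtype=np.float64)
    b = np.asarray(map_b.data, dtype=np.float64)
    if not a.any() or not b.any():
        raise ValueError("FSC of an all-zero map is undefined")

    fa = np.fft.fftn(a)
    fb = np.fft.fftn(b)
    bins, ds, n_shells = _shell_bins(map_a.shape, map_a.voxel_size)
    flat = bins.ravel()
    minlength = flat.max() + 1

    cross = np.bincount(flat, weights=(fa * np.conj(fb)).real.ravel(),
                        minlength=minlength)
    pow_a = np.bincount(flat, weights=(fa.real**2 + fa.imag**2).ravel(),
                        minlength=minlength)
    pow_b = np.bincount(flat, weights=(fb.real**2 + fb.imag**2).ravel(),
                        minlength=minlength)
    counts = np.bincount(flat, minlength=minlength)

    shells = np.arange(1, n_shells + 1)
    shells = shells[shells < minlength]
    denom = np.sqrt(pow_a[shells] * pow_b[shells])
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, cross[shells] / denom, 0.0)
    return FSCCurve(
        shell_freq=shells * ds,
        correlation=corr,
        n_voxels=counts[shells],
        voxel_size=map_a.voxel_size,
    )


def resolution_at_threshold(curve: FSCCurve, threshold: float) -> ResolutionEstimate:
    """Resolution at the first threshold crossing, by linear interpolation.

    If the first shell is already below the threshold the crossing is taken
    at the first shell's frequency; if the curve never drops below the
    threshold the Nyquist resolution is returned with ``crossed=False``.
    """
    c = curve.correlation
    s = curve.shell_freq
    if len(c) == 0:
        raise ValueError("empty FSC curve")
    below = np.nonzero(c < threshold)[0]
    if len(below) == 0:
        return ResolutionEstimate(threshold, curve.nyquist_resolution, crossed=False)
    i = below[0]
    if i == 0:
        s_star = s[0]
    else:
        c0, c1 = c[i - 1], c[i]
        s_star = s[i - 1] + (c0 - threshold) / (c0 - c1) * (s[i] - s[i - 1])
    return ResolutionEstimate(threshold, 1.0 / s_star, crossed=True)


def map_model_fsc(
    density_map: VoxelGrid,
    structure: Structure,
    params: SimulationParams,
) -> FSCCurve:
    """Map-model FSC: correlate a map with density simulated from its model.

    The model density is simulated on the map's exact geometry, then the
    unmasked FSC between the two volumes is returned.
    """
    simulated = simulate_on_map(structure, density_map, params)
    return fsc_curve(density_map, simulated)


def percent_improvement(before: float, after: float) -> float:
    """Resolution improvement in percent: ``100 * (before - after) / before``.

    Smaller Angstrom values are better, so a positive result means the
    ``after`` map resolves finer detail.
    """
    if before <= 0:
        raise ValueError("'before' resolution must be positive")
    return 100.0 * (before - after) / before


def summarize_resolutions(values) -> dict[str, float]:
    """Box-plot style summary: mean, median, quartiles and 1.5 IQR whiskers.

    Quartiles use linear interpolation between order statistics.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty collection")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    iqr = q3 - q1
    return {
        "mean": float(arr.mean()),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(q1 - 1.5 * iqr),
        "whisker_high": float(q3 + 1.5 * iqr),
        "n": int(arr.size),
    }
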