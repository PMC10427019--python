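"""Gaussian-spreading forward model: atom coordinates -> model density.

Each atom contributes a normalized isotropic Gaussian of width sigma,
scaled by its amplitude, evaluated at voxel centers and truncated at a
hard real-space radius of ``cutoff_multiple * sigma`` (default 4 sigma,
which captures more than 99.8% of the analytic Gaussian mass in 3D).

The spreading width is chosen so the Gaussian's full width at half
maximum equals the target resolution; on a grid the finest representable
resolution is twice the voxel size, which gives the voxel-size rule.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .grids import AtomSet, DensityGrid

__all__ = [
    "SpreadParams",
    "sigma_from_resolution",
    "sigma_from_voxel",
    "spread_density",
    "spread_gradient",
]

log = logging.getLogger(__name__)

# FWHM = 2*sqrt(2*ln 2) * sigma for a Gaussian
_FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass
class SpreadParams:
    """Parameters of the Gaussian spreading forward model.

    sigma : Gaussian width in Å (isotropic).
    cutoff_multiple : truncation radius in units of sigma.
    normalize : rescale the spread grid so voxel values sum to 1
        (required by the relative-entropy scores, which treat the model
        density as a probability distribution).
    """

    sigma: float
    cutoff_multiple: float = 4.0
    normalize: bool = False

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.cutoff_multiple <= 0:
            raise ValueError(f"cutoff_multiple must be positive, got {self.cutoff_multiple}")


def sigma_from_resolution(resolution: float) -> float:
    """Gaussian sigma whose full width at half maximum equals `resolution` (Å)."""
    if resolution <= 0:
        raise ValueError(f"resolution must be positive, got {resolution}")
    return resolution / _FWHM_FACTOR


def sigma_from_voxel(voxel_size: float) -> float:
    """Spreading width from the voxel size.

    The finest resolution representable on a grid is twice the voxel
    size (the Nyquist limit), so this is ``sigma_from_resolution(2 * voxel_size)``.
    """
    if voxel_size <= 0:
        raise ValueError(f"voxel size must be positive, got {voxel_size}")
    return sigma_from_resolution(2.0 * voxel_size)


def _active_dims(grid: DensityGrid) -> list[int]:
    """Axes with more than one voxel; degenerate axes do not count toward
    the Gaussian normalization exponent (1D/2D model systems)."""
    return [a for a in range(3) if grid.shape[a] > 1]


def _check_geometry(grid: DensityGrid, params: SpreadParams) -> float:
    active = _active_dims(grid)
    sp = grid.spacing[active] if active else grid.spacing
    if not np.allclose(sp, sp[0]):
        raise ValueError(f"spreading requires isotropic spacing, got {grid.spacing}")
    delta = float(sp[0])
    if params.sigma < delta / 2:
        log.warning(
            "sigma %.4g Å is below half the voxel size %.4g Å: the Gaussian is undersampled",
            params.sigma,
            delta,
        )
    return delta


def _atom_window(grid: DensityGrid, pos: np.ndarray, radius: float):
    """Index slices per axis covering voxel centers within `radius` of `pos`,
    clipped to the grid; returns None if the window is empty."""
    slices = []
    for a in range(3):
        lo = int(math.ceil((pos[a] - radius - grid.origin[a]) / grid.spacing[a]))
        hi = int(math.floor((pos[a] + radius - grid.origin[a]) / grid.spacing[a]))
        lo = max(lo, 0)
        hi = min(hi, grid.shape[a] - 1)
        if lo > hi:
            return None
        slices.append(slice(lo, hi + 1))
    return tuple(slices)


def _gaussian_prefactor(sigma: float, ndim: int) -> float:
    return (2.0 * math.pi * sigma * sigma) ** (-ndim / 2.0)


def spread_density(
    atoms: AtomSet, grid_geometry: DensityGrid, params: SpreadParams
) -> DensityGrid:
    """Spread atoms onto the grid: the model density rho^s.

    Each voxel receives ``A_i * (2*pi*sigma^2)^(-d/2) * exp(-|r_i - c_v|^2 / (2*sigma^2))``
    from every atom i within the truncation radius, where d is the number
    of non-degenerate grid dimensions and c_v the voxel center. With
    ``normalize=True`` the result is rescaled to unit sum (an all-zero
    grid is returned unchanged).
    """
    _check_geometry(grid_geometry, params)
    ndim = max(len(_active_dims(grid_geometry)), 1)
    sigma = params.sigma
    radius = params.cutoff_multiple * sigma
    pref = _gaussian_prefactor(sigma, ndim)
    values = np.zeros(grid_geometry.shape)
    axes = grid_geometry.voxel_centers()
    for pos, amp in zip(atoms.positions, atoms.amplitudes):
        if amp == 0.0:
            continue
        win = _atom_window(grid_geometry, pos, radius)
        if win is None:
            continue
        d2 = (
            (axes[0][win[0]] - pos[0])[:, None, None] ** 2
            + (axes[1][win[1]] - pos[1])[None, :, None] ** 2
            + (axes[2][win[2]] - pos[2])[None, None, :] ** 2
        )
        contrib = amp * pref * np.exp(-d2 / (2.0 * sigma * sigma))
        contrib[d2 > radius * radius] = 0.0
        values[win] += contrib
    if params.normalize:
        total = values.sum()
        if total > 0:
            values /= total
    return grid_geometry.like(values)


def spread_gradient(
    atoms: AtomSet,
    grid_geometry: DensityGrid,
    params: SpreadParams,
    voxel_weights: np.ndarray,
) -> np.ndarray:
    """Per-atom gradient of the weighted (unnormalized) spread density.

    Returns, for each atom i, ``sum_v w_v * grad_{r_i} rho^s_{v,i}`` with
    the analytic Gaussian gradient ``rho^s_{v,i} * (c_v - r_i) / sigma^2``,
    truncated identically to :func:`spread_density`. Normalization of the
    model density is *not* part of this function; callers propagating
    forces through a normalized model fold the normalization Jacobian
    into `voxel_weights` (see :mod:`mlfit.forces`).
    """
    voxel_weights = np.asarray(voxel_weights, dtype=float)
    if voxel_weights.shape != grid_geometry.shape:
        raise ValueError(
            f"weight grid shape {voxel_weights.shape} != grid shape {grid_geometry.shape}"
        )
    _check_geometry(grid_geometry, params)
    ndim = max(len(_active_dims(grid_geometry)), 1)
    sigma = params.sigma
    radius = params.cutoff_multiple * sigma
    pref = _gaussian_prefactor(sigma, ndim)
    axes = grid_geometry.voxel_centers()
    grads = np.zeros((len(atoms), 3))
    inv_s2 = 1.0 / (sigma * sigma)
    for i, (pos, amp) in enumerate(zip(atoms.positions, atoms.amplitudes)):
        if amp == 0.0:
            continue
        win = _atom_window(grid_geometry, pos, radius)
        if win is None:
            continue
        dx = (axes[0][win[0]] - pos[0])[:, None, None]
        dy = (axes[1][win[1]] - pos[1])[None, :, None]
        dz = (axes[2][win[2]] - pos[2])[None, None, :]
        d2 = dx**2 + dy**2 + dz**2
        rho = amp * pref * np.exp(-d2 / (2.0 * sigma * sigma))
        rho[d2 > radius * radius] = 0.0
        w = voxel_weights[win] * rho * inv_s2
        grads[i, 0] = np.sum(w * dx)
        grads[i, 1] = np.sum(w * dy)
        grads[i, 2] = np.sum(w * dz)
    return grads
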