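"""Map-map and model-model agreement metrics.

Fourier shell correlation (FSC) between two maps, its unweighted average
(a refinement-convergence monitor independent of the fitting potential),
threshold-crossing resolution estimates, and superposition-free RMSD
(the cryo-EM map fixes the absolute frame of reference, so no alignment
is performed; the result is an upper bound on aligned RMSD).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .grids import AtomSet, DensityGrid

__all__ = [
    "FSCCurve",
    "fsc_curve",
    "fsc_average",
    "ResolutionEstimate",
    "resolution_at_threshold",
    "sigma_for_eman2_resolution",
    "rmsd_no_superposition",
]


@dataclass
class FSCCurve:
    """Per-shell spatial frequencies (1/Å), correlations, and voxel counts."""

    frequencies: np.ndarray
    correlations: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.frequencies) > 0):
            raise ValueError("shell frequencies must be strictly increasing")
        if np.any(self.counts <= 0):
            raise ValueError("shell voxel counts must be positive")


def fsc_curve(map1: DensityGrid, map2: DensityGrid, max_frequency: float | None = None) -> FSCCurve:
    """Fourier shell correlation between two maps on the same grid.

    Shells are one reciprocal voxel wide (frequency step 1/(N*delta) of
    the largest axis) up to the Nyquist frequency; the DC term is
    excluded. Per shell:
    ``FSC = Re(sum F1 * conj(F2)) / sqrt(sum |F1|^2 * sum |F2|^2)``.
    """
    if map1.shape != map2.shape or not np.allclose(map1.spacing, map2.spacing):
        raise ValueError("maps must share grid shape and spacing")
    a = map1.values
    b = map2.values
    if not a.any() or not b.any():
        raise ValueError("FSC undefined for an all-zero map")
    F1 = np.fft.fftn(a)
    F2 = np.fft.fftn(b)
    freqs = [
        np.fft.fftfreq(n, d=d) for n, d in zip(a.shape, map1.spacing)
    ]
    s2 = (
        freqs[0][:, None, None] ** 2
        + freqs[1][None, :, None] ** 2
        + freqs[2][None, None, :] ** 2
    )
    s = np.sqrt(s2)
    # shell width: one reciprocal voxel of the coarsest-sampled (longest) axis
    active = [i for i in range(3) if a.shape[i] > 1]
    ds = min(1.0 / (a.shape[i] * map1.spacing[i]) for i in active)
    nyquist = min(0.5 / map1.spacing[i] for i in active)
    if max_frequency is not None:
        nyquist = min(nyquist, max_frequency)
    shell = np.rint(s / ds).astype(int)
    n_shells = int(math.floor(nyquist / ds + 0.5))
    cross = F1 * np.conj(F2)
    p1 = np.abs(F1) ** 2
    p2 = np.abs(F2) ** 2
    flat = shell.ravel()
    num = np.bincount(flat, weights=cross.real.ravel(), minlength=n_shells + 1)
    d1 = np.bincount(flat, weights=p1.ravel(), minlength=n_shells + 1)
    d2 = np.bincount(flat, weights=p2.ravel(), minlength=n_shells + 1)
    cnt = np.bincount(flat, minlength=n_shells + 1)
    idx = np.arange(1, n_shells + 1)  # exclude DC shell 0
    keep = (cnt[idx] > 0) & (d1[idx] > 0) & (d2[idx] > 0)
    idx = idx[keep]
    corr = num[idx] / np.sqrt(d1[idx] * d2[idx])
    return FSCCurve(idx * ds, corr, cnt[idx])


def fsc_average(curve: FSCCurve) -> float:
    """Unweighted arithmetic mean of the per-shell FSC values."""
    if len(curve.correlations) == 0:
        raise ValueError("empty FSC curve")
    return float(np.mean(curve.correlations))


@dataclass
class ResolutionEstimate:
    resolution: float  # Å
    crossed: bool  # False: curve never fell below the threshold (Nyquist limit returned)


def resolution_at_threshold(curve: FSCCurve, threshold: float) -> ResolutionEstimate:
    """Reciprocal of the first frequency where the FSC crosses below the
    threshold, with linear interpolation between shells."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    f = curve.frequencies
    c = curve.correlations
    below = np.flatnonzero(c < threshold)
    if len(below) == 0:
        return ResolutionEstimate(1.0 / f[-1], crossed=False)
    i = below[0]
    if i == 0:
        return ResolutionEstimate(1.0 / f[0], crossed=True)
    # linear interpolation between shell i-1 (above) and i (below)
    frac = (c[i - 1] - threshold) / (c[i - 1] - c[i])
    s_cross = f[i - 1] + frac * (f[i] - f[i - 1])
    return ResolutionEstimate(1.0 / s_cross, crossed=True)


def sigma_for_eman2_resolution(resolution: float) -> float:
    """Gaussian sigma corresponding to a resolution in the EMAN2 pdb2mrc
    convention, sigma = resolution / (pi * sqrt(2)); used to build the
    comparison densities for FSC monitoring (0.45 Å at 2 Å resolution)."""
    if resolution <= 0:
        raise ValueError(f"resolution must be positive, got {resolution}")
    return resolution / (math.pi * math.sqrt(2.0))


def rmsd_no_superposition(atoms_a: AtomSet, atoms_b: AtomSet) -> float:
    """Heavy-atom RMSD in the absolute frame (no alignment).

    Atoms with zero amplitude (hydrogens) are excluded. Atom order must
    match between the two sets.
    """
    if len(atoms_a) != len(atoms_b):
        raise ValueError(f"atom count mismatch: {len(atoms_a)} vs {len(atoms_b)}")
    heavy = (atoms_a.amplitudes > 0) & (atoms_b.amplitudes > 0)
    if not heavy.any():
        raise ValueError("no heavy atoms to compare")
    d2 = np.sum((atoms_a.positions[heavy] - atoms_b.positions[heavy]) ** 2, axis=1)
    return float(np.sqrt(np.mean(d2)))
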