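"""Per-atom fitting forces from the similarity gradient and the spreading
gradient.

The density force on atom i is

    F_i = k * sum_v dS/d(rho^s_v) * grad_{r_i} rho^s_v ,

the chain rule through the forward model. For the probability-based
scores the model density is the *normalized* spread; the Jacobian of the
sum-to-one normalization is propagated so the forces are the exact
negative coordinate gradient of U_fit = -k*S.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .grids import AtomSet, DensityGrid
from .similarity import (
    PreparedTarget,
    ScoreValue,
    is_probability_kind,
    score,
    score_derivative,
)
from .spreading import SpreadParams, spread_density, spread_gradient

__all__ = [
    "FittingForceField",
    "fitting_forces",
    "apply_multiple_timestep",
    "estimate_max_timestep",
]


@dataclass
class FittingForceField:
    """A similarity kind, prepared target, spreading parameters, force
    constant k (energy per score unit) and multiple-time-step period."""

    target: PreparedTarget
    params: SpreadParams
    k: float = 1.0
    n_fit: int = 1

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("force constant k must be nonnegative")
        if self.n_fit < 1:
            raise ValueError("N_fit must be >= 1")

    @property
    def kind(self) -> str:
        return self.target.kind


def model_density(ff: FittingForceField, atoms: AtomSet) -> DensityGrid:
    """Forward model under the force field's conventions (normalized for
    probability kinds, raw spread otherwise)."""
    raw = spread_density(atoms, ff.target.grid, replace(ff.params, normalize=False))
    if is_probability_kind(ff.kind):
        total = raw.values.sum()
        if total > 0:
            return raw.like(raw.values / total)
    return raw


def fitting_forces(
    ff: FittingForceField, atoms: AtomSet
) -> tuple[np.ndarray, ScoreValue, float]:
    """Density-guided forces, similarity, and fitting energy.

    Returns ``(F, S, U_fit)`` with ``F`` of shape (n_atoms, 3) equal to
    ``-grad U_fit`` and ``U_fit = -k * S``.
    """
    unnorm = replace(ff.params, normalize=False)
    raw = spread_density(atoms, ff.target.grid, unnorm)
    probability = is_probability_kind(ff.kind)
    if probability:
        total = raw.values.sum()
        model = raw.like(raw.values / total) if total > 0 else raw
    else:
        total = 0.0
        model = raw
    s = score(ff.kind, ff.target, model)
    g = score_derivative(ff.kind, ff.target, model)
    if probability and total > 0:
        # chain rule through p_v = u_v / sum(u): dS/du_v = (g_v - g.p) / sum(u)
        weights = (g - np.sum(g * model.values)) / total
    else:
        weights = g
    grads = spread_gradient(atoms, ff.target.grid, unnorm, weights)
    return ff.k * grads, s, -ff.k * s.S


def apply_multiple_timestep(forces: np.ndarray, n_fit: int) -> np.ndarray:
    """Scale forces by N_fit for application every N_fit-th step only.

    Applying the scaled force once per N_fit steps delivers the same
    impulse as applying the unscaled force every step, approximating the
    same effective Hamiltonian.
    """
    if n_fit < 1:
        raise ValueError("N_fit must be >= 1")
    return np.asarray(forces, dtype=float) * n_fit


def estimate_max_timestep(
    ff: FittingForceField, atoms: AtomSet, atom_index: int = 0, h: float = 1e-3, mass: float = 1.0
) -> float:
    """Advisory estimate of the largest stable integration step.

    Probes the stiffness of the fitting potential numerically around the
    current position of one atom (finite-difference of the force along
    x) and returns the oscillation period of the stiffest direction
    divided by pi. Heuristic only — the true limit depends on the target
    map, the score kind, and the force constant.
    """
    kappa = 0.0
    for axis in range(3):
        plus = AtomSet(atoms.positions.copy(), atoms.amplitudes.copy())
        plus.positions[atom_index, axis] += h
        minus = AtomSet(atoms.positions.copy(), atoms.amplitudes.copy())
        minus.positions[atom_index, axis] -= h
        f_plus, _, _ = fitting_forces(ff, plus)
        f_minus, _, _ = fitting_forces(ff, minus)
        stiff = -(f_plus[atom_index, axis] - f_minus[atom_index, axis]) / (2 * h)
        kappa = max(kappa, abs(stiff))
    if kappa == 0:
        return np.inf
    period = 2.0 * np.pi * np.sqrt(mass / kappa)
    return period / np.pi
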