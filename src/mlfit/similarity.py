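"""Similarity scores between a target density and a model density.

Four scores are implemented, all on a larger-is-better convention with
the fitting potential defined as ``U_fit = -k * S``:

``inner-product``
    ``S = sum_v rho_v * rho^s_v`` — equivalent to a potential
    proportional to the inverted target density.
``cross-correlation``
    cosine similarity ``S = sum(rho * rho^s) / sqrt(sum rho^2 * sum rho^s^2)``
    (no mean subtraction by default).
``relative-entropy``
    the maximum-likelihood score derived from per-voxel Poisson
    scattering statistics: ``S = -KL(rho || rho^s) <= 0`` with equality
    iff the densities agree on the support. Both densities are treated
    as probability distributions (nonnegative, unit sum).
``relative-entropy-swapped``
    the Dirichlet-model score ``S = sum_v rho^s_v * log rho_v`` — an
    inner product in which the target density is replaced by its
    logarithm.

Probability-based scores require the target to be prepared by clipping
negative values and normalizing to unit sum, and the model density to be
the normalized output of the spreading forward model. A positivity floor
``EPS`` keeps logarithms finite where the truncated spreading produces
exact zeros.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import DensityGrid

__all__ = [
    "KINDS",
    "PreparedTarget",
    "ScoreValue",
    "EPS",
    "normalize_kind",
    "is_probability_kind",
    "prepare_target",
    "score",
    "score_derivative",
    "project_normalization",
]

#: positivity floor for log arguments, relative to a unit-sum density
EPS = 1e-12

KINDS = (
    "inner-product",
    "cross-correlation",
    "relative-entropy",
    "relative-entropy-swapped",
)

_ALIASES = {
    "ip": "inner-product",
    "cc": "cross-correlation",
    "re": "relative-entropy",
    "res": "relative-entropy-swapped",
}


def normalize_kind(kind: str) -> str:
    kind = _ALIASES.get(kind, kind)
    if kind not in KINDS:
        raise ValueError(f"unknown similarity kind {kind!r}; expected one of {KINDS} "
                         f"or aliases {sorted(_ALIASES)}")
    return kind


def is_probability_kind(kind: str) -> bool:
    return normalize_kind(kind) in ("relative-entropy", "relative-entropy-swapped")


@dataclass
class PreparedTarget:
    """A target density after score-specific preprocessing.

    For probability kinds the values are nonnegative and sum to one and
    ``support_mask`` marks strictly positive voxels; for the other kinds
    values pass through unchanged and every voxel is in the support.
    """

    grid: DensityGrid
    kind: str
    support_mask: np.ndarray

    @property
    def values(self) -> np.ndarray:
        return self.grid.values


@dataclass
class ScoreValue:
    """Scalar similarity; larger is more similar."""

    S: float
    kind: str


def prepare_target(grid: DensityGrid, kind: str) -> PreparedTarget:
    """Preprocess a raw target map for the given similarity kind.

    Probability kinds: negative voxels are clipped to zero and the map is
    rescaled to unit sum (the free rescaling is justified because cryo-EM
    map values carry an arbitrary scale). Other kinds pass through.
    """
    kind = normalize_kind(kind)
    if is_probability_kind(kind):
        values = np.clip(grid.values, 0.0, None)
        total = values.sum()
        if total <= 0:
            raise ValueError("no positive density: cannot prepare a probability target")
        values = values / total
        return PreparedTarget(grid.like(values), kind, values > 0)
    return PreparedTarget(grid.like(grid.values.copy()), kind, np.ones(grid.shape, bool))


def _check_pair(target: PreparedTarget, model: DensityGrid) -> None:
    if model.shape != target.grid.shape:
        raise ValueError(
            f"model shape {model.shape} != target shape {target.grid.shape}"
        )


def score(kind: str, target: PreparedTarget, model: DensityGrid) -> ScoreValue:
    """Similarity score between a prepared target and a model density."""
    kind = normalize_kind(kind)
    if target.kind != kind:
        raise ValueError(f"target was prepared for kind {target.kind!r}, not {kind!r}")
    _check_pair(target, model)
    rho = target.values
    rs = model.values
    if kind == "inner-product":
        s = float(np.sum(rho * rs))
    elif kind == "cross-correlation":
        denom = np.sqrt(np.sum(rho * rho) * np.sum(rs * rs))
        if denom == 0:
            raise ValueError("cross-correlation undefined for an all-zero map")
        s = float(np.sum(rho * rs) / denom)
    elif kind == "relative-entropy":
        mask = target.support_mask
        s = float(np.sum(rho[mask] * np.log(np.maximum(rs[mask], EPS) / rho[mask])))
    else:  # relative-entropy-swapped
        mask = rs > 0
        s = float(np.sum(rs[mask] * np.log(np.maximum(rho[mask], EPS))))
    return ScoreValue(s, kind)


def score_derivative(kind: str, target: PreparedTarget, model: DensityGrid) -> np.ndarray:
    """Per-voxel derivative dS/d(rho^s_v), holding other voxels fixed.

    This is the raw derivative with respect to the model values as given;
    it does not include the Jacobian of the model's sum-to-one
    normalization (see :func:`project_normalization` and
    :func:`mlfit.forces.fitting_forces`, which propagate it).
    Where the positivity floor binds, the derivative is zero.
    """
    kind = normalize_kind(kind)
    if target.kind != kind:
        raise ValueError(f"target was prepared for kind {target.kind!r}, not {kind!r}")
    _check_pair(target, model)
    rho = target.values
    rs = model.values
    if kind == "inner-product":
        return rho.copy()
    if kind == "cross-correlation":
        b = np.sum(rho * rho)
        c = np.sum(rs * rs)
        if b == 0 or c == 0:
            raise ValueError("cross-correlation undefined for an all-zero map")
        a = np.sum(rho * rs)
        return (rho - (a / c) * rs) / np.sqrt(b * c)
    if kind == "relative-entropy":
        active = target.support_mask & (rs > EPS)
        deriv = np.zeros_like(rs)
        deriv[active] = rho[active] / rs[active]
        return deriv
    # relative-entropy-swapped: d/d(rs_v) [rs_v * log max(rho_v, eps)]
    return np.log(np.maximum(rho, EPS))


def project_normalization(deriv: np.ndarray, model: DensityGrid) -> np.ndarray:
    """Project a raw score derivative onto the tangent of the unit-sum simplex.

    For a model constrained to sum to one, only the component of the
    derivative orthogonal to a uniform rescaling produces force; the
    projected derivative is ``g_v - sum_w g_w * rho^s_w``.
    """
    g = np.asarray(deriv, dtype=float)
    return g - np.sum(g * model.values)
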