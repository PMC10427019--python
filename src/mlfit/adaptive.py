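"""Adaptive force-constant scaling and exerted-work accounting.

The protocol divides the force constant by (1 + alpha) when an
exponential moving average of the similarity increases relative to its
previous value, and multiplies it by (1 + 2*alpha) when the average
decreases; the asymmetric factors enforce a net increase of similarity
over time. The time scale of the coupling is set through
``alpha = N_fit * dt / tau``.

With the similarity S as reaction coordinate the work exerted by the
fitting potential is determined entirely by the force-constant history,

    W_fit = integral k dS  ~=  sum_frames k_frame * (S_frame - S_prev),

so the work of any protocol can be recomputed exactly from its logged
(k, S) trace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ScalingConfig",
    "ScalingState",
    "alpha_from_timescale",
    "update",
    "accumulate_work",
    "should_terminate",
]


@dataclass(frozen=True)
class ScalingConfig:
    """Adaptive-scaling parameters.

    alpha : dimensionless per-update increment (> 0).
    ema_weight : weight of the newest score in the exponential moving
        average (1.0 disables smoothing).
    k_init : initial force constant.
    f_max : refinement terminates when the largest per-atom force
        magnitude exceeds this threshold (integrator-stability proxy).
    """

    alpha: float
    ema_weight: float = 0.1
    k_init: float = 1.0
    f_max: float = math.inf

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not 0 < self.ema_weight <= 1:
            raise ValueError("ema_weight must be in (0, 1]")
        if self.k_init <= 0:
            raise ValueError("k_init must be positive")
        if self.f_max <= 0:
            raise ValueError("f_max must be positive")


@dataclass(frozen=True)
class ScalingState:
    """Running state of the protocol: current k, similarity EMA, the
    previous comparison value, accumulated work, raw last score and an
    update counter."""

    k: float
    ema_S: float | None = None
    prev_ema_S: float | None = None
    W: float = 0.0
    last_S: float | None = None
    frame: int = 0

    @staticmethod
    def initial(config: ScalingConfig) -> "ScalingState":
        return ScalingState(k=config.k_init)


def alpha_from_timescale(n_fit: int, dt: float, tau: float) -> float:
    """alpha = N_fit * dt / tau (dt the smallest integration step, tau the
    coupling time scale; all positive)."""
    if n_fit <= 0 or dt <= 0 or tau <= 0:
        raise ValueError("n_fit, dt and tau must all be positive")
    return n_fit * dt / tau


def update(state: ScalingState, S_new: float, config: ScalingConfig) -> ScalingState:
    """One adaptive update after observing similarity ``S_new``.

    The EMA is advanced, compared against its previous value, and k is
    decreased by 1/(1+alpha) on an increase (ties included: the tie rule
    biases toward gentleness) or increased by (1+2*alpha) on a decrease.
    Work accrues as k * dS with the raw score increments, using the force
    constant in effect while the increment was generated.
    """
    if not math.isfinite(S_new):
        raise FloatingPointError(f"similarity score is not finite: {S_new}")
    w = config.ema_weight
    ema = S_new if state.ema_S is None else (1 - w) * state.ema_S + w * S_new
    dW = 0.0 if state.last_S is None else state.k * (S_new - state.last_S)
    if state.prev_ema_S is None or ema >= state.prev_ema_S:
        k = state.k / (1.0 + config.alpha)
    else:
        k = state.k * (1.0 + 2.0 * config.alpha)
    return ScalingState(
        k=k,
        ema_S=ema,
        prev_ema_S=ema,
        W=state.W + dW,
        last_S=S_new,
        frame=state.frame + 1,
    )


def accumulate_work(k_trace, S_trace) -> float:
    """W = sum over frames of k_frame * (S_frame - S_{frame-1}).

    ``k_trace[i]`` is the force constant in effect while the system moved
    from ``S_trace[i-1]`` to ``S_trace[i]``.
    """
    k = np.asarray(k_trace, dtype=float)
    S = np.asarray(S_trace, dtype=float)
    if k.shape != S.shape:
        raise ValueError(f"trace length mismatch: {k.shape} vs {S.shape}")
    if k.size < 2:
        raise ValueError("traces must have at least two frames")
    return float(np.sum(k[1:] * np.diff(S)))


def should_terminate(max_force: float, config: ScalingConfig) -> bool:
    """True iff the largest force magnitude strictly exceeds f_max."""
    if max_force < 0:
        raise ValueError("max_force must be nonnegative")
    return max_force > config.f_max
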