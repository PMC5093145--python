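"""Leaky integrate-and-fire dynamics for both network layers.

The neuron accumulates non-negative input with exponential leak, fires when
the accumulated value reaches the integration threshold, hard-resets to
zero and then ignores all input for an absolute refractory period.  This
is the simplest LIF form consistent with the three parameters that define
each layer (threshold, leak time constant, refractory period); the leak is
exponential and the reset is to zero, per the standard textbook model.

Layer defaults (arbitrary units of the normalized trace):

========  =========  =========
quantity  layer 1    layer 2
========  =========  =========
i_thres   0.1 a.u.   0.58 a.u.
t_leak    0.2 ms     5.1 ms
t_refrac  4 ms       46.1 ms
========  =========  =========

A clock-driven update at the trace sampling rate (dt = 50 us at 20 kHz) is
the reference implementation; ``lif_spike_steps`` is a compiled kernel with
identical semantics used to run whole input channels quickly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "LIFParams",
    "LIFState",
    "LAYER1_DEFAULTS",
    "LAYER2_DEFAULTS",
    "lif_step",
    "lif_spike_steps",
    "run_lif_channel",
]

# Refractory comparisons use a 1 ns grace so that a step landing exactly at
# the end of the refractory window (up to float rounding in t = k*dt) is
# still treated as refractory; the neuron becomes eligible strictly after.
_T_EPS_S = 1e-9


@dataclass(frozen=True)
class LIFParams:
    """Threshold, leak time constant and absolute refractory period."""

    i_thres: float
    t_leak_s: float
    t_refractory_s: float

    def __post_init__(self) -> None:
        if not self.i_thres > 0:
            raise ConfigurationError("i_thres must be > 0")
        if not self.t_leak_s > 0:
            raise ConfigurationError("t_leak_s must be > 0 (no zero-leak variant)")
        if self.t_refractory_s < 0:
            raise ConfigurationError("t_refractory_s must be >= 0")


LAYER1_DEFAULTS = LIFParams(i_thres=0.1, t_leak_s=0.2e-3, t_refractory_s=4e-3)
LAYER2_DEFAULTS = LIFParams(i_thres=0.58, t_leak_s=5.1e-3, t_refractory_s=46.1e-3)


@dataclass
class LIFState:
    """Mutable integration state of one neuron."""

    integration: float = 0.0
    refractory_until_s: float = -math.inf
    last_spike_s: float | None = None

    def refractory_at(self, t_s: float) -> bool:
        return t_s <= self.refractory_until_s + _T_EPS_S


def lif_step(
    state: LIFState,
    params: LIFParams,
    drive: float,
    t_s: float,
    dt_s: float,
) -> tuple[LIFState, bool]:
    """Advance one neuron by one clock step of ``dt_s`` ending at ``t_s``.

    Outside refractoriness the integration decays by exp(-dt/t_leak) and
    then increases by ``drive``; crossing the threshold fires the neuron,
    resets the integration to zero and starts the refractory period.
    During refractoriness the state is untouched and the neuron cannot
    fire.  Returns the new state and whether a spike occurred.
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be > 0")
    if drive < 0:
        raise ValueError("drive must be non-negative (excitatory synapses only)")
    if state.refractory_at(t_s):
        return LIFState(state.integration, state.refractory_until_s, state.last_spike_s), False
    v = state.integration * math.exp(-dt_s / params.t_leak_s) + drive
    if v >= params.i_thres:
        return (
            LIFState(0.0, t_s + params.t_refractory_s, t_s),
            True,
        )
    return LIFState(v, state.refractory_until_s, state.last_spike_s), False


def _refractory_gap_steps(t_refractory_s: float, dt_s: float) -> int:
    # Steps to skip after a spike: eligible strictly after t_fire + t_refrac,
    # so a refractory period of exactly m*dt blocks m steps (gap m+1).
    return int(math.floor(t_refractory_s / dt_s * (1.0 + 1e-12))) + 1


def _lif_spike_steps_py(
    drive: np.ndarray, decay: float, i_thres: float, refrac_gap: int
) -> np.ndarray:
    out = np.empty(drive.size, dtype=np.int64)
    m = 0
    v = 0.0
    next_ok = 0
    for k in range(drive.size):
        if k < next_ok:
            continue
        v = v * decay + drive[k]
        if v >= i_thres:
            out[m] = k
            m += 1
            v = 0.0
            next_ok = k + refrac_gap
    return out[:m]


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    lif_spike_steps = njit(cache=False)(_lif_spike_steps_py)
except Exception:  # pragma: no cover - numba is normally available
    lif_spike_steps = _lif_spike_steps_py


def run_lif_channel(
    drive: np.ndarray, params: LIFParams, dt_s: float, t0_s: float = 0.0
) -> np.ndarray:
    """Spike times of one neuron driven by a per-step drive array.

    Equivalent to calling :func:`lif_step` at ``t = t0 + (k+1)*dt`` for
    every sample ``k`` starting from a resting state; implemented with the
    compiled kernel.
    """
    drive = np.ascontiguousarray(drive, dtype=np.float64)
    gap = _refractory_gap_steps(params.t_refractory_s, dt_s)
    decay = math.exp(-dt_s / params.t_leak_s)
    steps = lif_spike_steps(drive, decay, params.i_thres, gap)
    return t0_s + (steps + 1) * dt_s
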