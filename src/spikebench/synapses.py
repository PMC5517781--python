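"""Synapse models: delta jumps, single-exponential and double-exponential
conductances.

The double-exponential conductance waveform after a single presynaptic spike
is k * (e^{-t/tau_decay} - e^{-t/tau_rise}); the dimensionless normalizer k
is chosen so the waveform peaks at exactly 1, making the configured g_peak
the true peak conductance of one spike.  Traces a (fast, rise) and b (slow,
decay) are linear ODEs driven by delta events, so between events they are
propagated exactly by exponential decay regardless of the membrane solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "DeltaWeight",
    "DoubleExpParams",
    "DoubleExpState",
    "SingleExpParams",
    "SingleExpState",
    "peak_normalizer",
    "peak_time",
    "synapse_decay",
    "apply_spike",
    "synaptic_current",
]


@dataclass(frozen=True)
class DeltaWeight:
    """Delta (instantaneous-jump) synapse: jump g in mV, axonal delay d in ms.

    The sign of g encodes excitation (positive) or inhibition (negative).
    """

    g: float
    d: float


def peak_time(tau_rise: float, tau_decay: float) -> float:
    """Time of the peak of e^{-t/tau_decay} - e^{-t/tau_rise}, ms."""
    if not 0 < tau_rise < tau_decay:
        raise ValueError(
            f"need 0 < tau_rise < tau_decay, got {tau_rise}, {tau_decay}"
        )
    return (
        tau_rise * tau_decay / (tau_decay - tau_rise)
    ) * math.log(tau_decay / tau_rise)


def peak_normalizer(tau_rise: float, tau_decay: float) -> float:
    """Normalizer k with k * max_t (e^{-t/tau_decay} - e^{-t/tau_rise}) = 1.

    The degenerate alpha-function case tau_rise == tau_decay is rejected.
    """
    t_p = peak_time(tau_rise, tau_decay)
    return 1.0 / (math.exp(-t_p / tau_decay) - math.exp(-t_p / tau_rise))


@dataclass(frozen=True)
class DoubleExpParams:
    """Double-exponential conductance synapse.

    g_peak: peak conductance, nS; e_rev: reversal potential, mV;
    tau_rise/tau_decay: ms; delay: axonal delay, ms.  ``k`` is derived.
    """

    g_peak: float = 2.0
    e_rev: float = -75.0
    tau_rise: float = 0.99
    tau_decay: float = 1.0
    delay: float = 3.0
    k: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "k", peak_normalizer(self.tau_rise, self.tau_decay))


@dataclass(frozen=True)
class DoubleExpState:
    """Fast trace a (decays with tau_rise) and slow trace b (tau_decay)."""

    a: float = 0.0
    b: float = 0.0


@dataclass(frozen=True)
class SingleExpParams:
    g_peak: float = 0.0
    e_rev: float = 0.0
    tau: float = 5.0
    delay: float = 1.0

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError(f"tau must be positive, got {self.tau}")


@dataclass(frozen=True)
class SingleExpState:
    a: float = 0.0


def synapse_decay(state, taus, dt: float):
    """Propagate synapse traces over dt by exact exponential decay.

    ``taus`` is (tau_rise, tau_decay) for a DoubleExpState or a scalar tau
    for a SingleExpState.  Exact for the homogeneous linear dynamics, so two
    dt/2 steps compose to one dt step to machine precision.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if isinstance(state, DoubleExpState):
        tau_rise, tau_decay = taus
        return DoubleExpState(
            a=state.a * math.exp(-dt / tau_rise),
            b=state.b * math.exp(-dt / tau_decay),
        )
    if isinstance(state, SingleExpState):
        return SingleExpState(a=state.a * math.exp(-dt / float(taus)))
    raise TypeError(f"unsupported state type {type(state).__name__}")


def apply_spike(state, increment: float = 1.0):
    """Add a spike event: both traces (or the single trace) jump by
    ``increment``.  Unit increments make g_peak the per-spike peak
    conductance; simultaneous spikes superpose additively.
    """
    if isinstance(state, DoubleExpState):
        return DoubleExpState(a=state.a + increment, b=state.b + increment)
    if isinstance(state, SingleExpState):
        return SingleExpState(a=state.a + increment)
    raise TypeError(f"unsupported state type {type(state).__name__}")


def synaptic_current(state, params, v: float) -> float:
    """Instantaneous synaptic current in pA (nS * mV).

    Double-exp: g_peak * k * (b - a) * (e_rev - v);
    single-exp: g_peak * a * (e_rev - v).
    """
    if isinstance(state, DoubleExpState):
        return params.g_peak * params.k * (state.b - state.a) * (params.e_rev - v)
    if isinstance(state, SingleExpState):
        return params.g_peak * state.a * (params.e_rev - v)
    raise TypeError(f"unsupported state type {type(state).__name__}")
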