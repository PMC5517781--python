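"""Membrane models: leaky integrate-and-fire and classical Hodgkin-Huxley.

Two point-neuron classes are provided.  The LIF neuron obeys

    dv/dt = -v/tau + sum_j g * delta(t - t'_j - d),    v > theta: v -> v_r

with an absolute refractory period, and is advanced with the exact
exponential propagator (the homogeneous equation is linear, so the update
``v <- v * exp(-dt/tau)`` is exact between synaptic events).

The Hodgkin-Huxley neuron carries the four classical state variables
(v, m, h, n) with the modern shifted-voltage convention (rest near -65 mV)
and receives synaptic input as absolute conductances (nS) that are converted
to densities (mS/cm^2) through the membrane area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np

__all__ = [
    "LIFParams",
    "LIFState",
    "lif_step",
    "HHParams",
    "HHState",
    "RateSet",
    "hh_rates",
    "gating_steady_state",
    "hh_steady_state",
    "hh_derivatives",
]

# conductance unit bridge: 1 nS = 1e-6 mS
_NS_TO_MS = 1e-6


@dataclass(frozen=True)
class LIFParams:
    """LIF membrane parameters.

    tau : membrane time constant, ms
    theta : spike threshold, mV
    v_reset : reset potential, mV
    t_ref : absolute refractory period, ms
    """

    tau: float = 10.0
    theta: float = 1.0
    v_reset: float = 0.0
    t_ref: float = 5.01

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if not self.theta > self.v_reset:
            raise ValueError(
                f"theta ({self.theta}) must exceed v_reset ({self.v_reset})"
            )
        if self.t_ref < 0:
            raise ValueError(f"t_ref must be non-negative, got {self.t_ref}")


@dataclass(frozen=True)
class LIFState:
    """Instantaneous LIF state: potential plus refractory bookkeeping."""

    v: float = 0.0
    last_spike: float = -math.inf
    refractory_until: float = -math.inf


def lif_step(
    state: LIFState,
    params: LIFParams,
    dt: float,
    input_jump: float = 0.0,
    t: float = 0.0,
    refractory_mode: str = "clamp",
) -> tuple[LIFState, bool]:
    """Advance one LIF neuron by a single step ending at time ``t``.

    ``input_jump`` is the summed weight (mV) of all delta-synapse events
    delivered at ``t``.  Outside refractoriness the exact propagator is
    applied and the threshold checked; a spike resets ``v`` to ``v_reset``
    and starts the refractory period.

    Refractory semantics (``refractory_mode``):

    - ``"clamp"`` (default): the membrane is held at ``v_reset`` and inputs
      arriving during refractoriness are discarded.
    - ``"integrate"``: the membrane keeps integrating but the threshold is
      disabled until the refractory period expires.

    Expiry is evaluated in continuous time: the neuron becomes eligible at
    the first step whose terminal time is >= ``last_spike + t_ref``.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if refractory_mode not in ("clamp", "integrate"):
        raise ValueError(f"unknown refractory_mode {refractory_mode!r}")

    decay = math.exp(-dt / params.tau)
    refractory = t < state.refractory_until
    if refractory:
        if refractory_mode == "clamp":
            return replace(state, v=params.v_reset), False
        return replace(state, v=state.v * decay + input_jump), False

    v = state.v * decay + input_jump
    if v > params.theta:
        return (
            LIFState(
                v=params.v_reset,
                last_spike=t,
                refractory_until=t + params.t_ref,
            ),
            True,
        )
    return replace(state, v=v), False


# ---------------------------------------------------------------------------
# Hodgkin-Huxley
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HHParams:
    """Classical Hodgkin-Huxley parameters (shifted convention, rest ~ -65 mV).

    Conductances in mS/cm^2, potentials in mV, capacitance in uF/cm^2,
    injected current density in uA/cm^2.  ``area`` (cm^2) converts absolute
    synaptic conductances (nS) into densities; the default 1e-4 cm^2
    corresponds to a 100 pF cell at c = 1 uF/cm^2.
    """

    g_na: float = 120.0
    g_k: float = 36.0
    g_l: float = 0.3
    e_na: float = 50.0
    e_k: float = -77.0
    e_l: float = -54.4
    c: float = 1.0
    i_inj: float = 0.0
    area: float = 1e-4

    def __post_init__(self) -> None:
        if not self.c > 0:
            raise ValueError(f"capacitance must be positive, got {self.c}")
        if not self.area > 0:
            raise ValueError(f"area must be positive, got {self.area}")
        for name in ("g_na", "g_k", "g_l"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class HHState:
    """HH state: membrane potential (mV) and the three gating variables."""

    v: float = -65.0
    m: float = 0.05
    h: float = 0.6
    n: float = 0.32


class RateSet(NamedTuple):
    """The six voltage-dependent channel gating rates, 1/ms."""

    alpha_m: float
    beta_m: float
    alpha_h: float
    beta_h: float
    alpha_n: float
    beta_n: float


class HHDerivatives(NamedTuple):
    dv: float
    dm: float
    dh: float
    dn: float


# Quotient forms 0.1(v+40)/(1-e^{-(v+40)/10}) and 0.01(v+55)/(1-e^{-(v+55)/10})
# have removable singularities; below this margin they are replaced by the
# analytic limit to avoid 0/0.
_SINGULARITY_EPS = 1e-7


def _vtrap(x, scale):
    """x / (1 - exp(-x/scale)) with the removable singularity -> scale."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < _SINGULARITY_EPS
    safe = np.where(small, 1.0, x)
    out = np.where(small, scale, safe / -np.expm1(-safe / scale))
    return out


def hh_rates(v) -> RateSet:
    """Evaluate the six classical HH rate functions at voltage ``v`` (mV).

    Accepts scalars or arrays.  Uses the shifted convention:
    alpha_m = 0.1(v+40)/(1-e^{-(v+40)/10}), beta_m = 4 e^{-(v+65)/18},
    alpha_h = 0.07 e^{-(v+65)/20},          beta_h = 1/(1+e^{-(v+35)/10}),
    alpha_n = 0.01(v+55)/(1-e^{-(v+55)/10}), beta_n = 0.125 e^{-(v+65)/80}.
    """
    v_arr = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v_arr)):
        raise ValueError("membrane potential must be finite")
    alpha_m = 0.1 * _vtrap(v_arr + 40.0, 10.0)
    beta_m = 4.0 * np.exp(-(v_arr + 65.0) / 18.0)
    alpha_h = 0.07 * np.exp(-(v_arr + 65.0) / 20.0)
    beta_h = 1.0 / (1.0 + np.exp(-(v_arr + 35.0) / 10.0))
    alpha_n = 0.01 * _vtrap(v_arr + 55.0, 10.0)
    beta_n = 0.125 * np.exp(-(v_arr + 65.0) / 80.0)
    if np.isscalar(v) or np.ndim(v) == 0:
        return RateSet(
            float(alpha_m), float(beta_m), float(alpha_h),
            float(beta_h), float(alpha_n), float(beta_n),
        )
    return RateSet(alpha_m, beta_m, alpha_h, beta_h, alpha_n, beta_n)


def gating_steady_state(v):
    """Steady-state activations (m_inf, h_inf, n_inf) = alpha/(alpha+beta)."""
    r = hh_rates(v)
    m_inf = r.alpha_m / (r.alpha_m + r.beta_m)
    h_inf = r.alpha_h / (r.alpha_h + r.beta_h)
    n_inf = r.alpha_n / (r.alpha_n + r.beta_n)
    return m_inf, h_inf, n_inf


def hh_steady_state(v: float) -> HHState:
    """HH state with gating equilibrated at the given voltage."""
    m, h, n = gating_steady_state(v)
    return HHState(v=float(v), m=float(m), h=float(h), n=float(n))


def hh_derivatives(
    state: HHState,
    params: HHParams,
    syn: tuple[tuple[float, float], ...] = (),
) -> HHDerivatives:
    """Right-hand side of the HH system.

    ``syn`` is a sequence of ``(g_abs_nS, e_rev_mV)`` pairs giving the
    instantaneous absolute conductance and reversal potential of each
    synaptic channel; conductances are divided by ``params.area`` to obtain
    densities before entering the current balance.
    """
    v, m, h, n = state.v, state.m, state.h, state.n
    i_ion = (
        params.g_na * m**3 * h * (params.e_na - v)
        + params.g_k * n**4 * (params.e_k - v)
        + params.g_l * (params.e_l - v)
        + params.i_inj
    )
    i_syn = 0.0
    for g_abs, e_rev in syn:
        i_syn += (g_abs * _NS_TO_MS / params.area) * (e_rev - v)
    r = hh_rates(v)
    return HHDerivatives(
        dv=(i_ion + i_syn) / params.c,
        dm=r.alpha_m * (1.0 - m) - r.beta_m * m,
        dh=r.alpha_h * (1.0 - h) - r.beta_h * h,
        dn=r.alpha_n * (1.0 - n) - r.beta_n * n,
    )
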