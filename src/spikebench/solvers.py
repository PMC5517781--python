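"""Fixed-step integrators and rate-function lookup tables.

Three update rules cover the benchmark models:

- the exact ("linear") propagator for the LIF membrane, exp(-dt/tau);
- exponential Euler for gating variables, which relaxes each variable
  exactly toward its instantaneous steady state alpha/(alpha+beta);
- the classical 4th-order Runge-Kutta step for the full HH system.

Lookup tables sample a function on a uniform voltage grid; the solver then
linearly interpolates instead of evaluating transcendentals, which is the
standard acceleration for HH rate functions.  ``table_max_relative_error``
quantifies the accuracy of that replacement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import hh_rates

__all__ = [
    "exact_decay",
    "exp_euler_gating_step",
    "rk4_step",
    "LookupTable",
    "build_table",
    "table_lookup",
    "table_max_relative_error",
    "RATE_FUNCTIONS",
    "rate_table_errors",
]


def exact_decay(v, tau: float, dt: float):
    """Exact propagator of dv/dt = -v/tau over one step."""
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    return v * np.exp(-dt / tau)


def exp_euler_gating_step(x, alpha, beta, dt: float):
    """Exponential-Euler update for dx/dt = alpha (1-x) - beta x.

    x' = x_inf + (x - x_inf) e^{-dt (alpha+beta)}, x_inf = alpha/(alpha+beta).
    Where alpha + beta == 0 the variable is returned unchanged (no dynamics).
    Accepts scalars or arrays.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    total = alpha + beta
    safe = np.where(total == 0.0, 1.0, total)
    x_inf = np.where(total == 0.0, 0.0, alpha / safe)
    out = np.where(
        total == 0.0,
        x,
        x_inf + (np.asarray(x, dtype=float) - x_inf) * np.exp(-dt * total),
    )
    if np.ndim(x) == 0 and np.ndim(out) == 0:
        return float(out)
    return out


def rk4_step(f, y, t: float, dt: float):
    """Classical 4th-order Runge-Kutta step for dy/dt = f(t, y).

    ``y`` may be a scalar or ndarray; ``f`` must return the same shape.
    A non-finite value at any stage raises ArithmeticError naming the stage.
    """
    y = np.asarray(y, dtype=float)
    k1 = np.asarray(f(t, y), dtype=float)
    k2 = np.asarray(f(t + 0.5 * dt, y + 0.5 * dt * k1), dtype=float)
    k3 = np.asarray(f(t + 0.5 * dt, y + 0.5 * dt * k2), dtype=float)
    k4 = np.asarray(f(t + dt, y + dt * k3), dtype=float)
    for name, k in (("k1", k1), ("k2", k2), ("k3", k3), ("k4", k4)):
        if not np.all(np.isfinite(k)):
            raise ArithmeticError(f"non-finite derivative at RK4 stage {name}")
    out = y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class LookupTable:
    """Uniform-grid samples of a scalar function of voltage."""

    v_min: float
    v_max: float
    step: float
    samples: np.ndarray

    @property
    def grid(self) -> np.ndarray:
        return self.v_min + self.step * np.arange(len(self.samples))


def build_table(fn, v_min: float, v_max: float, step: float) -> LookupTable:
    """Tabulate ``fn`` on the grid v_min, v_min+step, ..., up to v_max.

    The table holds floor((v_max - v_min)/step) + 1 samples.
    """
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    if v_min >= v_max:
        raise ValueError(f"need v_min < v_max, got {v_min}, {v_max}")
    n = int(np.floor((v_max - v_min) / step + 1e-12)) + 1
    grid = v_min + step * np.arange(n)
    return LookupTable(
        v_min=v_min, v_max=v_max, step=step,
        samples=np.asarray(fn(grid), dtype=float),
    )


def table_lookup(table: LookupTable, v):
    """Linear interpolation between bracketing samples; no extrapolation."""
    v = np.asarray(v, dtype=float)
    top = table.v_min + table.step * (len(table.samples) - 1)
    if np.any(v < table.v_min - 1e-9) or np.any(v > top + 1e-9):
        raise ValueError(
            f"lookup voltage outside table range [{table.v_min}, {top}]"
        )
    out = np.interp(v, table.grid, table.samples)
    if out.ndim == 0:
        return float(out)
    return out


def table_max_relative_error(
    table: LookupTable, fn, n_probes: int = 100_000
) -> float:
    """Max relative error (%) of table interpolation vs direct evaluation.

    Probes uniformly over the tabulated span; requires at least 10 probes
    per sample so interior errors are resolved.  ``fn`` must be strictly
    nonzero on the range, otherwise relative error is undefined.
    """
    if n_probes < 10 * len(table.samples):
        raise ValueError(
            f"n_probes={n_probes} too small for {len(table.samples)} samples"
        )
    top = table.v_min + table.step * (len(table.samples) - 1)
    probes = np.linspace(table.v_min, top, n_probes)
    exact = np.asarray(fn(probes), dtype=float)
    if np.any(exact == 0.0):
        raise ValueError("function vanishes at a probe; relative error undefined")
    approx = np.interp(probes, table.grid, table.samples)
    return float(np.max(np.abs(approx - exact) / np.abs(exact)) * 100.0)


# the six classical rate functions, by name, as scalar/array callables
RATE_FUNCTIONS = {
    "alpha_m": lambda v: hh_rates(v).alpha_m,
    "beta_m": lambda v: hh_rates(v).beta_m,
    "alpha_h": lambda v: hh_rates(v).alpha_h,
    "beta_h": lambda v: hh_rates(v).beta_h,
    "alpha_n": lambda v: hh_rates(v).alpha_n,
    "beta_n": lambda v: hh_rates(v).beta_n,
}


def rate_table_errors(
    step: float,
    v_min: float = -100.0,
    v_max: float = 50.0,
    n_probes: int = 100_000,
) -> dict[str, float]:
    """Max relative interpolation error (%) per rate function at the given
    grid step over [v_min, v_max]."""
    out = {}
    for name, fn in RATE_FUNCTIONS.items():
        table = build_table(fn, v_min, v_max, step)
        out[name] = table_max_relative_error(table, fn, n_probes)
    return out
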