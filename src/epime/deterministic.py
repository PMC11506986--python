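"""Deterministic ODE baselines for SIS and SIR dynamics.

The mean-field equations track population fractions.  For SIS the infected
fraction obeys the logistic equation ``d rho/dt = (beta-gamma) rho -
beta rho^2``, solved in closed form; for ``R0 = beta/gamma > 1`` it
saturates at the endemic value ``1 - 1/R0``.  For SIR the standard system

    ds/dt = -beta s i,   di/dt = beta s i - gamma i,   dr/dt = gamma i

is integrated at high accuracy, and the final epidemic size satisfies the
implicit relation ``rho = 1 - s0 * exp(-R0 rho) - r0``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .state_model import EpidemicParams

__all__ = [
    "DeterministicTrajectory",
    "solve_sis_ode",
    "solve_sir_ode",
    "sir_final_size",
    "peak_time",
]

#: Default grid spacing for stored trajectories; peak times are resolved to
#: this step, tie-break earliest.
GRID_STEP = 0.01


@dataclass(frozen=True)
class DeterministicTrajectory:
    """Compartment fractions on a dense time grid."""

    times: np.ndarray
    s: np.ndarray
    i: np.ndarray
    r: np.ndarray
    params: EpidemicParams

    def value_at(self, t: float) -> tuple[float, float, float]:
        """(s, i, r) at the grid point nearest to ``t``."""
        if t < self.times[0] - GRID_STEP / 2 or t > self.times[-1] + GRID_STEP / 2:
            raise ValueError(f"t={t} outside trajectory span "
                             f"[{self.times[0]}, {self.times[-1]}]")
        k = int(np.argmin(np.abs(self.times - t)))
        return float(self.s[k]), float(self.i[k]), float(self.r[k])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "s": self.s,
                             "i": self.i, "r": self.r})


@dataclass(frozen=True)
class PeakResult:
    """Location of the infected-fraction maximum on the stored grid.

    ``interior`` is False when the maximum sits on the grid boundary (a
    monotone trajectory has no epidemic peak in the usual sense); the time
    and height are still reported.
    """

    t_peak: float
    height: float
    interior: bool


def _default_grid(t_max: float) -> np.ndarray:
    n = int(round(t_max / GRID_STEP))
    return np.linspace(0.0, n * GRID_STEP, n + 1)


def solve_sis_ode(params: EpidemicParams, rho0: float,
                  t_grid: Optional[np.ndarray] = None,
                  t_max: float = 100.0) -> DeterministicTrajectory:
    """Closed-form logistic solution of the SIS infected fraction.

    ``d rho/dt = r rho - beta rho^2`` with growth rate ``r = beta - gamma``:

    * ``beta = 0``: pure exponential decay ``rho0 * exp(-gamma t)``;
    * ``r != 0``: ``rho(t) = r rho0 e^{rt} / (r + beta rho0 (e^{rt} - 1))``;
    * ``r = 0`` (``R0 = 1``): algebraic decay ``rho0 / (1 + beta rho0 t)``.
    """
    if not 0.0 <= rho0 <= 1.0:
        raise ValueError(f"rho0 must lie in [0, 1], got {rho0}")
    t = np.asarray(t_grid, dtype=float) if t_grid is not None else _default_grid(t_max)
    beta, gamma = params.beta, params.gamma
    r = beta - gamma
    if beta == 0.0:
        rho = rho0 * np.exp(-gamma * t)
    elif r > 0.0:
        # growing branch written with exp(-rt) so large horizons don't overflow
        em = np.exp(-r * t)
        rho = r * rho0 / (r * em + beta * rho0 * (1.0 - em))
    elif r < 0.0:
        ep = np.exp(r * t)
        rho = r * rho0 * ep / (r + beta * rho0 * (ep - 1.0))
    else:
        rho = rho0 / (1.0 + beta * rho0 * t)
    rho = np.clip(rho, 0.0, 1.0)
    return DeterministicTrajectory(times=t, s=1.0 - rho, i=rho,
                                   r=np.zeros_like(rho), params=params)


def solve_sir_ode(params: EpidemicParams, s0: float, i0: float, r0: float,
                  t_grid: Optional[np.ndarray] = None,
                  t_max: float = 100.0) -> DeterministicTrajectory:
    """High-accuracy integration of the SIR fractions (rtol 1e-10)."""
    if abs(s0 + i0 + r0 - 1.0) > 1e-12:
        raise ValueError("initial fractions must sum to 1 within 1e-12")
    if min(s0, i0, r0) < 0:
        raise ValueError("initial fractions must be non-negative")
    t = np.asarray(t_grid, dtype=float) if t_grid is not None else _default_grid(t_max)
    beta, gamma = params.beta, params.gamma

    def rhs(_t, y):
        s, i = y
        inc = beta * s * i
        return [-inc, inc - gamma * i]

    sol = solve_ivp(rhs, (t[0], t[-1]), [s0, i0], t_eval=t,
                    method="DOP853", rtol=1e-10, atol=1e-13)
    if not sol.success:
        raise RuntimeError(f"SIR integration failed: {sol.message}")
    s = np.clip(sol.y[0], 0.0, 1.0)
    i = np.clip(sol.y[1], 0.0, 1.0)
    return DeterministicTrajectory(times=t, s=s, i=i, r=1.0 - s - i,
                                   params=params)


def sir_final_size(r0_number: float, s0: float = 1.0,
                   r0_init: float = 0.0) -> float:
    """Attack rate: largest root in [0, 1] of ``rho = 1 - s0 e^{-R0 rho} - r0``.

    Solved by bracketing and bisection on ``[1e-9, 1]`` to 1e-12.  When no
    positive root exists (subcritical ``R0 * s0 <= 1`` with vanishing initial
    infection) the outbreak infects nobody and 0 is returned.
    """
    if not (0.0 <= s0 <= 1.0 and 0.0 <= r0_init <= 1.0 and s0 + r0_init <= 1.0 + 1e-12):
        raise ValueError("require s0, r0_init in [0,1] with s0 + r0_init <= 1")
    if r0_number < 0:
        raise ValueError("r0_number must be >= 0")

    def f(rho: float) -> float:
        return rho - 1.0 + s0 * np.exp(-r0_number * rho) + r0_init

    lo, hi = 1e-9, 1.0
    if f(lo) >= 0.0:
        # no sign change: the only solution is the disease-free rho ~ 0
        return 0.0
    if f(hi) < 0.0:
        raise RuntimeError("final-size bracket [1e-9, 1] has no sign change")
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16))


def peak_time(traj: DeterministicTrajectory) -> PeakResult:
    """Earliest grid time attaining the maximum infected fraction.

    A trajectory whose maximum does not strictly exceed both endpoint values
    (monotone decay, or a rise to a plateau as in supercritical SIS) has no
    epidemic peak and is flagged ``interior=False`` rather than raising.
    """
    k = int(np.argmax(traj.i))
    peak = traj.i[k]
    interior = (0 < k < len(traj.times) - 1
                and peak > traj.i[0] + 1e-12 and peak > traj.i[-1] + 1e-12)
    return PeakResult(t_peak=float(traj.times[k]), height=float(traj.i[k]),
                      interior=interior)
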