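"""Forecast-uncertainty experiment: entropy of the peak as forecasts near it.

A deterministic SIR trajectory plays the role of the observed course of an
outbreak.  Conditioning the master equation on the trajectory's state at time
``t0`` — collapsing the probabilistic state to the single configuration
nearest the observed fractions — and propagating forward yields the full
ensemble of futures consistent with that observation.  The Shannon entropy of
the infected marginal at the reference epidemic peak, ``H_inf(t_peak)``,
measures how uncertain a forecast of the peak made at ``t0`` necessarily is.
Times are compared across scenarios through relative offsets
``dt0_rel = (t0 - t_peak)/t_peak`` in [-1, 0] and
``dthmax_rel = (t_Hmax - t_peak)/t_peak``, where ``t_Hmax`` locates the
maximum entropy along the propagated trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .deterministic import (DeterministicTrajectory, peak_time, solve_sir_ode)
from .observables import entropy, marginal_infected
from .propagation import (ProbabilityVector, PropagationConfig,
                          StepOperator, delta_state)
from .state_model import (EpidemicParams, Model, StateSpace, build_generator,
                          build_state_space)

__all__ = [
    "ForecastConfig",
    "ForecastResult",
    "condition_on_trajectory",
    "peak_entropy",
    "relative_times",
    "run_forecast_study",
]


@dataclass(frozen=True)
class ForecastConfig:
    """Study settings: pathogens, population, conditioning grid.

    ``rel_t0_grid`` holds conditioning times as relative offsets in [-1, 0]
    (−1 is the outbreak start, 0 the epidemic peak).  The defaults — R0 in
    {2, 4, 6}, N=100, a 21-point grid — are a desk-scale study resolving the
    full qualitative structure of the entropy curves.
    """

    r0_list: tuple = (2.0, 4.0, 6.0)
    N: int = 100
    gamma: float = 0.1
    dt: float = 0.1
    rel_t0_grid: tuple = tuple(np.round(np.linspace(-1.0, 0.0, 21), 10))
    i0: int = 1
    keep_entropy_series: bool = False

    def __post_init__(self) -> None:
        if self.N < 10:
            raise ValueError("N must be >= 10")
        if any(not -1.0 <= x <= 0.0 for x in self.rel_t0_grid):
            raise ValueError("relative conditioning times must lie in [-1, 0]")


@dataclass
class ForecastResult:
    """Per-(R0, t0) peak entropies and maximum-entropy offsets.

    ``table`` columns: r0, rel_t0, t0, t_peak, peak_entropy, t_hmax,
    rel_t_hmax.  ``entropy_series`` (optional) maps (r0, rel_t0) to a
    DataFrame (time, entropy).
    """

    table: pd.DataFrame
    entropy_series: dict = field(default_factory=dict)


def condition_on_trajectory(traj: DeterministicTrajectory, t0: float,
                            space: StateSpace) -> ProbabilityVector:
    """Collapse the state onto the configuration observed at ``t0``.

    Reads ``(s(t0), i(t0))`` from the reference trajectory, rounds each
    fraction times N to the nearest integer, repairs ``S + I > N`` overflows
    by decrementing S first (then I), and returns the point mass on that
    basis configuration — the measurement analogy: observing the outbreak
    leaves the system in a definite configuration.
    """
    if space.model is not Model.SIR:
        raise ValueError("conditioning is defined on the SIR state space")
    s_frac, i_frac, _ = traj.value_at(t0)
    n = space.N
    s = int(round(s_frac * n))
    i = int(round(i_frac * n))
    while s + i > n and s > 0:
        s -= 1
    while s + i > n and i > 0:
        i -= 1
    pv = delta_state(space, (s, i))
    return pv.at_time(t0)


def relative_times(t0: float, t_peak: float,
                   t_hmax: float) -> tuple[float, float]:
    """Offsets of conditioning and maximum-entropy times relative to the peak."""
    if t_peak <= 0:
        raise ValueError("t_peak must be > 0")
    return (t0 - t_peak) / t_peak, (t_hmax - t_peak) / t_peak


def _entropy_series(params: EpidemicParams, space: StateSpace, op: StepOperator,
                    p0: ProbabilityVector, n_steps: int) -> tuple[np.ndarray, np.ndarray]:
    """Propagate ``p0`` for ``n_steps`` recording the infected-marginal entropy."""
    times = np.empty(n_steps + 1)
    ents = np.empty(n_steps + 1)
    current = p0
    times[0] = current.time
    ents[0] = entropy(marginal_infected(current, space))
    for k in range(1, n_steps + 1):
        current = op.apply(current)
        times[k] = current.time
        ents[k] = entropy(marginal_infected(current, space))
    return times, ents


def peak_entropy(params: EpidemicParams, traj: DeterministicTrajectory,
                 t0: float, space: StateSpace,
                 config: Optional[PropagationConfig] = None) -> float:
    """Entropy of the infected marginal at the reference peak, forecast from t0.

    Conditions the state on the trajectory at ``t0``, propagates to the
    deterministic ``t_peak`` and applies the Shannon entropy to the infected
    marginal.  ``t0 = t_peak`` needs no propagation and returns 0 exactly
    (a point mass has zero entropy).
    """
    dt = config.dt if config is not None else 0.1
    pk = peak_time(traj)
    if t0 > pk.t_peak:
        raise ValueError("conditioning time must not exceed the peak time")
    p0 = condition_on_trajectory(traj, t0, space)
    n_steps = int(round((pk.t_peak - t0) / dt))
    if n_steps == 0:
        return 0.0
    gen = build_generator(
        EpidemicParams(params.beta, params.gamma, params.N, Model.SIR), space)
    op = StepOperator(gen, dt)
    current = p0
    for _ in range(n_steps):
        current = op.apply(current)
    return entropy(marginal_infected(current, space))


def run_forecast_study(config: ForecastConfig) -> ForecastResult:
    """Full conditioning study across ``r0_list`` and the relative-time grid.

    For each R0 a reference SIR trajectory is integrated (``i0/N`` initially
    infected, recovery rate ``gamma``, ``beta = gamma * R0``).  For each
    conditioning offset the state is collapsed onto the trajectory,
    propagated over ``[t0, 2*t_peak]``, and the entropy of the infected
    marginal recorded at every step; the peak entropy and the location of
    the entropy maximum (earliest argmax on the step grid) are tabulated.
    Pathogens with ``R0 <= 1`` have no epidemic peak and are flagged by a
    row of NaNs.
    """
    rows = []
    series: dict = {}
    for r0 in config.r0_list:
        params = EpidemicParams.from_r0(r0, gamma=config.gamma, N=config.N,
                                        model=Model.SIR)
        if r0 <= 1.0:
            for rel_t0 in config.rel_t0_grid:
                rows.append({"r0": r0, "rel_t0": rel_t0, "t0": np.nan,
                             "t_peak": np.nan, "peak_entropy": np.nan,
                             "t_hmax": np.nan, "rel_t_hmax": np.nan})
            continue
        i0_frac = config.i0 / config.N
        # horizon generous enough to contain the peak for slow-growing R0
        horizon = 60.0 / (params.beta - params.gamma) + 20.0
        traj = solve_sir_ode(params, 1.0 - i0_frac, i0_frac, 0.0,
                             t_max=horizon)
        pk = peak_time(traj)
        if not pk.interior:
            raise RuntimeError(f"no interior epidemic peak found for R0={r0}")
        space = build_state_space(params)
        gen = build_generator(params, space)
        op = StepOperator(gen, config.dt)
        for rel_t0 in config.rel_t0_grid:
            t0 = pk.t_peak * (1.0 + rel_t0)
            p0 = condition_on_trajectory(traj, t0, space)
            n_steps = int(round((2.0 * pk.t_peak - t0) / config.dt))
            times, ents = _entropy_series(params, space, op, p0, n_steps)
            k_peak = int(round((pk.t_peak - t0) / config.dt))
            h_peak = 0.0 if k_peak == 0 else float(ents[k_peak])
            k_max = int(np.argmax(ents))          # earliest on ties
            t_hmax = float(times[k_max])
            _, rel_hmax = relative_times(t0, pk.t_peak, t_hmax)
            rows.append({"r0": r0, "rel_t0": rel_t0, "t0": t0,
                         "t_peak": pk.t_peak, "peak_entropy": h_peak,
                         "t_hmax": t_hmax, "rel_t_hmax": rel_hmax})
            if config.keep_entropy_series:
                series[(r0, rel_t0)] = pd.DataFrame(
                    {"time": times, "entropy": ents})
    return ForecastResult(table=pd.DataFrame(rows), entropy_series=series)
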