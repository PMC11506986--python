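"""Marginals, entropies, order parameters and no-outbreak mass.

The full master-equation state over SIR configurations carries more detail
than most epidemiological questions need; the quantities of interest are the
marginal distributions of single compartments, ``P(I) = sum_S P(S, I)`` and
``P(R) = sum_{S+I=N-R} P(S, I)``, their Shannon entropy ``H = -sum P log P``
(the forecast-uncertainty measure used throughout), and integrals of the
recovered marginal over the low-attack-rate region, which quantify the
probability that the outbreak dies out before spreading.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .propagation import (ProbabilityVector, PropagationConfig,
                          delta_state, evolve)
from .state_model import (EpidemicParams, Model, StateSpace,
                          build_generator, build_state_space)

__all__ = [
    "MarginalDistribution",
    "marginal_infected",
    "marginal_recovered",
    "entropy",
    "expected_fraction",
    "no_outbreak_mass",
    "order_parameter_cloud",
    "OrderParameterCloud",
]


@dataclass(frozen=True)
class MarginalDistribution:
    """Distribution of a single compartment's occupation number 0..N."""

    compartment: str            # "I" or "R"
    probabilities: np.ndarray   # indexed by occupation number
    time: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "probabilities",
                           np.asarray(self.probabilities, dtype=float))

    @property
    def support(self) -> np.ndarray:
        return np.arange(len(self.probabilities))

    @property
    def n(self) -> int:
        return len(self.probabilities) - 1

    def mean(self) -> float:
        return float(self.support @ self.probabilities)

    def variance(self) -> float:
        m = self.mean()
        return float((self.support - m) ** 2 @ self.probabilities)


def _check_alignment(p: ProbabilityVector, space: StateSpace) -> None:
    if p.p.shape != (space.size,):
        raise ValueError(
            f"vector of length {p.p.shape[0]} does not match state space "
            f"of size {space.size}"
        )


def marginal_infected(p: ProbabilityVector,
                      space: StateSpace) -> MarginalDistribution:
    """``P(I)``: sum the state over ``S`` at fixed infected count.

    SIS states already are the infected counts, so the vector passes through.
    """
    _check_alignment(p, space)
    if space.model is Model.SIS:
        probs = p.p.copy()
    else:
        probs = np.bincount(space.infected_counts(), weights=p.p,
                            minlength=space.N + 1)
    return MarginalDistribution("I", probs, time=p.time)


def marginal_recovered(p: ProbabilityVector,
                       space: StateSpace) -> MarginalDistribution:
    """``P(R)``: sum over the anti-diagonal ``S + I = N - R``."""
    _check_alignment(p, space)
    if space.model is Model.SIS:
        raise ValueError("SIS has no recovered compartment")
    probs = np.bincount(space.recovered_counts(), weights=p.p,
                        minlength=space.N + 1)
    return MarginalDistribution("R", probs, time=p.time)


def entropy(dist: MarginalDistribution, log_base: Optional[float] = None) -> float:
    """Shannon entropy ``-sum P log P`` with the ``0 log 0 = 0`` convention.

    Natural log by default; pass ``log_base`` to change units.
    """
    p = dist.probabilities
    nz = p[p > 0.0]
    h = float(-(nz * np.log(nz)).sum())
    if log_base is not None:
        h /= math.log(log_base)
    return 0.0 if h <= 0.0 else h      # clamp roundoff, avoid -0.0


def expected_fraction(dist: MarginalDistribution, N: Optional[int] = None) -> float:
    """Mean occupation as a fraction of the population."""
    n = dist.n if N is None else N
    return dist.mean() / n


def no_outbreak_mass(recovered_marginal: MarginalDistribution,
                     upper_bound: float) -> float:
    """Probability mass of the recovered marginal at or below ``upper_bound``.

    With the marginal taken at (near-)steady state this is the probability
    that the outbreak ended as a minor one (attack rate within the bound).
    """
    if upper_bound < 0:
        raise ValueError("upper_bound must be >= 0")
    k = int(math.floor(upper_bound))
    return float(recovered_marginal.probabilities[: k + 1].sum())


@dataclass
class OrderParameterCloud:
    """Order-parameter marginals and entropies across a grid of R0 values.

    ``cloud`` has one row per (R0, occupation value): columns
    ``(r0, value, rho, probability)``.  ``entropies`` has one row per R0:
    columns ``(r0, entropy)``.
    """

    model: Model
    cloud: pd.DataFrame
    entropies: pd.DataFrame


def order_parameter_cloud(
    r0_grid: Sequence[float],
    N: int,
    i0: int = 1,
    *,
    model: Model = Model.SIS,
    gamma: float = 0.1,
    measure_time: float = 1000.0,
    dt: float = 0.1,
    log_base: Optional[float] = None,
) -> OrderParameterCloud:
    """Marginal of the order parameter as a function of R0.

    For SIS the order parameter is the prevalence in the long-lived
    metastable state, measured as the infected marginal at ``measure_time``
    (default t=1000: late enough for the metastable structure, before full
    absorption at moderate N).  For SIR it is the attack rate, measured as
    the recovered marginal once the state is stationary (the propagation
    stops early on stationarity, with ``measure_time`` as the horizon).
    The recovery rate is held fixed and ``beta = gamma * R0`` varies.
    """
    cloud_rows = []
    ent_rows = []
    for r0 in r0_grid:
        params = EpidemicParams.from_r0(r0, gamma=gamma, N=N, model=model)
        space = build_state_space(params)
        gen = build_generator(params, space)
        if model is Model.SIS:
            p0 = delta_state(space, i0)
        else:
            p0 = delta_state(space, (N - i0, i0))
        config = PropagationConfig(dt=dt, t_max=measure_time,
                                   record_stride=max(1, int(round(1.0 / dt))))
        series = evolve(gen, p0, config,
                        stop_when_steady=(model is Model.SIR))
        final = series.final
        marg = (marginal_infected(final, space) if model is Model.SIS
                else marginal_recovered(final, space))
        h = entropy(marg, log_base=log_base)
        ent_rows.append({"r0": r0, "entropy": h})
        for value, prob in zip(marg.support, marg.probabilities):
            cloud_rows.append({"r0": r0, "value": int(value),
                               "rho": value / N, "probability": prob})
    return OrderParameterCloud(model=model,
                               cloud=pd.DataFrame(cloud_rows),
                               entropies=pd.DataFrame(ent_rows))
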