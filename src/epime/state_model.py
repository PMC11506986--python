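"""State spaces and transition-rate generators for stochastic SIS/SIR dynamics.

A closed, well-mixed population of ``N`` individuals moves between disease
compartments through two elementary reactions: contagion (a susceptible meets
an infectious individual and becomes infectious at rate ``beta*S*I/N``) and
recovery (each infectious individual recovers at rate ``gamma``).  Treating
every population configuration as a basis state, the stochastic dynamics is a
continuous-time Markov chain whose probability vector obeys the master
equation ``dP/dt = H @ P``, with ``H`` the transition-rate generator built
here.  The generator is the matrix representation of the second-quantised
(Doi-Peliti) Hamiltonian of the process: its off-diagonal element ``(x', x)``
is the rate of the single reaction taking configuration ``x`` to ``x'``, and
each diagonal element closes its column to zero so probability is conserved.

For SIS the configuration is fully described by the infected count ``I``
(``S = N - I``); for SIR by the pair ``(S, I)`` with the recovered count
implicit as ``R = N - S - I``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmwrite

__all__ = [
    "Model",
    "EpidemicParams",
    "StateSpace",
    "Generator",
    "build_state_space",
    "build_generator",
    "MAX_STATES_DEFAULT",
]

#: Guard on the state-space dimension: the SIR basis grows as (N+1)(N+2)/2
#: and generator/propagator memory becomes the binding constraint well before
#: arithmetic does.  2e5 states keeps dense intermediates under ~1 GiB.
MAX_STATES_DEFAULT = 200_000

Label = Union[int, tuple]


class Model(str, enum.Enum):
    """Compartmental model tag."""

    SIS = "SIS"
    SIR = "SIR"


@dataclass(frozen=True)
class EpidemicParams:
    """Epidemiological rates and population size.

    Parameters
    ----------
    beta:
        Contagion rate per unit time (per infectious contact), ``>= 0``.
    gamma:
        Recovery rate per unit time, ``> 0``.
    N:
        Population size, integer ``>= 1``.
    model:
        :class:`Model` tag (``SIS`` or ``SIR``).
    """

    beta: float
    gamma: float
    N: int
    model: Model = Model.SIS

    def __post_init__(self) -> None:
        if not np.isfinite(self.beta) or self.beta < 0:
            raise ValueError(f"beta must be finite and >= 0, got {self.beta}")
        if not np.isfinite(self.gamma) or self.gamma <= 0:
            raise ValueError(f"gamma must be finite and > 0, got {self.gamma}")
        if int(self.N) != self.N or self.N < 1:
            raise ValueError(f"N must be an integer >= 1, got {self.N}")
        object.__setattr__(self, "N", int(self.N))
        object.__setattr__(self, "model", Model(self.model))

    @property
    def r0(self) -> float:
        """Basic reproduction number ``beta / gamma``."""
        return self.beta / self.gamma

    @classmethod
    def from_r0(cls, r0: float, gamma: float, N: int,
                model: Model = Model.SIS) -> "EpidemicParams":
        """Build parameters from ``R0`` with ``beta = r0 * gamma``."""
        return cls(beta=r0 * gamma, gamma=gamma, N=N, model=model)


@dataclass(frozen=True)
class StateSpace:
    """Ordered enumeration of the configuration basis with bijective indexing.

    SIS labels are infected counts ``I`` in ``0..N`` (index equals ``I``).
    SIR labels are pairs ``(S, I)`` ordered lexicographically descending in
    ``S`` then ascending in ``I``; the linear index has the closed form
    ``idx(S, I) = (N-S)(N-S+1)/2 + I``.  The ordering is frozen so tabulated
    output is reproducible across runs.
    """

    model: Model
    N: int
    labels: tuple = field(repr=False)

    @property
    def size(self) -> int:
        return len(self.labels)

    def index_of(self, label: Label) -> int:
        """Linear index of a basis label (O(1), closed form)."""
        if self.model is Model.SIS:
            i = int(label)
            if not 0 <= i <= self.N:
                raise KeyError(f"SIS label I={label} outside 0..{self.N}")
            return i
        s, i = (int(label[0]), int(label[1]))
        if s < 0 or i < 0 or s + i > self.N:
            raise KeyError(f"SIR label (S,I)={label} violates S,I>=0, S+I<=N")
        k = self.N - s
        return k * (k + 1) // 2 + i

    def label_of(self, index: int) -> Label:
        if not 0 <= index < self.size:
            raise KeyError(f"index {index} outside 0..{self.size - 1}")
        return self.labels[index]

    def infected_counts(self) -> np.ndarray:
        """Infected count ``I`` for every basis state, in index order."""
        if self.model is Model.SIS:
            return np.arange(self.N + 1)
        return np.array([i for (_, i) in self.labels])

    def susceptible_counts(self) -> np.ndarray:
        if self.model is Model.SIS:
            return self.N - np.arange(self.N + 1)
        return np.array([s for (s, _) in self.labels])

    def recovered_counts(self) -> np.ndarray:
        """Recovered count ``R = N - S - I`` (identically 0 for SIS)."""
        return self.N - self.susceptible_counts() - self.infected_counts()

    def to_frame(self) -> pd.DataFrame:
        """Label table with columns (index, S, I, R)."""
        return pd.DataFrame(
            {
                "index": np.arange(self.size),
                "S": self.susceptible_counts(),
                "I": self.infected_counts(),
                "R": self.recovered_counts(),
            }
        )

    def to_csv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, index=False)


def build_state_space(params: EpidemicParams,
                      max_states: int = MAX_STATES_DEFAULT) -> StateSpace:
    """Enumerate the complete configuration basis for ``params``.

    Raises
    ------
    ValueError
        If the state-space dimension would exceed ``max_states``.
    """
    n = params.N
    if params.model is Model.SIS:
        dim = n + 1
        labels = tuple(range(dim))
    else:
        dim = (n + 1) * (n + 2) // 2
        if dim > max_states:
            raise ValueError(
                f"SIR state space for N={n} has {dim} states, exceeding the "
                f"guard of {max_states}; raise max_states explicitly if the "
                "memory cost is acceptable"
            )
        labels = tuple((s, i) for s in range(n, -1, -1) for i in range(n - s + 1))
    if dim > max_states:
        raise ValueError(f"state space of {dim} states exceeds guard {max_states}")
    return StateSpace(model=params.model, N=n, labels=labels)


@dataclass(frozen=True)
class Generator:
    """Sparse transition-rate matrix of the master equation ``dP/dt = H P``.

    Entry ``(x', x)`` with ``x' != x`` is the rate from configuration ``x``
    (column) to configuration ``x'`` (row); the diagonal holds minus the total
    outflow rate, so every column sums to zero and total probability is
    conserved.  Columns of absorbing configurations (``I = 0``) are
    identically zero.
    """

    matrix: sparse.csc_array
    space: StateSpace

    @property
    def dim(self) -> int:
        return self.matrix.shape[0]

    def rate(self, source: Label, target: Label) -> float:
        """Transition rate from ``source`` to ``target`` (0 if not allowed)."""
        i = self.space.index_of(target)
        j = self.space.index_of(source)
        return float(self.matrix[i, j])

    def column_sums(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=0)).ravel()

    def to_mtx(self, path: Union[str, Path]) -> None:
        """Export in Matrix Market sparse coordinate format."""
        mmwrite(str(path), sparse.coo_array(self.matrix))


def _sis_generator(params: EpidemicParams, space: StateSpace) -> sparse.csc_array:
    n = params.N
    i_vals = np.arange(n + 1, dtype=float)
    up = params.beta * i_vals * (n - i_vals) / n     # I -> I+1
    down = params.gamma * i_vals                      # I -> I-1
    diag = -(up + down)
    h = sparse.diags_array(
        [down[1:], diag, up[:-1]], offsets=[1, 0, -1], format="csc"
    )
    # offsets: row I receives rate up[I-1] from column I-1 (sub-diagonal)
    # and rate down[I+1] from column I+1 (super-diagonal).
    return h


def _sir_generator(params: EpidemicParams, space: StateSpace) -> sparse.csc_array:
    n = params.N
    s = space.susceptible_counts().astype(float)
    i = space.infected_counts().astype(float)
    idx = np.arange(space.size)

    k = (n - s).astype(int)
    def index_of(sv: np.ndarray, iv: np.ndarray) -> np.ndarray:
        kk = n - sv.astype(int)
        return kk * (kk + 1) // 2 + iv.astype(int)

    rows, cols, vals = [], [], []

    cont = params.beta * s * i / n                    # (S,I) -> (S-1,I+1)
    m = cont > 0
    rows.append(index_of(s[m] - 1, i[m] + 1))
    cols.append(idx[m])
    vals.append(cont[m])

    rec = params.gamma * i                            # (S,I) -> (S,I-1)
    m = rec > 0
    rows.append(index_of(s[m], i[m] - 1))
    cols.append(idx[m])
    vals.append(rec[m])

    rows.append(idx)
    cols.append(idx)
    vals.append(-(cont + rec))

    h = sparse.coo_array(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(space.size, space.size),
    )
    return h.tocsc()


def build_generator(params: EpidemicParams, space: StateSpace) -> Generator:
    """Build the master-equation generator for ``params`` on ``space``.

    SIS rates: ``I -> I+1`` at ``beta*I*(N-I)/N`` and ``I -> I-1`` at
    ``gamma*I``.  SIR rates: ``(S,I) -> (S-1,I+1)`` at ``beta*S*I/N`` and
    ``(S,I) -> (S,I-1)`` at ``gamma*I``.  The frequency-dependent contact
    form ``beta*S*I/N`` is used throughout.
    """
    if space.model is not params.model or space.N != params.N:
        raise ValueError(
            f"state space ({space.model.value}, N={space.N}) does not match "
            f"params ({params.model.value}, N={params.N})"
        )
    if params.model is Model.SIS:
        h = _sis_generator(params, space)
    else:
        h = _sir_generator(params, space)
    return Generator(matrix=h, space=space)
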