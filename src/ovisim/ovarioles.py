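"""Bank of ovarioles: where egg-laying becomes stochastic.

The fly carries ``J`` identical ovarioles, each holding at most ``M``
simultaneously maturing oocytes.  Yolk emitted by the protein pipeline fills
the ovarioles in turn (round-robin, full portions first); every loaded portion
draws an independent integer maturation time xi, uniform on ``[p+1, p+q]``,
and the whole portion is laid on its due day.  Randomness enters the model
here and only here: with ``q = 1`` the simulated pattern is deterministic,
with ``q >= 2`` the day-to-day "tooth-like" variation of real oviposition
records appears.  Ovarioles do not age: nothing in this module depends on the
oxidative-vulnerability coefficients or on absolute time beyond due dates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class OvarioleParams:
    """``J`` ovarioles, ``M`` oocytes max per ovariole, maturation time
    uniform on the integers ``[p+1, p+q]`` (offset ``p`` days, spread ``q``)."""

    J: int
    M: int
    p: int = 0
    q: int = 4

    def validate(self) -> list[str]:
        errors = []
        if self.J < 1:
            errors.append(f"ovarioles.J must be >= 1 (got {self.J})")
        if self.M < 1:
            errors.append(f"ovarioles.M must be >= 1 (got {self.M})")
        if self.p < 0:
            errors.append(f"ovarioles.p must be >= 0 (got {self.p})")
        if self.q < 1:
            errors.append(f"ovarioles.q must be >= 1 (got {self.q})")
        return errors


@dataclass
class Portion:
    """A batch of oocytes maturing together in one ovariole."""

    ovariole_id: int
    size: int
    due_day: int


@dataclass
class OvarioleBankState:
    """Current contents of the ovariole bank.

    ``x_ov[j]`` is the egg load of ovariole *j* (the sizes of its outstanding
    portions sum to it); ``ready_buffer`` holds emitted yolk not yet loadable
    (including sub-egg remainders); ``rr_pointer`` is the round-robin cursor,
    persisting across days so loading stays fair under scarcity.
    """

    portions: list[Portion] = field(default_factory=list)
    x_ov: list[int] = field(default_factory=list)
    ready_buffer: float = 0.0
    cum_laid: int = 0
    cum_loaded: int = 0
    rr_pointer: int = 0

    @classmethod
    def empty(cls, params: OvarioleParams) -> "OvarioleBankState":
        return cls(x_ov=[0] * params.J)


def draw_maturation_time(rng: np.random.Generator, params: OvarioleParams) -> int:
    """One draw of xi: integer uniform on ``[p+1, p+q]``, probability 1/q each."""
    if params.q < 1:
        raise ValueError(f"maturation spread q must be >= 1 (got {params.q})")
    return int(rng.integers(params.p + 1, params.p + params.q + 1))


def lay_eggs(state: OvarioleBankState, k: int) -> tuple[OvarioleBankState, int]:
    """Lay every portion due on or before day *k*; return the day's egg count.

    Portions are laid whole — this is the unit of maturation and the source of
    the lumpy day-to-day egg counts.  ``0 <= s_k <= J*M`` always.
    """
    due = [p for p in state.portions if p.due_day <= k]
    s_k = 0
    for portion in due:
        state.x_ov[portion.ovariole_id] -= portion.size
        s_k += portion.size
    state.portions = [p for p in state.portions if p.due_day > k]
    state.cum_laid += s_k
    assert all(load >= 0 for load in state.x_ov)
    return state, s_k


def load_ovarioles(
    state: OvarioleBankState,
    y_k: float,
    params: OvarioleParams,
    rng: np.random.Generator,
    k: int,
) -> OvarioleBankState:
    """Add the day's yolk to the buffer and load portions round-robin.

    Ovarioles are visited in a fixed circular order starting where the
    previous day stopped; each with free space receives a portion of
    ``min(free space, floor(buffer))`` whole eggs (so abundant yolk fills
    ovarioles completely with portions of exactly ``M``).  Each portion draws
    its own maturation time.  Loading stops when the buffer holds less than
    one egg-equivalent or no free space remains; fractions carry over.
    """
    if y_k < 0:
        raise ValueError(f"yolk emission cannot be negative (got {y_k})")
    state.ready_buffer += y_k
    J = params.J
    last_loaded = None
    for step in range(J):
        if state.ready_buffer < 1.0:
            break
        j = (state.rr_pointer + step) % J
        free = params.M - state.x_ov[j]
        if free <= 0:
            continue
        size = min(free, int(math.floor(state.ready_buffer)))
        if size < 1:
            break
        xi = draw_maturation_time(rng, params)
        state.portions.append(Portion(ovariole_id=j, size=size, due_day=k + xi))
        state.x_ov[j] += size
        state.ready_buffer -= size
        state.cum_loaded += size
        last_loaded = j
    if last_loaded is not None:
        state.rr_pointer = (last_loaded + 1) % J
    return state
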