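"""Dietary-protein → yolk-protein processing pipeline.

Dietary protein arrives at a constant rate ``a`` (measured in egg-equivalents:
one unit is the protein needed to provision one egg) and pools in the body as
raw protein ``x``.  Each day an amount ``n(k)`` is admitted into a processing
system of capacity ``L``; the admitted protein matures into yolk during the
day and is handed to the ovarioles the next day, so the daily yolk emission is
``y(k) = n(k-1)``.  Processing machinery stays occupied for two days per
admission, so the occupancy variable obeys

    x_y(k) = x_y(k-1) + n(k) - n(k-2)  =  n(k) + n(k-1),

and the admission rule keeps ``x_y(k) <= N(k)``:

    n(k) = max(0, min(x(k-1) + a,  N(k) - [x_y(k-1) - n(k-2)])).

The two-day occupancy is what caps steady throughput at ``L/2`` and hence the
plateau laying rate at ``RC = min(L/2, a)``; for ``a > L/2`` the admission rule
produces period-2 forced oscillations, a regime this model excludes at
validation.

After senescence onset ``T`` the capacity itself ages with oxidative
vulnerability ``beta2``: ``N(k) = L * exp(-beta2 * W)`` where ``W`` is the
trailing-window sum of daily energy expenditure ``P2`` over the last ``T``
days (the discrete rendering of an integral from ``k-T`` to ``k``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence


@dataclass(frozen=True)
class ProteinParams:
    """Parameters of the protein-processing subsystem.

    ``a``: daily dietary protein intake (egg-equivalents/day);
    ``L``: processing capacity (egg-equivalents);
    ``beta2``: oxidative vulnerability of the processing system (1/energy),
    expected to exceed ``beta1`` of the energy system;
    ``x0``: raw protein present at hatching (egg-equivalents).
    """

    a: float
    L: float
    beta2: float = 0.0
    x0: float = 0.0

    def validate(self) -> list[str]:
        errors = []
        if self.a < 0:
            errors.append(f"protein.a must be >= 0 (got {self.a})")
        if not self.L > 0:
            errors.append(f"protein.L must be > 0 (got {self.L})")
        if self.beta2 < 0:
            errors.append(f"protein.beta2 must be >= 0 (got {self.beta2})")
        if self.x0 < 0:
            errors.append(f"protein.x0 must be >= 0 (got {self.x0})")
        if self.L > 0 and self.a > self.L / 2:
            errors.append(
                f"protein.a must not exceed L/2 (got a={self.a}, L/2={self.L / 2}): "
                "the a > L/2 regime drives forced period-2 oscillations of the "
                "pipeline and is outside this model"
            )
        return errors


@dataclass
class ProteinState:
    """Pipeline state at the end of a day.

    ``x`` raw protein; ``xy`` capacity occupancy (= ``n(k) + n(k-1)``);
    ``n_km1``/``n_km2`` admissions on the two preceding days; ``cum_emitted``
    total yolk handed to the ovarioles so far.  The in-process *mass* not yet
    emitted is ``n_km1`` (today's admission), which is what the conservation
    identity uses; ``xy`` additionally counts yesterday's admission whose
    machinery is released only tonight.
    """

    x: float = 0.0
    xy: float = 0.0
    n_km1: float = 0.0
    n_km2: float = 0.0
    cum_emitted: float = 0.0

    @classmethod
    def at_hatching(cls, params: ProteinParams) -> "ProteinState":
        return cls(x=params.x0)


def yolk_capacity(
    params: ProteinParams,
    k: int,
    T_onset: int | None,
    p2_history: Sequence[float],
) -> float:
    """Effective processing capacity ``N(k)``.

    Equals ``L`` before senescence onset (or with ``beta2 = 0``); afterwards
    ``L * exp(-beta2 * W)`` with ``W`` the sum of daily expenditure ``P2``
    over the trailing ``T_onset`` days ending at day ``k-1`` (days before
    hatching contribute nothing).  ``p2_history[i]`` is the expenditure of
    day ``i + 1``.
    """
    if T_onset is None or k <= T_onset:
        return params.L
    lo = max(0, (k - 1) - T_onset)
    window_sum = math.fsum(p2_history[lo : k - 1])
    return params.L * math.exp(-params.beta2 * window_sum)


def step_protein(
    params: ProteinParams, state: ProteinState, N_k: float
) -> tuple[ProteinState, float]:
    """Advance the pipeline one day under capacity ``N_k``; return emitted yolk.

    Emission first (``y_k = n(k-1)``, yesterday's admission), then the largest
    admission compatible with raw-protein availability and with the occupancy
    bound ``x_y(k) <= N_k``.
    """
    if not N_k > 0:
        raise ValueError(f"capacity N_k must be positive (got {N_k})")
    y_k = state.n_km1
    free = N_k - (state.xy - state.n_km2)
    n_k = max(0.0, min(state.x + params.a, free))
    assert n_k >= 0.0, "admission must be non-negative"
    state.x = state.x + params.a - n_k
    state.xy = state.xy + n_k - state.n_km2
    state.n_km2 = state.n_km1
    state.n_km1 = n_k
    state.cum_emitted += y_k
    assert state.x >= -1e-12 and state.xy >= -1e-12
    return state, y_k


def plateau_rate(params: ProteinParams) -> float:
    """Predicted plateau egg-laying rate ``RC = min(L/2, a)`` (eggs/day)."""
    return min(params.L / 2.0, params.a)
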