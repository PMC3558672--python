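"""Energy budget of a single fly.

The organism runs on a daily energy ledger.  Intake :math:`P_1` starts at
``P1MAX`` and, as cumulative metabolic expenditure accrues oxidative damage,
declines quasi-exponentially with vulnerability coefficient ``beta1``:

.. math:: P_1(k) = P_{1\\mathrm{MAX}} \\exp(-\\beta_1 D(k-1)),

where :math:`D` is the cumulative expenditure since hatching.  Expenditure on
day *k* is somatic maintenance plus the cost of the eggs actually laid,
:math:`P_2(k) = P_s + \\alpha s(k)`.  The reserve integrates the difference,
:math:`E(k) = E_0 + \\sum_{i\\le k} [P_1(i) - P_2(i)]`.

Senescence onset ``T`` is the first day on which expenditure strictly exceeds
intake; death is the first day the reserve is exhausted (``E <= 0``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass(frozen=True)
class EnergyParams:
    """Parameters of the energy subsystem.

    Attributes
    ----------
    P1MAX : float
        Maximum daily energy intake (energy/day); the main control knob for
        the s/m/l phenotypes.
    beta1 : float
        Oxidative vulnerability of the energy system (1/energy).  ``0``
        switches intake senescence off.
    Ps : float
        Constant daily somatic energy consumption (energy/day).
    alpha : float
        Energy cost of laying one egg (energy/egg).
    E0 : float
        Initial energy reserve at hatching (energy).  Defaults to 0.
    """

    P1MAX: float
    beta1: float = 0.0
    Ps: float = 0.0
    alpha: float = 0.0
    E0: float = 0.0

    def validate(self) -> list[str]:
        errors = []
        if not self.P1MAX > 0:
            errors.append(f"energy.P1MAX must be > 0 (got {self.P1MAX})")
        if self.beta1 < 0:
            errors.append(f"energy.beta1 must be >= 0 (got {self.beta1})")
        if self.Ps < 0:
            errors.append(f"energy.Ps must be >= 0 (got {self.Ps})")
        if self.alpha < 0:
            errors.append(f"energy.alpha must be >= 0 (got {self.alpha})")
        if self.E0 < 0:
            errors.append(f"energy.E0 must be >= 0 (got {self.E0})")
        return errors


@dataclass
class EnergyState:
    """Mutable energy ledger of one fly.

    ``D`` (cumulative expenditure) is non-decreasing; ``T_onset`` is set once,
    on the first day with ``P2 > P1``, and never changes afterwards.
    """

    E: float = 0.0
    D: float = 0.0
    P1_today: float = 0.0
    P2_today: float = 0.0
    T_onset: int | None = None
    P2_history: list[float] = field(default_factory=list)

    @classmethod
    def at_hatching(cls, params: EnergyParams) -> "EnergyState":
        return cls(E=params.E0)


def daily_intake(params: EnergyParams, state: EnergyState) -> float:
    """Realized energy intake for the coming day, ``P1MAX * exp(-beta1 * D)``.

    Equals ``P1MAX`` at hatching (no damage yet) or when ``beta1 == 0``;
    strictly decreasing in cumulative expenditure otherwise.
    """
    if state.D < 0:
        raise ValueError("cumulative expenditure D cannot be negative")
    return params.P1MAX * math.exp(-params.beta1 * state.D)


def update_energy(
    params: EnergyParams, state: EnergyState, s_k: int, k: int
) -> EnergyState:
    """Apply day *k*'s intake/expenditure to the ledger, in place.

    ``state.P1_today`` must already hold the day's intake (from
    :func:`daily_intake`).  Sets ``T_onset`` on the first day with strict
    ``P2 > P1``; a tie does not trigger onset.
    """
    if s_k < 0:
        raise ValueError(f"eggs laid on day {k} cannot be negative (got {s_k})")
    p2 = params.Ps + params.alpha * s_k
    state.P2_today = p2
    state.E += state.P1_today - p2
    state.D += p2
    state.P2_history.append(p2)
    if state.T_onset is None and p2 > state.P1_today:
        state.T_onset = k
    return state


def is_dead(state: EnergyState, k: int) -> bool:
    """True iff the reserve is exhausted (``E <= 0``) at the end of day *k*."""
    return state.E <= 0.0
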