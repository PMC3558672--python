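"""Daily-loop orchestration: couple energy, protein pipeline and ovarioles
from hatching to death.

Within each simulated day *k* the fixed event order is:

1. effective yolk capacity ``N(k)`` from the senescence state;
2. the protein pipeline emits yolk ``y(k) = n(k-1)`` and admits new protein;
3. ripe portions are laid (``s(k)``);
4. the emitted yolk is loaded into the space the laying just freed;
5. the day's energy intake ``P1(k)`` is realized;
6. the energy ledger is updated with the day's actual laying cost, possibly
   marking senescence onset;
7. the day is recorded; the run stops at death (``E <= 0``) or at the
   ``max_days`` cap (censored).

Laying before loading implements the rule that a freed ovariole is refilled
immediately; updating energy last makes the reproductive cost consistent with
the eggs actually laid that day.  All randomness lives in the maturation-time
draws of the ovariole bank, so one seeded generator per fly makes runs
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import energy as en
from . import ovarioles as ov
from . import protein as pr
from .config import SimulationConfig, validate_config

#: trajectory columns, in canonical order
TRAJECTORY_COLUMNS = [
    "day",
    "eggs_laid",
    "E",
    "P1",
    "P2",
    "N",
    "x_protein",
    "x_yolk",
    "senescence_onset_flag",
    "censored",
]

#: additional audit columns used by the conservation checks
AUDIT_COLUMNS = ["in_process", "buffer", "in_ovarioles", "cum_laid", "cum_emitted"]


@dataclass(frozen=True)
class ReproductivePattern:
    """A fly's life in eggs: the day-by-day counts from hatching to death.

    ``death_cause_raw`` is the simulator's own ledger-based label
    (``overload`` / ``senescence`` / ``censored``); patterns loaded from file
    carry ``None``.  The phenotype classifier makes its own, fit-based call.
    """

    daily_eggs: tuple[int, ...]
    life_span: int
    death_cause_raw: str | None = None

    @property
    def total_eggs(self) -> int:
        return int(sum(self.daily_eggs))

    @property
    def censored(self) -> bool:
        return self.death_cause_raw == "censored"

    def __len__(self) -> int:
        return len(self.daily_eggs)


@dataclass
class _RunAccumulator:
    rows: list[dict] = field(default_factory=list)


def simulate_fly(
    config: SimulationConfig,
    *,
    overload_trailing_days: int = 3,
    overload_fraction: float = 0.5,
) -> tuple[ReproductivePattern, pd.DataFrame]:
    """Simulate one fly; return its pattern and full daily trajectory.

    The raw death-cause label is ``overload`` when death strikes before
    senescence onset or while the trailing ``overload_trailing_days``-day mean
    laying rate is still at least ``overload_fraction`` of the predicted
    plateau ``RC = min(L/2, a)``; otherwise ``senescence``.
    """
    validate_config(config)
    rng = np.random.default_rng(config.seed)
    estate = en.EnergyState.at_hatching(config.energy)
    pstate = pr.ProteinState.at_hatching(config.protein)
    bank = ov.OvarioleBankState.empty(config.ovarioles)

    eggs: list[int] = []
    acc = _RunAccumulator()
    died_on: int | None = None

    for k in range(1, config.max_days + 1):
        N_k = pr.yolk_capacity(config.protein, k, estate.T_onset, estate.P2_history)
        pstate, y_k = pr.step_protein(config.protein, pstate, N_k)
        bank, s_k = ov.lay_eggs(bank, k)
        bank = ov.load_ovarioles(bank, y_k, config.ovarioles, rng, k)
        estate.P1_today = en.daily_intake(config.energy, estate)
        en.update_energy(config.energy, estate, s_k, k)
        eggs.append(s_k)
        acc.rows.append(
            {
                "day": k,
                "eggs_laid": s_k,
                "E": estate.E,
                "P1": estate.P1_today,
                "P2": estate.P2_today,
                "N": N_k,
                "x_protein": pstate.x,
                "x_yolk": pstate.xy,
                "senescence_onset_flag": int(
                    estate.T_onset is not None and k >= estate.T_onset
                ),
                "in_process": pstate.n_km1,
                "buffer": bank.ready_buffer,
                "in_ovarioles": int(sum(bank.x_ov)),
                "cum_laid": bank.cum_laid,
                "cum_emitted": pstate.cum_emitted,
            }
        )
        if en.is_dead(estate, k):
            died_on = k
            break

    censored = died_on is None
    life_span = config.max_days if censored else died_on
    if censored:
        cause = "censored"
    elif estate.T_onset is None:
        cause = "overload"
    else:
        tail = eggs[-overload_trailing_days:]
        trailing_mean = sum(tail) / len(tail)
        plateau = pr.plateau_rate(config.protein)
        cause = (
            "overload"
            if plateau > 0 and trailing_mean >= overload_fraction * plateau
            else "senescence"
        )

    trajectory = pd.DataFrame(acc.rows)
    trajectory["censored"] = int(censored)
    trajectory = trajectory[TRAJECTORY_COLUMNS + AUDIT_COLUMNS]
    pattern = ReproductivePattern(
        daily_eggs=tuple(eggs), life_span=life_span, death_cause_raw=cause
    )
    return pattern, trajectory


def simulate_cohort(
    config: SimulationConfig, n: int, seed_base: int | None = None
) -> list[ReproductivePattern]:
    """Run ``n`` independent flies with seeds ``seed_base, seed_base+1, ...``.

    Fly *i* depends only on ``seed_base + i``, so any subset of the cohort is
    reproducible in isolation.
    """
    if n < 1:
        raise ValueError(f"cohort size must be >= 1 (got {n})")
    base = config.seed if seed_base is None else int(seed_base)
    return [simulate_fly(config.with_seed(base + i))[0] for i in range(n)]
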