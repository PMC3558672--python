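"""Regime sweeps and cohort summaries.

The model's claim is that a single knob — the maximum daily energy intake
``P1MAX`` — moves a fly between the three resource-allocation phenotypes:
scarce energy kills mid-laying (*s*, reproductive overload), a balanced
budget lets reproduction just complete (*m*), and an ample budget leaves a
post-reproductive tail of life (*l*).  :func:`phenotype_sweep` runs that
experiment; :func:`summarize_cohort` aggregates a cohort the way a
demographic table would.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .errors import NoReproductionError
from .pattern import ClassifierThresholds, classify_phenotype, fit_three_stage
from .simulate import ReproductivePattern, simulate_cohort, simulate_fly


@dataclass(frozen=True)
class SweepResult:
    """One row per (P1MAX value, seed): phenotype call and life summary."""

    table: pd.DataFrame
    base_config: SimulationConfig
    values: tuple[float, ...]
    seeds: tuple[int, ...]

    def modal_labels(self) -> list[str]:
        """Most frequent phenotype label at each grid value, in grid order."""
        out = []
        for v in self.values:
            labels = self.table.loc[self.table["P1MAX"] == v, "label"]
            out.append(labels.mode().iloc[0])
        return out

    def modal_death_causes(self) -> list[str]:
        out = []
        for v in self.values:
            causes = self.table.loc[self.table["P1MAX"] == v, "death_cause"]
            out.append(causes.mode().iloc[0])
        return out


@dataclass(frozen=True)
class CohortSummary:
    n: int
    n_censored: int
    lifespan_mean: float
    lifespan_sd: float
    total_eggs_mean: float
    total_eggs_sd: float
    phenotype_freq: dict[str, float]
    death_cause_freq: dict[str, float]


def _sweep_cell(config: SimulationConfig, thresholds: ClassifierThresholds) -> dict:
    pattern, _ = simulate_fly(config)
    try:
        fit = fit_three_stage(pattern)
        call = classify_phenotype(pattern, fit, thresholds)
        label, cause, rc = call.label, call.death_cause, fit.params.RC
    except NoReproductionError:
        label, cause, rc = "degenerate", pattern.death_cause_raw, 0.0
    return {
        "seed": config.seed,
        "label": label,
        "death_cause": cause,
        "LS": pattern.life_span,
        "total_eggs": pattern.total_eggs,
        "RC_fit": rc,
        "censored": pattern.censored,
    }


def phenotype_sweep(
    base_config: SimulationConfig,
    p1max_values: Sequence[float],
    seeds: Sequence[int],
    thresholds: ClassifierThresholds = ClassifierThresholds(),
) -> SweepResult:
    """Simulate, fit and classify every (P1MAX, seed) grid cell.

    Each cell varies only ``P1MAX`` from the base config and is independent
    of every other, so the mapping (value, seed) -> outcome is deterministic
    and permutation-invariant.
    """
    if len(p1max_values) < 1 or len(seeds) < 1:
        raise ValueError("need at least one P1MAX value and one seed")
    rows = []
    for v in p1max_values:
        cfg_v = base_config.with_p1max(v)
        for seed in seeds:
            try:
                cell = _sweep_cell(cfg_v.with_seed(seed), thresholds)
            except Exception as exc:
                raise type(exc)(
                    f"sweep cell P1MAX={v}, seed={seed}: {exc}"
                ) from exc
            cell["P1MAX"] = v
            rows.append(cell)
    table = pd.DataFrame(rows)[
        ["P1MAX", "seed", "label", "death_cause", "LS", "total_eggs", "RC_fit",
         "censored"]
    ]
    return SweepResult(
        table=table,
        base_config=base_config,
        values=tuple(float(v) for v in p1max_values),
        seeds=tuple(int(s) for s in seeds),
    )


def summarize_cohort(
    patterns: Sequence[ReproductivePattern],
    calls: Sequence,
) -> CohortSummary:
    """Aggregate a cohort: life-span and fecundity moments plus phenotype and
    death-cause frequencies (exact counts / n).  Censored runs are counted
    separately and excluded from the death-cause tally only if their call
    says so."""
    if len(patterns) != len(calls):
        raise ValueError(
            f"patterns ({len(patterns)}) and calls ({len(calls)}) must align"
        )
    if len(patterns) < 1:
        raise ValueError("need at least one pattern")
    ls = np.array([p.life_span for p in patterns], dtype=float)
    eggs = np.array([p.total_eggs for p in patterns], dtype=float)
    n = len(patterns)
    labels = Counter(c.label for c in calls)
    causes = Counter(c.death_cause for c in calls)
    return CohortSummary(
        n=n,
        n_censored=sum(p.censored for p in patterns),
        lifespan_mean=float(ls.mean()),
        lifespan_sd=float(ls.std(ddof=0)),
        total_eggs_mean=float(eggs.mean()),
        total_eggs_sd=float(eggs.std(ddof=0)),
        phenotype_freq={k: v / n for k, v in sorted(labels.items())},
        death_cause_freq={k: v / n for k, v in sorted(causes.items())},
    )
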