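"""Three-stage approximation of a reproductive pattern, and the s/m/l call.

A lifetime egg-laying record is summarized by a piecewise "skeleton" with
five parameters: nothing before the first egg at ``t0`` (maturation), a
constant plateau ``RC`` up to day ``T`` (adult stage), then an exponential
tail ``RC * exp(-(t - T)/tau)`` until death at ``LS`` (senescence).  The fit
strips the slow, age-driven structure from a pattern so that the fast
day-to-day scatter can be studied separately.

The phenotype call compares the reproductive window with the life span:
*s*-flies die mid-laying (reproductive overload), *m*-flies die about when
reproduction completes, *l*-flies outlive their reproduction (both die of
senescence).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import NoReproductionError
from .simulate import ReproductivePattern

_TAU_LO, _TAU_HI = 1e-3, 1e6


@dataclass(frozen=True)
class ThreeStageParams:
    """Skeleton parameters: first egg ``t0``, plateau end ``T``, plateau rate
    ``RC`` (eggs/day), tail time constant ``tau`` (days), life span ``LS``."""

    t0: int
    T: int
    RC: float
    tau: float
    LS: int

    def __post_init__(self):
        if not (0 < self.t0 <= self.T <= self.LS):
            raise ValueError(
                f"need 0 < t0 <= T <= LS (got t0={self.t0}, T={self.T}, LS={self.LS})"
            )
        if self.RC < 0:
            raise ValueError(f"RC must be >= 0 (got {self.RC})")
        if not self.tau > 0:
            raise ValueError(f"tau must be > 0 (got {self.tau})")


@dataclass(frozen=True)
class ThreeStageFit:
    params: ThreeStageParams
    rss: float
    n_days: int


@dataclass(frozen=True)
class ClassifierThresholds:
    """Operational thresholds of the phenotype rule.

    ``epsilon``: the fitted rate falling below ``epsilon * RC`` defines
    completion of reproduction (``R_end = T + tau * ln(1/epsilon)``);
    ``overload_fraction`` and ``trailing_days``: death counts as mid-laying
    when the mean of the last ``trailing_days`` daily counts is at least
    ``overload_fraction * RC``; ``post_margin``: surviving ``post_margin``
    days past ``R_end`` makes a fly *l*.
    """

    epsilon: float = 0.05
    overload_fraction: float = 0.5
    trailing_days: int = 3
    post_margin: float = 5.0


@dataclass(frozen=True)
class PhenotypeCall:
    """s / m / l label with its death-cause corollary and the evidence used."""

    label: str
    death_cause: str
    evidence: dict = field(default_factory=dict)

    def __post_init__(self):
        assert (self.label == "s") == (self.death_cause == "overload")


def three_stage_value(params: ThreeStageParams, t: float) -> float:
    """Skeleton laying rate on day ``t``; continuous at ``t = T``."""
    if not 1 <= t <= params.LS:
        raise ValueError(f"day {t} outside pattern domain [1, {params.LS}]")
    if t < params.t0:
        return 0.0
    if t <= params.T:
        return params.RC
    return params.RC * math.exp(-(t - params.T) / params.tau)


def three_stage_curve(params: ThreeStageParams) -> np.ndarray:
    """The full skeleton as an array over days ``1..LS``."""
    t = np.arange(1, params.LS + 1, dtype=float)
    out = np.where(
        t < params.t0,
        0.0,
        np.where(
            t <= params.T,
            params.RC,
            params.RC * np.exp(-(t - params.T) / params.tau),
        ),
    )
    return out


def _fit_tau(tail: np.ndarray, rc: float) -> tuple[float, float]:
    """Least-squares tail time constant for residuals against
    ``rc * exp(-d/tau)``, ``d = 1..len(tail)``; returns (tau, rss).

    Works on raw counts (zeros in the tail are usable, unlike a log-linear
    fit).  A coarse log-spaced scan brackets the optimum, then a bounded
    scalar minimization refines it.
    """
    d = np.arange(1, len(tail) + 1, dtype=float)

    def rss_of(log_tau: float) -> float:
        resid = tail - rc * np.exp(-d / math.exp(log_tau))
        return float(resid @ resid)

    grid = np.log(np.geomspace(_TAU_LO, _TAU_HI, 181))
    values = [rss_of(g) for g in grid]
    i = int(np.argmin(values))
    lo = grid[max(0, i - 1)]
    hi = grid[min(len(grid) - 1, i + 1)]
    res = minimize_scalar(rss_of, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    if res.fun <= values[i]:
        return math.exp(float(res.x)), float(res.fun)
    return math.exp(grid[i]), float(values[i])


def fit_three_stage(pattern: ReproductivePattern | np.ndarray) -> ThreeStageFit:
    """Fit the five-parameter skeleton to a pattern by least squares.

    ``t0`` is the first day with a positive count and ``LS`` the pattern
    length; the plateau end ``T`` is found by exhaustive search over the
    integers ``[t0, LS]``, taking for each candidate the plateau mean as
    ``RC`` and the best one-parameter exponential for the tail.  Ties in the
    residual sum of squares break toward the smallest ``T``.
    """
    s = np.asarray(
        pattern.daily_eggs if isinstance(pattern, ReproductivePattern) else pattern,
        dtype=float,
    )
    ls = len(s)
    if ls < 3:
        raise NoReproductionError(f"pattern too short to fit ({ls} days)")
    positive = np.nonzero(s > 0)[0]
    if positive.size == 0:
        raise NoReproductionError("pattern contains no eggs; fit undefined")
    t0 = int(positive[0]) + 1

    best: tuple[float, int, float, float] | None = None  # (rss, T, RC, tau)
    for T in range(t0, ls + 1):
        plateau = s[t0 - 1 : T]
        rc = float(plateau.mean())
        plateau_rss = float(((plateau - rc) ** 2).sum())
        tail = s[T:]
        if tail.size == 0:
            tau, tail_rss = 1.0, 0.0
        else:
            tau, tail_rss = _fit_tau(tail, rc)
        rss = plateau_rss + tail_rss
        if best is None or rss < best[0] - 1e-12 * max(1.0, best[0]):
            best = (rss, T, rc, tau)

    rss, T, rc, tau = best
    params = ThreeStageParams(t0=t0, T=T, RC=rc, tau=tau, LS=ls)
    return ThreeStageFit(params=params, rss=rss, n_days=ls)


def reproduction_end(params: ThreeStageParams, epsilon: float = 0.05) -> float:
    """Day the fitted rate falls to ``epsilon * RC``: ``T + tau ln(1/eps)``."""
    return params.T + params.tau * math.log(1.0 / epsilon)


def classify_phenotype(
    pattern: ReproductivePattern,
    fit: ThreeStageFit,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
) -> PhenotypeCall:
    """Call the s/m/l phenotype of a fitted pattern.

    *s* (death by reproductive overload): the trailing mean laying rate at
    death is still at least ``overload_fraction`` of the plateau.  *l*: the
    fly survived at least ``post_margin`` days past the completion of
    reproduction.  *m*: everything between.  Only *s* deaths are overload;
    *m* and *l* die of senescence.
    """
    s = np.asarray(pattern.daily_eggs, dtype=float)
    p = fit.params
    nd = min(thresholds.trailing_days, len(s))
    trailing_mean = float(s[-nd:].mean())
    r_end = reproduction_end(p, thresholds.epsilon)
    evidence = {
        "trailing_mean": trailing_mean,
        "trailing_ratio": trailing_mean / p.RC if p.RC > 0 else float("inf"),
        "reproduction_end": r_end,
        "post_reproductive_days": pattern.life_span - r_end,
        "thresholds": thresholds,
    }
    if p.RC > 0 and trailing_mean >= thresholds.overload_fraction * p.RC:
        return PhenotypeCall("s", "overload", evidence)
    if pattern.life_span >= r_end + thresholds.post_margin:
        return PhenotypeCall("l", "senescence", evidence)
    return PhenotypeCall("m", "senescence", evidence)
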