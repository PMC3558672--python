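"""Curated default parameter set.

The full parameter set behind published individual patterns is not available,
so the package ships one curated configuration, chosen once, that puts the
model in a biologically sensible regime: plateau laying near 50 eggs/day
(dietary intake a = 50 egg-equivalents/day, processing capacity L = 120, so
RC = min(L/2, a) = 50), a bank of J = 30 ovarioles of M = 5 oocytes each
(within the 30-45 ovarioles of real D. melanogaster, and large enough that
the bank never throttles the plateau: J*M = 150 >= a * E[xi] = 125),
maturation times of 1-4 days (p = 0, q = 4), somatic upkeep Ps = 40 energy
units/day with a cost of alpha = 0.6 per egg (plateau expenditure 70/day, so
stopping reproduction saves a meaningful but not overwhelming fraction of the
budget), and oxidative vulnerabilities beta1 = 6e-4, beta2 = 4*beta1 so the
protein-processing system ages faster than the energy system.  Sweeping P1MAX
through DEFAULT_P1MAX_SML = (82, 115, 165) then moves a fly from death
mid-laying at ~26 days (s), through a balanced ~58-day life (m), to a long
post-reproductive tail and death near 100 days (l).
"""

from __future__ import annotations

from .config import SimulationConfig
from .energy import EnergyParams
from .ovarioles import OvarioleParams
from .protein import ProteinParams

#: flat default values, keyed section.field as in config files
DEFAULTS: dict[str, float | int] = {
    "energy.P1MAX": 115.0,
    "energy.beta1": 6.0e-4,
    "energy.Ps": 40.0,
    "energy.alpha": 0.6,
    "energy.E0": 0.0,
    "protein.a": 50.0,
    "protein.L": 120.0,
    "protein.beta2": 2.4e-3,
    "protein.x0": 0.0,
    "ovarioles.J": 30,
    "ovarioles.M": 5,
    "ovarioles.p": 0,
    "ovarioles.q": 4,
    "seed": 0,
    "max_days": 500,
}

#: P1MAX values producing the s, m and l regimes under the defaults
DEFAULT_P1MAX_SML: tuple[float, float, float] = (82.0, 115.0, 165.0)


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The curated default :class:`SimulationConfig`.

    ``overrides`` use flat dotted keys, e.g. ``default_config(**{"energy.P1MAX":
    70.0})``.
    """
    flat = dict(DEFAULTS)
    for key, value in overrides.items():
        if key not in flat:
            raise KeyError(f"unknown parameter {key!r}")
        flat[key] = value
    flat["seed"] = seed
    return config_from_flat(flat)


def config_from_flat(flat: dict) -> SimulationConfig:
    """Build a config from a flat ``section.field`` dict (all keys present)."""
    return SimulationConfig(
        energy=EnergyParams(
            P1MAX=float(flat["energy.P1MAX"]),
            beta1=float(flat["energy.beta1"]),
            Ps=float(flat["energy.Ps"]),
            alpha=float(flat["energy.alpha"]),
            E0=float(flat["energy.E0"]),
        ),
        protein=ProteinParams(
            a=float(flat["protein.a"]),
            L=float(flat["protein.L"]),
            beta2=float(flat["protein.beta2"]),
            x0=float(flat["protein.x0"]),
        ),
        ovarioles=OvarioleParams(
            J=int(flat["ovarioles.J"]),
            M=int(flat["ovarioles.M"]),
            p=int(flat["ovarioles.p"]),
            q=int(flat["ovarioles.q"]),
        ),
        seed=int(flat["seed"]),
        max_days=int(flat["max_days"]),
    )


def config_to_flat(config: SimulationConfig) -> dict:
    """Inverse of :func:`config_from_flat`."""
    e, pr_, ov = config.energy, config.protein, config.ovarioles
    return {
        "energy.P1MAX": e.P1MAX,
        "energy.beta1": e.beta1,
        "energy.Ps": e.Ps,
        "energy.alpha": e.alpha,
        "energy.E0": e.E0,
        "protein.a": pr_.a,
        "protein.L": pr_.L,
        "protein.beta2": pr_.beta2,
        "protein.x0": pr_.x0,
        "ovarioles.J": ov.J,
        "ovarioles.M": ov.M,
        "ovarioles.p": ov.p,
        "ovarioles.q": ov.q,
        "seed": config.seed,
        "max_days": config.max_days,
    }


def sample_random_config(rng, max_days: int = 300) -> SimulationConfig:
    """Draw a random valid configuration spanning the model's regime.

    Used to stress-test the conservation laws: intake, capacities,
    vulnerabilities, bank geometry and maturation interval are all varied,
    subject to the structural constraints (a <= L/2, beta2 > beta1).
    """
    a = float(rng.uniform(20.0, 55.0))
    L = a * float(rng.uniform(2.2, 3.0))
    Ps = float(rng.uniform(10.0, 45.0))
    alpha = float(rng.uniform(0.3, 1.0))
    beta1 = 0.0 if rng.random() < 0.2 else float(rng.uniform(1e-5, 1.5e-3))
    beta2 = beta1 * float(rng.uniform(2.0, 6.0))
    p2_plateau = Ps + alpha * a
    return SimulationConfig(
        energy=EnergyParams(
            P1MAX=p2_plateau * float(rng.uniform(1.05, 2.5)),
            beta1=beta1,
            Ps=Ps,
            alpha=alpha,
            E0=float(rng.uniform(0.0, 20.0)),
        ),
        protein=ProteinParams(
            a=a, L=L, beta2=beta2, x0=float(rng.uniform(0.0, 20.0))
        ),
        ovarioles=OvarioleParams(
            J=int(rng.integers(10, 41)),
            M=int(rng.integers(3, 8)),
            p=int(rng.integers(0, 3)),
            q=int(rng.integers(1, 6)),
        ),
        seed=int(rng.integers(0, 2**31 - 1)),
        max_days=max_days,
    )
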