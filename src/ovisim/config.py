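"""Simulation configuration: the single source of truth for one run."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

from .energy import EnergyParams
from .errors import ConfigError
from .ovarioles import OvarioleParams
from .protein import ProteinParams


@dataclass(frozen=True)
class SimulationConfig:
    """All model parameters plus RNG seed and run limits.

    ``max_days`` caps a run: a fly still alive there is reported as censored,
    never silently truncated (a no-senescence fly would otherwise live
    forever).
    """

    energy: EnergyParams
    protein: ProteinParams
    ovarioles: OvarioleParams
    seed: int = 0
    max_days: int = 500

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=int(seed))

    def with_p1max(self, p1max: float) -> "SimulationConfig":
        return replace(self, energy=replace(self.energy, P1MAX=float(p1max)))


class BetaOrderWarning(UserWarning):
    """The protein system is expected to age faster than the energy system."""


def validate_config(
    config: SimulationConfig, *, strict_beta_order: bool = False
) -> SimulationConfig:
    """Check every parameter invariant; raise :class:`ConfigError` listing all
    violations by parameter name.

    The model assumption ``beta2 > beta1`` (protein processing ages faster
    than the energy system) is a warning by default; pass
    ``strict_beta_order=True`` to promote it to an error.
    """
    errors: list[str] = []
    errors += config.energy.validate()
    errors += config.protein.validate()
    errors += config.ovarioles.validate()
    if config.max_days < 1:
        errors.append(f"max_days must be >= 1 (got {config.max_days})")
    beta_msg = (
        "model assumes beta2 > beta1 (the protein-processing system ages "
        f"faster than the energy system); got beta1={config.energy.beta1}, "
        f"beta2={config.protein.beta2}"
    )
    beta_ok = (
        config.protein.beta2 > config.energy.beta1
        or (config.energy.beta1 == 0.0 and config.protein.beta2 == 0.0)
    )
    if not beta_ok:
        if strict_beta_order:
            errors.append(beta_msg)
        else:
            warnings.warn(beta_msg, BetaOrderWarning, stacklevel=2)
    if errors:
        raise ConfigError(errors)
    return config
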