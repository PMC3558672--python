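"""Readers and writers: config files, pattern files, trajectory files.

Patterns and trajectories are plain comma-separated text with a mandatory
header — there is no standard interchange format for fecundity schedules, and
CSV feeds straight into downstream statistics.  All writers are
byte-deterministic for a given object (fixed column order, ``\\n`` line
endings, integers written as integers, reals with six significant digits), and
every reader/writer pair is inverse on valid data.

Config files are YAML with sections mirroring the parameter groups
(``energy``, ``protein``, ``ovarioles``) plus top-level ``seed`` and
``max_days``.  Unknown keys are rejected by name — a typo in a parameter must
never silently fall back to a default — and missing keys take the documented
defaults.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import pandas as pd
import yaml

from .config import SimulationConfig, validate_config
from .defaults import DEFAULTS, config_from_flat, config_to_flat
from .errors import ConfigError, PatternFormatError
from .simulate import TRAJECTORY_COLUMNS, ReproductivePattern

logger = logging.getLogger("ovisim")

_SECTIONS = ("energy", "protein", "ovarioles")
_TOP_KEYS = ("seed", "max_days")


def read_config(path: str | Path) -> SimulationConfig:
    """Load, default-fill and validate a simulation config.

    The effective (fully defaulted) config is echoed to the package logger at
    INFO level together with its hash.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError([f"{path}: cannot parse YAML: {exc}"]) from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError([f"{path}: top level must be a mapping"])

    flat = dict(DEFAULTS)
    errors: list[str] = []
    for key, value in raw.items():
        if key in _TOP_KEYS:
            flat[key] = value
        elif key in _SECTIONS:
            if not isinstance(value, dict):
                errors.append(f"{path}: section {key!r} must be a mapping")
                continue
            for sub, sval in value.items():
                dotted = f"{key}.{sub}"
                if dotted not in DEFAULTS:
                    errors.append(f"{path}: unknown parameter {dotted!r}")
                else:
                    flat[dotted] = sval
        else:
            errors.append(f"{path}: unknown key {key!r}")
    if errors:
        raise ConfigError(errors)
    try:
        config = config_from_flat(flat)
    except (TypeError, ValueError) as exc:
        raise ConfigError([f"{path}: type mismatch: {exc}"]) from exc
    validate_config(config)
    logger.info("loaded config %s (hash %s): %s", path, config_hash(config),
                config_to_flat(config))
    return config


def write_config(config: SimulationConfig, path: str | Path) -> None:
    """Write the effective config as sectioned YAML (round-trips exactly)."""
    flat = config_to_flat(config)
    doc: dict = {section: {} for section in _SECTIONS}
    for dotted, value in flat.items():
        if "." in dotted:
            section, sub = dotted.split(".", 1)
            doc[section][sub] = value
        else:
            doc[dotted] = value
    Path(path).write_text(
        yaml.safe_dump(doc, sort_keys=True, default_flow_style=False)
    )


def config_hash(config: SimulationConfig) -> str:
    """Short stable hash of the effective parameter set."""
    flat = config_to_flat(config)
    canon = yaml.safe_dump(flat, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _fmt(value: float) -> str:
    """Integers as integers, reals with 6 significant digits."""
    if float(value) == int(value):
        return str(int(value))
    return format(float(value), ".6g")


def write_pattern(pattern: ReproductivePattern, path: str | Path) -> None:
    """Write a pattern as ``day,eggs`` CSV, one row per day of life."""
    lines = ["day,eggs"]
    lines += [f"{day},{eggs}" for day, eggs in
              enumerate(pattern.daily_eggs, start=1)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_pattern(path: str | Path) -> ReproductivePattern:
    """Read a ``day,eggs`` CSV; days must run 1, 2, ... without gaps."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0].strip().lower() not in ("day,eggs", "day,eggs_laid"):
        raise PatternFormatError(f"{path}:1: missing 'day,eggs' header")
    eggs: list[int] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise PatternFormatError(f"{path}:{lineno}: expected 2 fields, got "
                                     f"{len(parts)}")
        try:
            day, count = int(parts[0]), int(parts[1])
        except ValueError as exc:
            raise PatternFormatError(f"{path}:{lineno}: non-integer value: "
                                     f"{line!r}") from exc
        if day != len(eggs) + 1:
            raise PatternFormatError(
                f"{path}:{lineno}: day {day} out of order (expected "
                f"{len(eggs) + 1}; days must be gapless from 1)"
            )
        if count < 0:
            raise PatternFormatError(f"{path}:{lineno}: negative egg count "
                                     f"{count}")
        eggs.append(count)
    if not eggs:
        raise PatternFormatError(f"{path}: no data rows")
    return ReproductivePattern(daily_eggs=tuple(eggs), life_span=len(eggs),
                               death_cause_raw=None)


def write_trajectory(trajectory: pd.DataFrame, path: str | Path) -> None:
    """Write the canonical trajectory columns as deterministic CSV."""
    df = trajectory[TRAJECTORY_COLUMNS]
    lines = [",".join(TRAJECTORY_COLUMNS)]
    for row in df.itertuples(index=False):
        lines.append(",".join(_fmt(v) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_trajectory(path: str | Path) -> pd.DataFrame:
    """Read a trajectory CSV written by :func:`write_trajectory`."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise PatternFormatError(f"{path}: missing columns {missing}")
    return df
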