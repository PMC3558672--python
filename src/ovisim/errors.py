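"""Exception types shared across the package."""


class OvisimError(Exception):
    """Base class for package errors."""


class ConfigError(OvisimError):
    """Invalid configuration: carries the full list of violations."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n  " + "\n  ".join(self.errors))


class PatternFormatError(OvisimError):
    """Malformed pattern or trajectory file (message carries line context)."""


class NoReproductionError(OvisimError):
    """A fit was requested on a pattern with no eggs at all."""
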