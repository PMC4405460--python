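"""Exception hierarchy shared across the package."""


class SteppescanError(Exception):
    """Base class for all package errors."""


class FormatError(SteppescanError, ValueError):
    """An input file violates the documented dialect or an invariant."""


class ConfigError(SteppescanError, ValueError):
    """An analysis or simulation configuration is invalid."""


class DatingError(SteppescanError, RuntimeError):
    """Admixture-date estimation failed (no signal, no convergence, censoring)."""
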