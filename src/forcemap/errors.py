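"""Exception hierarchy for forcemap."""


class ForcemapError(Exception):
    """Base class for all forcemap errors."""


class ParseError(ForcemapError):
    """A curve file could not be parsed; the message names the line."""


class DataError(ForcemapError):
    """Input data violate a structural invariant (length, finiteness...)."""


class ConfigError(ForcemapError):
    """A configuration value or manifest is invalid."""


class FitError(ForcemapError):
    """A fitting routine cannot proceed (degenerate design, too few points)."""
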