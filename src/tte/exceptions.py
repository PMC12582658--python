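"""Exception types raised across the pipeline."""


class ConfigError(ValueError):
    """A configuration field is invalid; the message names the field."""


class PositivityError(RuntimeError):
    """An estimated treatment/censoring probability is numerically 0 or 1.

    Carries the offending covariate pattern (or arm/month cell) so the
    violation can be diagnosed rather than silently producing infinite
    weights.
    """

    def __init__(self, message: str, pattern=None):
        super().__init__(message)
        self.pattern = pattern


class ConvergenceError(RuntimeError):
    """A model fit did not converge (possible separation)."""
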