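"""Exception types shared across the package."""


class ConfigError(ValueError):
    """Malformed configuration file or unknown configuration key."""


class ValidationError(ValueError):
    """A parameter value violates a model invariant."""


class CalibrationError(RuntimeError):
    """A calibration target is unreachable within physical bounds."""
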