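"""Exception types shared across the pipeline."""


class ConfigError(ValueError):
    """An invalid configuration (weights not summing to 1, duplicate tags...)."""


class CapacityError(ValueError):
    """More unique sequences requested than the sequence space holds."""


class CalibrationError(ValueError):
    """Spike-in calibration is impossible (no spike-in reads, <2 ladder levels)."""
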