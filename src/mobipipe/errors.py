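"""Exception hierarchy shared across the pipeline."""


class MobiError(Exception):
    """Base class for all pipeline errors."""


class FormatError(MobiError):
    """A file could not be parsed in the expected format."""


class MissingMarkerError(FormatError):
    """A marker CSV lacks markers required for gait analysis."""

    def __init__(self, missing):
        self.missing = sorted(missing)
        super().__init__(f"missing required markers: {', '.join(self.missing)}")


class ConfigError(MobiError):
    """Invalid pipeline configuration."""


class UnknownConfigKeyError(ConfigError):
    """A configuration file contains keys the pipeline does not define."""

    def __init__(self, keys):
        self.keys = sorted(keys)
        super().__init__(f"unknown configuration keys: {', '.join(self.keys)}")


class InsufficientGaitError(MobiError):
    """Too few gait events were detected to compute stride metrics."""
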