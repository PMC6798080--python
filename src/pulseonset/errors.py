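"""Exception hierarchy for the pulseonset package."""


class PulseOnsetError(Exception):
    """Base class for all package errors."""


class ConfigError(PulseOnsetError):
    """Invalid configuration value or unknown parameter."""


class ParseError(PulseOnsetError):
    """Malformed waveform or annotation file."""


class SamplingError(ParseError):
    """Time axis is not uniformly sampled."""


class DetectionError(PulseOnsetError):
    """Detection cannot proceed (e.g. no pulsatile activity in the signal)."""


class ProcessingError(PulseOnsetError):
    """A numeric operation received degenerate input."""
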