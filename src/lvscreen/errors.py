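"""Exception hierarchy for the screening pipeline."""


class LVScreenError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LVScreenError):
    """Invalid configuration (bad prevalences, sampling rate too low, ...)."""


class NoBeatsDetected(LVScreenError):
    """No QRS complexes could be found in the record."""


class InsufficientBeats(LVScreenError):
    """Fewer usable beats than the quality gate requires (default 8)."""


class WaveNotFound(LVScreenError):
    """A wave (typically T) could not be resolved above the noise floor."""


class StageError(LVScreenError):
    """A pipeline stage could not run, e.g. a missing upstream artifact."""
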