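"""Exception hierarchy."""


class GaitPhaseError(Exception):
    """Base class for all package errors."""


class ConfigError(GaitPhaseError, ValueError):
    """An invalid configuration field; the message names the field."""


class AlignmentError(GaitPhaseError, ValueError):
    """Streams cannot be synchronized (missing trigger, rate mismatch...)."""


class DataError(GaitPhaseError, ValueError):
    """Malformed or inconsistent input data."""


class ShapeError(GaitPhaseError, ValueError):
    """An array does not have the expected dimensions."""
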