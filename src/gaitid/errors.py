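"""Exception hierarchy for the gaitid pipeline."""


class GaitIdError(Exception):
    """Base class for all gaitid errors."""


class FormatError(GaitIdError):
    """A session file could not be parsed (wrong column count, bad header...)."""


class ValidationError(GaitIdError):
    """Data violates an invariant of the recording model (e.g. pressure not in {0,1,2})."""


class DegenerateStepError(GaitIdError):
    """A step segment is too short to be normalized."""


class FitError(GaitIdError):
    """A discriminant fit could not be computed (empty null space, rank deficit...)."""


class ProtocolError(GaitIdError):
    """The evaluation protocol cannot be satisfied (e.g. a subject with too few samples)."""


class ConfigError(GaitIdError):
    """An unknown or invalid configuration key/value."""
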