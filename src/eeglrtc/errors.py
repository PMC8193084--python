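"""Exception hierarchy shared across the pipeline."""


class EegLrtcError(Exception):
    """Base class for all package errors."""


class ParameterError(EegLrtcError, ValueError):
    """An argument is outside its documented domain."""


class DataError(EegLrtcError, ValueError):
    """Input data are malformed (NaN/Inf, wrong shape, ...)."""


class LengthError(EegLrtcError, ValueError):
    """A series is too short for the requested operation."""


class DegenerateSignalError(EegLrtcError, ValueError):
    """Constant or exactly linear input for which DFA is undefined."""


class FitError(EegLrtcError, RuntimeError):
    """A model fit failed to converge or produced a degenerate result."""


class AlignmentError(EegLrtcError, ValueError):
    """Two time courses do not share a common window grid."""


class SampleSizeError(EegLrtcError, ValueError):
    """Too few samples/trials for a meaningful statistical test."""


class ChannelError(EegLrtcError, KeyError):
    """A requested channel label is absent from a recording."""


class FormatError(EegLrtcError, ValueError):
    """A file could not be parsed in the expected format."""
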