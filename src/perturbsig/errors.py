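"""Exception hierarchy shared across the pipeline."""


class PerturbsigError(Exception):
    """Base class for all package errors."""


class InvalidInputError(PerturbsigError, ValueError):
    """Inputs violate a documented precondition (shape, length, missing values)."""


class UnsupportedFormatError(PerturbsigError, ValueError):
    """A file is not in the supported GCT #1.3 text dialect."""


class CorruptFileError(PerturbsigError, ValueError):
    """A GCT file's declared dimensions disagree with its data block."""


class InvalidGroupingError(PerturbsigError, ValueError):
    """A consensus group mixes cell lines or is otherwise ill-formed."""


class DegenerateDataError(PerturbsigError, ValueError):
    """Data carry no usable variance (constant matrix, zero-norm signature)."""


class InvalidConfigError(PerturbsigError, ValueError):
    """A generator configuration violates its invariants."""
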