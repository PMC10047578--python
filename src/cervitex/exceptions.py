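"""Exception hierarchy for cervitex."""


class CervitexError(Exception):
    """Base class for all cervitex errors."""


class DecodeError(CervitexError):
    """An image file could not be read or decoded."""


class ParameterError(CervitexError, ValueError):
    """An operation received an out-of-range or unknown parameter."""


class ShapeError(CervitexError, ValueError):
    """An array does not have the shape an operation requires."""


class LayoutError(CervitexError, ValueError):
    """A feature block has the wrong length for the fused-vector layout."""


class ConsistencyError(CervitexError, ValueError):
    """Inputs that must agree (e.g. matrices from the same channel) do not."""


class DegenerateInputError(CervitexError, ValueError):
    """The input admits no valid computation (e.g. no pixel pair fits the offset)."""


class StratificationError(CervitexError, ValueError):
    """A class has too few instances to stratify into the requested folds."""


class DegenerateLabelError(CervitexError, ValueError):
    """Training labels contain a single class."""


class ModelMismatchError(CervitexError, ValueError):
    """A fitted model does not match the dimensionality of the data."""


class RankError(CervitexError, ValueError):
    """Too few samples to fit the requested number of components."""


class ManifestError(CervitexError, ValueError):
    """A dataset manifest is malformed (e.g. missing labels)."""


class EmptyDatasetError(CervitexError, ValueError):
    """An operation requiring at least one image received none."""
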