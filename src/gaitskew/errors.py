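"""Exception types shared across the package."""


class GaitSkewError(Exception):
    """Base class for all package errors."""


class ParseError(GaitSkewError):
    """A keypoint file could not be parsed; the message names the file."""


class LayoutError(GaitSkewError):
    """Keypoint data does not match the declared skeleton layout."""


class NoPersonError(GaitSkewError):
    """An operation required at least one detected person."""


class UndefinedCentroidError(GaitSkewError):
    """Centroid requested on an all-zero heat map."""


class InsufficientDataError(GaitSkewError):
    """Too few usable samples for a trajectory fit."""


class BackendMissingError(GaitSkewError):
    """A requested optional feature-extraction backend is not installed."""
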