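"""Exception hierarchy for the toolkit.

All toolkit-specific failures derive from :class:`FragchalError` so callers
can distinguish bad input data from programming errors.
"""


class FragchalError(Exception):
    """Base class for all toolkit errors."""


class FormatError(FragchalError):
    """A file or string does not conform to its declared format."""


class DataError(FragchalError):
    """Structurally valid input is missing required data (e.g. coordinates)."""


class ValidationError(FragchalError):
    """Input violates a submission or ground-truth contract."""


class InsufficientPointsError(FragchalError):
    """Too few paired points for a rigid-body fit (need at least 3)."""


class PairingError(FragchalError):
    """Receptors share too few common C-alpha residues to be aligned."""


class GraphMismatchError(FragchalError):
    """Two molecular graphs that must be isomorphic are not."""


class ResourceError(FragchalError):
    """A configurable resource cap (e.g. automorphism node count) was hit."""


class DegenerateDataError(FragchalError):
    """A resampling procedure produced no usable resamples."""


class DegenerateGeometryWarning(UserWarning):
    """Point set is (near-)collinear; the rigid fit is still returned."""
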