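"""Exception hierarchy shared across the package.

``ValidationError`` covers malformed inputs (exit code 2 in the CLI),
``NumericalError`` covers failures of the iterative fitting machinery
(exit code 3).
"""


class HierfcError(Exception):
    """Base class for all package errors."""


class ValidationError(HierfcError):
    """Invalid user input: files, shapes, partitions, configuration."""


class FormatError(ValidationError):
    """Structurally malformed table (ragged rows, missing header)."""


class ParseError(ValidationError):
    """A cell could not be parsed; message names the row/column."""


class PartitionError(ValidationError):
    """Sub-network partition violates its invariants."""


class UnknownRoiError(PartitionError):
    """Partition references an ROI name absent from the time series."""


class OverlapError(PartitionError):
    """Two sub-networks claim the same ROI."""


class UncoveredRoiError(PartitionError):
    """Some ROI belongs to no sub-network."""


class InvalidWindowError(ValidationError):
    """Sliding-window spec incompatible with the series length."""


class NumericalError(HierfcError):
    """Iterative estimation produced non-finite or unusable values."""


class DegenerateCovarianceError(NumericalError):
    """All residuals vanish (e.g. a single window) and no ridge was given."""
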