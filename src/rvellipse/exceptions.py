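"""Exception hierarchy.

All rvellipse errors derive from :class:`RVEllipseError` so callers can
catch the whole family; the subclasses mirror the distinct failure modes
(bad scalar input, malformed mask stack, unusable cohort data, degenerate
statistical samples, under-resolved phantom grids, caller misuse).
"""


class RVEllipseError(Exception):
    """Base class for all rvellipse errors."""


class DomainError(RVEllipseError, ValueError):
    """An input value is outside the mathematical domain of an operation."""


class FormatError(RVEllipseError, ValueError):
    """A mask stack or file does not conform to the expected format."""


class DataError(RVEllipseError, ValueError):
    """Cohort/replicate data are structurally unusable (empty, missing)."""


class SampleSizeError(DataError):
    """Too few paired observations for a statistical operation."""


class DegenerateSampleError(DataError):
    """A sample is degenerate (e.g. all paired differences are zero)."""


class ResolutionError(RVEllipseError, ValueError):
    """A voxel grid is too coarse for the requested geometry."""


class UsageError(RVEllipseError, ValueError):
    """The caller combined arguments inconsistently (e.g. phase mismatch)."""
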