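"""Exception hierarchy shared across the toolkit."""


class HdikitError(Exception):
    """Base class for all toolkit errors."""


class AlignmentError(HdikitError):
    """Grids do not share a GridSpec (or CRS labels differ)."""


class LegendError(HdikitError):
    """A land-use code is missing from the legend."""


class ScoringError(HdikitError):
    """A land-use class has no entry in the naturalness table."""


class ConversionError(HdikitError):
    """An energy carrier has no standard-coal factor."""


class CoverageError(HdikitError):
    """A temporal averaging window is not fully covered by the series."""


class AllocationError(HdikitError):
    """Area-based allocation has no target cells to receive the total."""


class EmptyZoneError(HdikitError):
    """Requested zone id does not occur in the zone raster."""


class DegenerateInputError(HdikitError):
    """Input lacks the variation required by the statistic (e.g. < k distinct values)."""


class RangeError(HdikitError):
    """A value falls outside its documented range."""
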