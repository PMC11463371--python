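"""Exception hierarchy for reachkdi.

All library errors derive from :class:`ReachKDIError` so callers (and the
CLI) can catch one base class; subclasses distinguish malformed files,
schema problems, degenerate inputs and bad parameters.
"""


class ReachKDIError(Exception):
    """Base class for all reachkdi errors."""


class FormatError(ReachKDIError):
    """A track file does not conform to the declared CSV dialect."""


class SchemaError(ReachKDIError):
    """A table lacks required columns or has mismatched variables."""


class DuplicationError(ReachKDIError):
    """Duplicate identifiers where uniqueness is required."""


class DegenerateInputError(ReachKDIError):
    """Input too small or empty to be meaningful (e.g. < 2 frames)."""


class ParameterError(ReachKDIError):
    """A parameter outside its documented range."""


class UnrecoverableTraceError(ReachKDIError):
    """A marker/coordinate trace with no observed points at all."""


class DegenerateGeometryError(ReachKDIError):
    """Zero matrices or other geometry for which a rotation is undefined."""


class DimensionalityError(ReachKDIError):
    """Fewer variables than requested components, or mismatched J."""


class ReferenceUnavailableError(ReachKDIError):
    """An animal has no baseline-success trials to build a reference from."""
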