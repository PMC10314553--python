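"""Exception hierarchy.

All package errors derive from :class:`AirwayMorphError` so callers can catch
one base class; subclasses distinguish input-validation failures from
geometric degeneracies and file-format problems.
"""


class AirwayMorphError(Exception):
    """Base class for all errors raised by airwaymorph."""


class FormatError(AirwayMorphError):
    """A file could not be parsed in its declared format."""


class ValidationError(AirwayMorphError):
    """Input data violates a documented precondition."""


class MissingLandmarkError(ValidationError):
    """A task requires landmarks that the set does not contain."""

    def __init__(self, missing, task: str = ""):
        self.missing = sorted(missing)
        self.task = task
        where = f" for {task}" if task else ""
        super().__init__(f"missing required landmarks{where}: {', '.join(self.missing)}")


class EmptySegmentationError(ValidationError):
    """A mask contains no foreground voxels."""


class DegenerateGeometryError(AirwayMorphError):
    """Landmark configuration does not determine the requested geometry."""


class StatisticsError(AirwayMorphError):
    """A statistical routine received data it cannot operate on."""
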