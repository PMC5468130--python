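"""Exception hierarchy for the aggregation-assay pipeline.

Every module raises subclasses of :class:`AggregationError` so callers can
catch pipeline failures without masking programming errors.
"""


class AggregationError(Exception):
    """Base class for all assay-pipeline errors."""


class InvalidFrameError(AggregationError):
    """A frame violates its invariants (e.g. fewer than two positions)."""


class SamplingError(AggregationError):
    """Frame spacing is incompatible with the requested sampling scheme."""


class EmptyTrackError(AggregationError):
    """An operation would leave a track with no frames."""


class DegenerateTrackError(AggregationError):
    """The track's statistic is undefined (all individuals coincident)."""


class IncompatibilityError(AggregationError):
    """Two objects that must share a group size or arena do not."""


class DegenerateDataError(AggregationError):
    """Statistical input carries no usable variation."""


class DegenerateCovariateError(DegenerateDataError):
    """A continuous predictor is constant (or absent) across observations."""


class ParameterError(AggregationError):
    """Simulation or configuration parameters are out of their valid range."""


class ParseError(AggregationError):
    """A track/design file violates the documented schema.

    Carries ``row`` (0-based data-row index, if known) so users can locate
    the offending line.
    """

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"{message} (data row {row})"
        super().__init__(message)
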