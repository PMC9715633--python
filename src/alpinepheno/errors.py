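"""Exception hierarchy shared across the pipeline.

``PipelineError`` is the base for anything raised on bad user input or
degenerate data; the CLI maps it to exit code 2 while genuine usage errors
(bad flags, missing files) exit 1.
"""


class PipelineError(Exception):
    """Base class for data/validation errors raised by pipeline stages."""


class InvalidInputError(PipelineError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateSeriesError(PipelineError):
    """A series is constant/empty where variation is required."""


class InsufficientDataError(PipelineError):
    """Too few observations for the requested operation."""


class UndefinedIndexError(PipelineError):
    """An index (e.g. greenness on an all-black ROI) is undefined."""


class NoSeasonError(PipelineError):
    """Season-start detection never found qualifying conditions."""


class CoverageError(PipelineError):
    """Temperature coverage of a requested window is insufficient."""


class StageError(PipelineError):
    """Wraps an error from a pipeline stage with stage/unit context."""

    def __init__(self, stage: str, unit_id: str, cause: Exception):
        self.stage = stage
        self.unit_id = unit_id
        self.cause = cause
        super().__init__(f"[{stage}] unit={unit_id}: {cause}")
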