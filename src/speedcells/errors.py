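"""Exception hierarchy shared across the pipeline.

"Signals" in the sense of the analysis contracts (degenerate unit, skipped
stage) are exceptions that orchestration code catches and logs; hard contract
violations (bad files, malformed tables) are errors the caller must fix.
"""


class SpeedcellsError(Exception):
    """Base class for all package errors."""


class FormatError(SpeedcellsError):
    """A file or table does not have the expected layout (e.g. missing column)."""


class ValidationError(SpeedcellsError):
    """Data violate a structural invariant (non-uniform timestamps, overlapping trials...)."""


class ConfigError(SpeedcellsError):
    """A configuration value is unusable (e.g. duration too short for one bout)."""


class DegenerateSeriesError(SpeedcellsError):
    """A unit or series cannot support the requested statistic (zero variance,
    too few overlapping bins, zero surrogate SD). Pipelines catch this and
    record the unit as excluded with the message as the reason."""


class AnalysisSkipped(SpeedcellsError):
    """A whole analysis stage cannot run on this session (e.g. too few trials
    for block stability, too few bins for decoding)."""
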