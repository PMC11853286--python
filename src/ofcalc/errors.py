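"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`OfcalcError`, so the orchestrator
can attribute a failure to its stage and offending input.
"""


class OfcalcError(Exception):
    """Base class for all pipeline errors."""


class AlignmentError(OfcalcError):
    """GPIO trigger missing, or alignment would leave no samples."""


class FormatError(OfcalcError):
    """A file on disk does not satisfy its documented dialect."""


class ScheduleError(OfcalcError):
    """An experiment schedule violates its invariants."""


class AnalysisError(OfcalcError):
    """A computation was requested on inputs it is undefined for."""


class ConfigError(OfcalcError):
    """The run configuration is missing or inconsistent."""
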