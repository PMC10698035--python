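"""Exception hierarchy used across the package."""


class GaitPrintError(Exception):
    """Base class for all package errors."""


class TrialIdError(GaitPrintError, ValueError):
    """Malformed or out-of-range trial identifier token."""


class SchemaError(GaitPrintError, ValueError):
    """A file or table does not match the expected column schema."""


class GenerationError(GaitPrintError, ValueError):
    """Synthetic-trial parameters produce an inconsistent trial."""


class InsufficientDataError(GaitPrintError, ValueError):
    """Not enough gait events or samples to run the requested analysis."""


class AnalysisError(GaitPrintError, ValueError):
    """An analysis precondition failed (constant input, no neighbors, ...)."""
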