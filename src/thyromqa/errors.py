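"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """Raised for malformed configuration: bad category proportions,
    duplicate question ids, prompt templates missing a placeholder."""


class DimensionMismatchError(ValueError):
    """Raised when two embedding vectors of different dimension are compared."""


class IncompleteGridError(ValueError):
    """Raised when an answer set does not cover the full report x question grid.

    Carries the missing (report_id, question_id) cells in ``missing``.
    """

    def __init__(self, message: str, missing=None):
        super().__init__(message)
        self.missing = list(missing or [])


class StagingError(ValueError):
    """Raised for staging inputs outside the rule domain (nonpositive size,
    negative node counts)."""
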