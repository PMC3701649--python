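"""Exception types shared across the package."""


class LtrTraceError(Exception):
    """Base class for all package-specific errors."""


class DegenerateSequenceError(LtrTraceError, ValueError):
    """Raised when an operation receives an empty or unusable sequence."""


class AlignmentShapeError(LtrTraceError, ValueError):
    """Raised when a set of sequences expected to form an alignment has unequal lengths."""


class SaturationError(LtrTraceError, ValueError):
    """Raised when an evolutionary distance is undefined (log argument <= 0)."""


class InsufficientDataError(LtrTraceError, ValueError):
    """Raised when too few observations are available for an estimate."""


class MissingArtifactError(LtrTraceError, FileNotFoundError):
    """Raised by the pipeline when an upstream stage's output file is absent."""

    def __init__(self, path, producer):
        self.path = str(path)
        self.producer = producer
        super().__init__(
            f"missing artifact {path!s}; run the '{producer}' subcommand first"
        )
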