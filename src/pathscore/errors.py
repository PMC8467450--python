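"""Exception hierarchy shared across the package."""


class PathscoreError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(PathscoreError, ValueError):
    """Invalid input data or parameters."""


class ConfigurationError(PathscoreError, ValueError):
    """Invalid model or run configuration."""


class CalibrationError(PathscoreError, ValueError):
    """Training data unsuitable for model calibration."""


class MissingEvidenceError(PathscoreError, LookupError):
    """A profile or matrix lacks probesets required by the model.

    Missing evidence is never imputed; the caller must supply every
    probeset the model expects.
    """

    def __init__(self, missing_ids):
        self.missing_ids = tuple(missing_ids)
        ids = ", ".join(self.missing_ids)
        super().__init__(
            f"{len(self.missing_ids)} model probeset(s) missing from input: {ids}"
        )


class ParseError(PathscoreError, ValueError):
    """A file could not be parsed under the requested dialect."""


class QCError(PathscoreError, ValueError):
    """Quality control failed hard (e.g. unresolvable missing values)."""
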