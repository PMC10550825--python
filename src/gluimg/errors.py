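"""Exception types shared across the package.

Exit-code mapping used by the CLI: usage errors -> 1, data errors -> 2,
analysis refusals (e.g. missing positive control) -> 3.
"""


class GluimgError(Exception):
    """Base class for all package errors."""


class ParameterError(GluimgError, ValueError):
    """An argument is outside its valid domain."""


class DataError(GluimgError):
    """Input data are malformed or inconsistent (shape/page mismatch, unreadable file)."""


class OnsetDetectionError(GluimgError):
    """Fewer stimulus onsets were found in the tracer channel than expected."""

    def __init__(self, found: int, expected: int):
        self.found = found
        self.expected = expected
        super().__init__(
            f"expected {expected} puff onsets but found {found} threshold crossings"
        )


class MotionEstimationError(GluimgError):
    """The morphology template is featureless; shifts cannot be estimated."""


class MissingControlError(GluimgError):
    """The positive-control (l-Glut) response map is empty; the cell cannot be scored."""


class ClassificationRefusedError(GluimgError):
    """Too few ROIs (or missing inputs) for a meaningful paired statistical test."""


class PairingError(GluimgError):
    """Per-ROI statistics from two acquisitions cannot be paired."""
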