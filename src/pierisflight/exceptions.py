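"""Package-wide exception hierarchy."""


class PierisFlightError(Exception):
    """Base class for all package errors."""


class DegenerateProjectionError(PierisFlightError):
    """3D point lies on (or numerically at) a camera's principal plane."""


class InvertibilityError(PierisFlightError):
    """Radial distortion map could not be inverted over the image."""


class SingularSystemError(PierisFlightError):
    """Calibration point configuration is rank-deficient (e.g. coplanar)."""


class InsufficientDataError(PierisFlightError):
    """Too few observations to run the requested estimation."""


class CalibrationError(PierisFlightError):
    """Nonlinear calibration failed to converge."""


class EmptyTrackError(PierisFlightError):
    """Rendered subject was never visible to a camera."""


class NumericalFailureError(PierisFlightError):
    """A filtering covariance lost positive definiteness."""


class UndefinedQuantityError(PierisFlightError):
    """A flight or morphometric quantity is undefined for this input."""


class InvalidOutlineError(PierisFlightError):
    """Wing outline polygon is not simple (self-intersecting)."""


class MissingLandmarkError(PierisFlightError):
    """A required wing landmark is absent; specimen must be excluded."""


class GenerationError(PierisFlightError):
    """Synthetic-data targets are infeasible or inconsistent."""


class SchemaError(PierisFlightError):
    """A CSV file does not match its documented schema."""
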