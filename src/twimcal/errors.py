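"""Exception hierarchy shared across the package."""


class TwimcalError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(TwimcalError):
    """An input table is missing a required column."""


class RowParseError(TwimcalError):
    """A table row holds a value that cannot be interpreted.

    Carries the zero-based data-row index so users can locate the offender.
    """

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


class UnknownClassError(TwimcalError):
    """A biomolecular-class label is not one of the accepted labels."""


class InvalidCorrectionError(TwimcalError):
    """The EDC flight-time correction produced a non-positive drift time."""


class InsufficientCalibrantsError(TwimcalError):
    """Too few calibrants to fit a calibration curve."""


class FitConvergenceError(TwimcalError):
    """Nonlinear least squares failed; carries the log-log seed estimate."""

    def __init__(self, message: str, seed_params=None):
        self.seed_params = seed_params
        super().__init__(message)


class NoSignalError(TwimcalError):
    """An arrival-time distribution contains no usable intensity."""


class UnsupportedDataError(TwimcalError):
    """Raw data lack a required dimension (e.g. no ion-mobility axis)."""


class UnsupportedChargeError(TwimcalError):
    """Feature charge state outside the calibrated range (z = 1-3)."""


class MissingCurveError(TwimcalError):
    """No calibration curve is available for the requested class/charge."""


class UnassignableFeatureError(TwimcalError):
    """A singly charged feature has no m/z-eligible class.

    The per-class distances to the trendlines are attached so the caller can
    report how far each rejected class was.
    """

    def __init__(self, feature_id: str, per_class_delta: dict):
        self.feature_id = feature_id
        self.per_class_delta = dict(per_class_delta)
        deltas = ", ".join(f"{k}={v:.2f}" for k, v in per_class_delta.items())
        super().__init__(
            f"feature {feature_id!r}: no m/z-eligible class (deltas: {deltas})"
        )


class GenerationError(TwimcalError):
    """Synthetic-data generation produced a physically impossible value."""
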