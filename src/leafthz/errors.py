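"""Exception and warning hierarchy.

Every error raised by this package derives from :class:`LeafTHzError`, so
callers can catch the whole family with one clause. Physically plausible but
suspicious situations (negative optical depth, clipped detector readings,
negative predicted water mass) emit warnings instead of raising: the
calibration workflow must tolerate them, and silently truncating them would
bias validation statistics.
"""


class LeafTHzError(Exception):
    """Base class for all package errors."""


class InvalidIntensityError(LeafTHzError, ValueError):
    """An intensity reading is non-positive or non-finite."""


class ProtocolError(LeafTHzError, ValueError):
    """Measurement protocol violated (e.g. wrong number of transmission points)."""


class GravimetryError(LeafTHzError, ValueError):
    """Dry mass exceeds fresh mass — physically impossible weighing."""


class DomainError(LeafTHzError, ValueError):
    """A quantity is outside its physical domain (e.g. area <= 0)."""


class GeometryError(LeafTHzError, ValueError):
    """Polygon outline is degenerate or self-intersecting."""


class SegmentationError(LeafTHzError, RuntimeError):
    """Automatic leaf segmentation found no usable foreground."""


class FixtureError(LeafTHzError, ValueError):
    """Synthetic image rendering cannot meet its resolution contract."""


class InsufficientDataError(LeafTHzError, ValueError):
    """Too few records/groups to fit or test."""


class DegenerateDesignError(LeafTHzError, ValueError):
    """Zero variance in a predictor or variable; fit/test undefined."""


class NonInvertibleCalibrationError(LeafTHzError, ValueError):
    """Calibration slope is not positive; the model cannot be inverted."""


class MeasurementFormatError(LeafTHzError, ValueError):
    """Measurement CSV does not match the declared dialect."""


class ReportError(LeafTHzError, ValueError):
    """Nothing to report (no fitted models)."""


class NegativeOpticalDepthWarning(UserWarning):
    """Transmitted intensity exceeded incident intensity (drift/noise)."""


class ClippedIntensityWarning(UserWarning):
    """Simulated detector readings fell below the positivity floor and were clipped."""


class NegativePredictionWarning(UserWarning):
    """Predicted water mass is negative (tau*L_A < C0); reported as-is."""
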