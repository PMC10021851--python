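"""Exception hierarchy."""


class MmrcalError(Exception):
    """Base class for all package errors."""


class ValidationError(MmrcalError, ValueError):
    """Invalid input value or malformed table; the message names the field."""


class UndefinedRateError(MmrcalError, ZeroDivisionError):
    """A rate is requested with a zero denominator (distinct from a zero rate)."""


class DegenerateCalibrationError(MmrcalError):
    """A calibration factor would be infinite or undefined.

    Raised when the facility-system state rate on the chosen calibration path
    is zero while the reference rate is positive.
    """
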