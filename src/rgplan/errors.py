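"""Exception hierarchy for rgplan.

All rgplan-specific failures derive from :class:`RGPlanError` so callers can
catch the whole family; input-validation failures additionally derive from
``ValueError``.
"""


class RGPlanError(Exception):
    """Base class for all rgplan errors."""


class InvalidInputError(RGPlanError, ValueError):
    """An argument violates a documented precondition."""


class InsufficientDataError(RGPlanError):
    """Too few data points to perform the requested operation."""


class DegenerateFitError(RGPlanError):
    """A fit has no information content (e.g. all-zero signals)."""


class DegenerateCurveError(RGPlanError):
    """A calibration curve violates an assumption (e.g. zero signal at max RG)."""


class OutOfRangeError(RGPlanError):
    """A receiver-gain query falls outside the calibrated range."""


class NoNoiseRegionError(RGPlanError):
    """No admissible signal-free window for noise estimation."""


class UndefinedSNRError(RGPlanError):
    """SNR is undefined because the noise estimate is zero."""


class NotClippedError(RGPlanError):
    """No clipping plateau found; the ADC ceiling cannot be estimated."""


class InfeasiblePlanError(RGPlanError):
    """Every (RG, alpha) grid cell violates the overflow constraint.

    Attributes
    ----------
    cell : tuple
        ``(rg, alpha_deg, predicted_fid_max)`` of the minimal-violation cell.
    """

    def __init__(self, message: str, cell=None):
        super().__init__(message)
        self.cell = cell


class SchemaError(RGPlanError):
    """A file does not conform to the expected column/field schema."""
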