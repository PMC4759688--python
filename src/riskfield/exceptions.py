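"""Exception hierarchy shared across the package."""


class RiskfieldError(Exception):
    """Base class for all package errors."""


class DataFormatError(RiskfieldError):
    """Malformed or contract-violating input data (VCF/TSV/phenotypes)."""


class QCError(RiskfieldError):
    """Quality-control produced an unusable dataset (e.g. no variants left)."""


class ModelFitError(RiskfieldError):
    """A model fit failed (separation, rank deficiency, non-convergence)."""


class SingularModelError(ModelFitError):
    """The estimating-equation design is singular in strict mode."""


class CalibrationError(RiskfieldError):
    """A simulation calibration (prevalence / effect scale) could not bracket."""
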