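"""Exception hierarchy shared across the pipeline stages."""


class FirecommError(Exception):
    """Base class for all pipeline errors."""


class InvalidDesignError(FirecommError):
    """Study design violates the paired 2x2x2 layout."""


class InvalidSpecError(FirecommError):
    """Effect specification outside its documented domain."""


class DegenerateInputError(FirecommError):
    """Input is structurally valid but carries no usable signal."""


class BarcodeError(FirecommError):
    """Barcode set invalid (duplicates, unequal lengths, empty)."""


class TableParseError(FirecommError):
    """Malformed count/metadata/taxonomy table."""


class CalibrationError(FirecommError):
    """Threshold calibration received no usable controls."""


class DegenerateSampleError(FirecommError):
    """A sample row has no positive counts."""


class RankDeficiencyError(FirecommError):
    """Design matrix rank-deficient beyond what conditioning absorbs."""


class DegenerateFitError(FirecommError):
    """Model fit impossible (zero variance, singular covariance)."""
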