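"""Exception and warning types shared across the package."""


class InvalidMeasurementError(ValueError):
    """A fluorescence yield violates physical constraints (e.g. F_m <= F_o)."""


class InsufficientDataError(ValueError):
    """Too few observations for the requested fit or test."""


class MissingBandError(KeyError):
    """A reflectance index was requested but a required wavelength bin is absent."""

    def __init__(self, band_nm: int):
        self.band_nm = band_nm
        super().__init__(f"reflectance band {band_nm} nm is missing from the spectrum")


class MissingReferenceError(ValueError):
    """No warm-treated discs available to build the unquenched reference."""


class NormalizationError(ValueError):
    """Normalisation denominator is zero or undefined."""


class SchemaError(ValueError):
    """An input table does not match the expected column layout."""


class DegenerateDataError(ValueError):
    """Data carry no usable variation for the requested statistic."""


class NegativeNPQWarning(UserWarning):
    """F_m' exceeded dark F_m, producing a negative quenching value."""


class LiteralFormulaWarning(UserWarning):
    """The literal (typographically garbled) dark-point formula was requested."""
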