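"""Exception hierarchy shared across the package."""


class SaSpatialError(Exception):
    """Base class for all package-specific errors."""


class MissingComponentError(SaSpatialError):
    """A required input file is absent from a Visium-style directory."""


class AlignmentError(SaSpatialError):
    """Barcodes in the expression matrix do not match the spot table."""


class OrphanBarcodeError(SaSpatialError):
    """Expression rows reference barcodes absent from the coordinate table."""


class DuplicateEntryError(SaSpatialError):
    """Ambiguous duplicated (barcode, gene) rows in a long-format table."""


class ZeroDepthError(SaSpatialError):
    """A spot has zero total counts and cannot be depth-normalized."""


class ZeroVarianceError(SaSpatialError):
    """A gene is constant across spots; Moran statistics are undefined."""


class DegenerateWeightsError(SaSpatialError):
    """The spatial weight matrix has zero aggregate weight (S0 = 0)."""


class EmptyRoiError(SaSpatialError):
    """A region of interest resolves to no spots."""


class UnknownBarcodeError(SaSpatialError):
    """A barcode was referenced that does not exist in the section."""


class ConfigError(SaSpatialError):
    """Pipeline configuration failed validation."""
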