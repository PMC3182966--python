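"""Exception hierarchy for the quantification pipeline."""


class RppaQuantError(Exception):
    """Base class for all package-specific errors."""


class UnsupportedImageError(RppaQuantError):
    """Image file exists but is not a single-channel integer image of <= 16 bits."""


class LayoutValidationError(RppaQuantError):
    """Array layout violates an invariant (duplicate address, bad pitch, ...).

    ``records`` lists the offending entries when applicable.
    """

    def __init__(self, message, records=None):
        super().__init__(message)
        self.records = list(records) if records else []


class GridNotFoundError(RppaQuantError):
    """No spot lattice detectable in the image; supply a manual origin."""


class InsufficientDataError(RppaQuantError):
    """Too few series / dilution steps / observations to identify the SuperCurve."""


class FlatFitError(RppaQuantError):
    """All responses identical: the sigmoid slope is unidentifiable."""
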