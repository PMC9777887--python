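"""Exception hierarchy.

Every error raised by the library derives from :class:`SpecfuseError` so
pipeline callers can tag failures with the stage that produced them.
"""


class SpecfuseError(ValueError):
    """Base class for all specfuse errors."""


class ParseError(SpecfuseError):
    """A cell in a spectra CSV could not be parsed; names row and column."""


class FormatError(SpecfuseError):
    """Structural problem in a spectra file (e.g. duplicate wavenumber header)."""


class LabelError(SpecfuseError):
    """A label is outside the class alphabet."""


class RangeError(SpecfuseError):
    """A wavenumber crop produced no columns."""


class ConsistencyError(SpecfuseError):
    """Replicates of one sample carry conflicting labels."""


class SplitError(SpecfuseError):
    """A calibration/prediction split cannot satisfy its invariants."""


class DegenerateRowError(SpecfuseError):
    """A spectral row is constant where a preprocessing step needs spread."""


class ShapeError(SpecfuseError):
    """Matrix dimensions do not match the fitted state."""


class SelectionError(SpecfuseError):
    """A variable selector ran out of variables."""


class AlignmentError(SpecfuseError):
    """Two sample sets that must be row-aligned are not."""


class StratificationError(SpecfuseError):
    """A cross-validation fold is missing a class."""
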