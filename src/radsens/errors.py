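"""Exception hierarchy shared across the package.

Every stage raises a subclass of :class:`RadsensError` so callers (and the
CLI) can name the failing stage without matching on message strings.
"""


class RadsensError(Exception):
    """Base class for all radsens errors."""


class CountMatrixError(RadsensError):
    """Malformed or invalid count matrix (parse errors name row/column)."""


class SampleSheetError(RadsensError):
    """Invalid sample sheet or sheet/matrix mismatch."""


class PanelError(RadsensError):
    """Panel gene missing from, or ambiguous in, a count matrix."""


class NormalizationError(RadsensError):
    """Normalization preconditions violated (zero library, single sample)."""


class DoseError(RadsensError):
    """Dose computation undefined (e.g. alpha + beta*d <= 0)."""


class SyntheticDataError(RadsensError):
    """Synthetic cohort generation could not satisfy its constraints."""
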