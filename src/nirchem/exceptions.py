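"""Exception types raised across the package.

All inherit from :class:`NirchemError` so callers can catch package errors
with a single clause; most also inherit :class:`ValueError` because they
signal invalid inputs.
"""


class NirchemError(Exception):
    """Base class for all package-specific errors."""


class FormatError(NirchemError, ValueError):
    """A file could not be parsed as the expected wide-CSV spectra dialect."""


class ConsistencyError(NirchemError, ValueError):
    """Replicate rows or metadata contradict each other (e.g. one sample id
    carrying two different origin labels)."""


class DegenerateInputError(NirchemError, ValueError):
    """Numerically degenerate input (constant spectrum, zero-variance matrix)."""


class StructureError(NirchemError, ValueError):
    """Coefficient bookkeeping of a wavelet decomposition is inconsistent."""


class SchemeError(NirchemError, ValueError):
    """A pipeline scheme name/stage combination is not a supported scheme."""


class LeakageError(NirchemError, RuntimeError):
    """Calibration and prediction sample sets overlap."""
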