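"""Exception hierarchy for spectral decomposition errors."""


class AfspectError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(AfspectError, ValueError):
    """A peak-shape parameter is non-finite or violates its invariant."""


class DegenerateSpectrumError(AfspectError, ValueError):
    """Spectrum cannot be normalized (all-zero or non-positive maximum)."""


class NotNormalizedError(AfspectError, ValueError):
    """Operation requires a peak-100-normalized spectrum."""


class NonConvergenceError(AfspectError, RuntimeError):
    """All optimizer starts failed; carries the best attempt if any."""

    def __init__(self, message, best_result=None):
        super().__init__(message)
        self.best_result = best_result


class DegenerateFitError(AfspectError, ValueError):
    """Fit has zero total area; contributions are undefined."""


class UndefinedRatioError(AfspectError, ValueError):
    """A ratio's denominator is zero; reported as missing, never inf."""


class BandCoverageError(AfspectError, ValueError):
    """An emission band lies outside the recorded wavelength grid."""


class InsufficientDataError(AfspectError, ValueError):
    """A comparison group has fewer than two values."""


class SpectraParseError(AfspectError, ValueError):
    """Malformed spectra table; message carries offending rows."""
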