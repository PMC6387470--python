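"""Exception and warning types shared across the package."""


class AlbuminBindError(Exception):
    """Base class for all package errors."""


class SpectrumParseError(AlbuminBindError, ValueError):
    """A spectrum or table file could not be parsed; message names the line."""


class ValidationError(AlbuminBindError, ValueError):
    """A container invariant was violated (grids, signs, lengths)."""


class GridRangeError(AlbuminBindError, ValueError):
    """A wavelength/concentration grid request falls outside the data range."""


class ParameterError(AlbuminBindError, ValueError):
    """An operation parameter is out of its admissible set."""


class DomainError(AlbuminBindError, ValueError):
    """An input is outside the mathematical domain of the operation."""


class FitError(AlbuminBindError, RuntimeError):
    """A regression or nonlinear fit could not be performed or did not converge."""


class AlbuminBindWarning(UserWarning):
    """Base warning; subtypes identify the originating rule."""


class InterceptWarning(AlbuminBindWarning):
    """Stern-Volmer intercept deviates from 1 beyond 3 standard errors."""


class ExcludedPointWarning(AlbuminBindWarning):
    """Data points excluded from a fit (non-quenched, zero velocity, ...)."""


class RangeWarning(AlbuminBindWarning):
    """A derived quantity fell outside its physically expected range."""


class BaselineWarning(AlbuminBindWarning):
    """An unfolding curve does not clearly span both baselines."""


class ConsistencyWarning(AlbuminBindWarning):
    """Two independent computation routes disagree beyond tolerance."""
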