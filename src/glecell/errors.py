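"""Exception hierarchy for trajectory ingest, estimation, and fitting."""


class GleCellError(Exception):
    """Base class for all package errors."""


class SamplingError(GleCellError):
    """Time stamps are not uniformly spaced within tolerance."""


class GapError(GleCellError):
    """Missing values / NaN rows in a trajectory file."""


class LengthError(GleCellError):
    """Trajectory shorter than the configured minimum."""


class ParameterError(GleCellError):
    """Invalid user-supplied parameter (window, lag, horizon, ...)."""


class IllConditionedError(GleCellError):
    """A recursion or linear solve hit a near-zero pivot."""


class FitError(GleCellError):
    """Nonlinear least squares failed to converge."""


class DegenerateInputError(GleCellError):
    """Input carries no usable signal (zero variance, flat VACF, ...)."""


class DomainError(GleCellError):
    """Parameters outside the model's physical domain (e.g. overdamped
    hidden mode of the Markovian embedding)."""


class ResolutionError(GleCellError):
    """Time step too coarse to resolve the fastest model rate."""


class ConfigError(GleCellError):
    """Malformed pipeline or population-spec configuration."""
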