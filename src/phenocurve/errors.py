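"""Exception hierarchy shared by all phenocurve modules."""


class PhenocurveError(Exception):
    """Base class for all package-specific errors."""


class NestingError(PhenocurveError):
    """The plant/genotype/population hierarchy is not strictly nested."""


class GridError(PhenocurveError):
    """Spatial coordinates or the time grid are inconsistent."""


class DomainError(PhenocurveError):
    """Evaluation requested outside the spline knot domain."""


class ConfigError(PhenocurveError):
    """An invalid model or simulation configuration."""


class SingularityError(PhenocurveError):
    """Rank-deficient fixed-effect design."""

    def __init__(self, message, columns=None):
        super().__init__(message)
        self.columns = columns or []


class ConvergenceError(PhenocurveError):
    """REML iterations did not converge within the allowed iterations."""

    def __init__(self, message, last_fit=None):
        super().__init__(message)
        self.last_fit = last_fit


class SkippedTime(PhenocurveError):
    """All phenotype values missing at a measurement time."""


class UnknownUnit(PhenocurveError):
    """A population/genotype/plant identifier not present in the fit."""


class WindowError(PhenocurveError):
    """A trait-extraction window lies outside the modelled time domain."""


class DegenerateError(PhenocurveError):
    """A computation is undefined for the given (degenerate) input."""


class EmptyCurve(PhenocurveError):
    """Trait extraction requested from an empty curve."""
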