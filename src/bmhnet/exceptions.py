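"""Exception hierarchy shared across the package."""


class BMHError(Exception):
    """Base class for all package-specific errors."""


class DegenerateInputError(BMHError, ValueError):
    """A time-series window has zero variance (correlation undefined)."""


class InvalidLagError(BMHError, ValueError):
    """Requested lag leaves fewer than two aligned samples."""


class InvalidCorrelationError(BMHError, ValueError):
    """A correlation value lies outside [-1, 1] beyond numerical tolerance."""


class NegativeWeightError(BMHError, ValueError):
    """A distance/weight input is negative."""


class UnsupportedDegreeError(BMHError, ValueError):
    """Chain degree outside the implemented range (k <= 2, n in {0, 1})."""


class MismatchedBasesError(BMHError, ValueError):
    """Two chain bases do not belong to the same space/level/flavour."""


class ConfigurationError(BMHError, ValueError):
    """Invalid partition, grid or model configuration."""


class NonStationaryError(BMHError, ValueError):
    """VAR(1) coupling matrix has spectral radius >= 1."""


class SingleClassError(BMHError, ValueError):
    """Training data contains fewer than two classes."""


class UndefinedMetricError(BMHError, ValueError):
    """A classification metric is undefined (e.g. no positive labels)."""
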