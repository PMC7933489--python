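"""Exception hierarchy for the twosmr package."""


class TwosmrError(Exception):
    """Base class for all package errors."""


class ConfigError(TwosmrError):
    """Invalid configuration: missing columns, bad thresholds, unknown traits."""


class ValidationError(TwosmrError):
    """A record or matrix violates an invariant (se <= 0, p outside (0, 1], ...)."""


class EmptyPanelError(TwosmrError):
    """Harmonization or filtering left no usable variants."""


class InsufficientInstrumentsError(TwosmrError):
    """Too few variants for the requested fit (J <= K, or J < K + 3 for PRESSO)."""


class CollinearityError(TwosmrError):
    """The weighted normal matrix is singular; exposures are linearly dependent."""


class DegenerateFitError(TwosmrError):
    """Zero residual degrees of freedom; heterogeneity undefined."""


class UndefinedRatioError(TwosmrError):
    """Wald ratio requested with a zero exposure effect."""
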