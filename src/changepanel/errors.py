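"""Exception hierarchy shared across the package."""


class ChangePanelError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ChangePanelError, ValueError):
    """A parameter object or run configuration is invalid.

    The message names the offending field(s).
    """


class WaveNotFoundError(ChangePanelError, KeyError):
    """A requested survey wave is not present in the panel."""


class InsufficientWavesError(ChangePanelError, ValueError):
    """An estimator needs more panel waves than the data provide."""


class InsufficientDataError(ChangePanelError, ValueError):
    """Fewer observations than regression coefficients."""


class SingularDesignError(ChangePanelError, ValueError):
    """The regression design matrix is rank deficient (collinear terms)."""


class LatentColumnError(ChangePanelError, ValueError):
    """Latent diagnostic columns (u, lambda_it, y_init) were offered to an
    estimator.  Estimators may consume observable columns only."""


class UnsupportedCombinationError(ChangePanelError, NotImplementedError):
    """No closed-form probability limit is implemented for this
    estimator/data-generating-process pair."""
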