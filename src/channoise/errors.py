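"""Exception taxonomy for channoise."""


class ChannoiseError(Exception):
    """Base class for all channoise errors."""


class DegenerateKineticsError(ChannoiseError):
    """alpha + beta = 0: the subunit has no stationary relaxation."""


class InvalidRateError(ChannoiseError):
    """A transition rate evaluated to a negative or non-finite value."""


class NonErgodicSchemeError(ChannoiseError):
    """Rate matrix has more than one stationary distribution (rank deficiency > 1)."""


class OscillatorySchemeError(ChannoiseError):
    """Rate matrix has eigenvalues with a non-negligible imaginary part; the
    open-state autocovariance is not a sum of decaying real exponentials."""


class DefectiveSchemeError(ChannoiseError):
    """Rate matrix is not diagonalizable; the spectral decomposition of the
    autocovariance is outside the supported derivation."""


class StepSizeError(ChannoiseError):
    """Per-step transition probabilities are invalid at this dt (total exit
    probability >= 1 for some state)."""


class IntegrationFailureError(ChannoiseError):
    """Membrane potential diverged during integration."""

    def __init__(self, message, step=None):
        super().__init__(message)
        self.step = step


class SeriesTooShortError(ChannoiseError):
    """Time series shorter than the estimator requires."""


class ConfigError(ChannoiseError):
    """Invalid configuration document or override."""
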