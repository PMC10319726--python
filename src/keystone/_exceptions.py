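"""Exception hierarchy for the keystone package."""


class KeystoneError(Exception):
    """Base class for all errors raised by this package."""


class MalformedDataError(KeystoneError, ValueError):
    """An input table violates a basic precondition (e.g. negative values)."""


class IdentifierError(KeystoneError, ValueError):
    """Duplicate or otherwise invalid taxon/sample identifiers."""


class DegenerateSampleError(KeystoneError, ValueError):
    """A sample carries no abundance mass and cannot be normalized."""


class DegenerateProfileError(KeystoneError, ValueError):
    """All abundance mass sits on the excluded taxon; renormalization undefined."""


class UndefinedEPIError(KeystoneError, ValueError):
    """EPI requested for a taxon present in all samples or absent from all."""


class InstabilityError(KeystoneError, RuntimeError):
    """Generalized Lotka-Volterra integration diverged.

    Carries enough context (model seed, sample index if applicable) to
    reproduce the unstable trajectory.
    """

    def __init__(self, message, *, seed=None, sample=None):
        super().__init__(message)
        self.seed = seed
        self.sample = sample


class NoDataError(KeystoneError, ValueError):
    """A summary was requested but every underlying observation was invalid."""


class TooFewSamplesError(KeystoneError, ValueError):
    """Not enough samples to build a sample-similarity network."""


class TooFewTaxaError(KeystoneError, ValueError):
    """Not enough eligible taxa to run a screen."""
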