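"""Exception hierarchy shared across the package."""


class NfpMarkovError(Exception):
    """Base class for package-specific errors."""


class SchemaError(NfpMarkovError):
    """A required column or config field is missing or malformed."""


class IntegrityError(NfpMarkovError):
    """Structural violation of the panel contract (e.g. duplicate id/round)."""


class PanelValidationError(NfpMarkovError):
    """A cell value is outside its enumerated levels; message names the rows."""


class ConfigError(NfpMarkovError):
    """Invalid generator or pipeline configuration."""


class UndefinedRatioError(NfpMarkovError):
    """A net-force ratio was requested where the net force is not positive."""


class SamplerError(NfpMarkovError):
    """The MCMC sampler failed (e.g. a chain rejected every proposal)."""


class SeparationWarning(UserWarning):
    """A transition was never observed in a covariate stratum; the ML
    estimate is bounded rather than infinite."""
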