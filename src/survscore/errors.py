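"""Exception types shared across the package."""


class SurvScoreError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(SurvScoreError):
    """Invalid simulation or analysis configuration."""


class SchemaError(SurvScoreError):
    """Cohort table does not conform to the documented schema."""


class MissingDataError(SurvScoreError):
    """A required measurement is missing; the message names the field."""


class SeparationError(SurvScoreError):
    """Complete separation in a logistic fit; the message names the covariate."""


class EstimationError(SurvScoreError):
    """A statistical estimation step received degenerate input."""
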