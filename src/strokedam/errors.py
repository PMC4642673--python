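"""Exception hierarchy for strokedam.

Range violations mirror the eligibility restrictions of the calibration
cohort (age >= 18, SBP <= 200 mmHg, OTT <= 270 min); they are raised, not
silently clamped, because a prediction outside those ranges would be an
extrapolation the model was never calibrated for.
"""


class StrokeDamError(Exception):
    """Base class for all strokedam errors."""


class RangeViolationError(StrokeDamError, ValueError):
    """A patient covariate lies outside the model's supported range."""

    def __init__(self, field: str, value, message: str):
        self.field = field
        self.value = value
        super().__init__(f"{field}={value!r}: {message}")


class MissingDataError(StrokeDamError, ValueError):
    """A mandatory covariate is absent and cannot be imputed."""

    def __init__(self, field: str):
        self.field = field
        super().__init__(f"mandatory field {field!r} is missing")


class ConfigurationError(StrokeDamError, ValueError):
    """A coefficient set or score configuration is inconsistent."""


class SeparationError(StrokeDamError, RuntimeError):
    """Logistic fit failed: perfect separation or degenerate outcomes."""


class UndefinedStatisticError(StrokeDamError, ValueError):
    """A diagnostic statistic is undefined for the given data."""
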