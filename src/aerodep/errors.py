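"""Exception hierarchy shared across the pipeline."""


class AerodepError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AerodepError):
    """Invalid or infeasible configuration (bounds, missing tables, ...)."""


class InvalidCohortError(AerodepError):
    """Cohort request that cannot produce a valid virtual population."""


class DegenerateLobeError(AerodepError):
    """A lung lobe whose inspiratory volume does not exceed its expiratory one."""


class DomainError(AerodepError):
    """Physically meaningless argument (negative flow, GSD < 1, ...)."""


class NumericError(AerodepError):
    """Non-finite intermediate in the deposition computation."""


class CalibrationError(AerodepError):
    """Surrogate calibration failed to converge."""


class UndefinedRatioError(AerodepError):
    """Central-to-peripheral ratio requested with zero peripheral deposition."""


class MissingStrataError(AerodepError):
    """Statistical table lacks required patient/product/flow/region strata."""


class InsufficientPairsError(AerodepError):
    """Too few paired observations for the equivalence test."""
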