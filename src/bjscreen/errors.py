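"""Exception types shared across the package."""


class BjscreenError(Exception):
    """Base class for all package errors."""


class CohortParseError(BjscreenError):
    """A CSV row could not be parsed; the message names the offending row."""


class CohortValidationError(BjscreenError):
    """A record or cohort violates a domain invariant."""


class UndefinedRatioError(BjscreenError):
    """kappa/lambda ratio is not representable (lambda sFLC is zero)."""


class RocUndefinedError(BjscreenError):
    """ROC analysis requires at least one case and one control."""


class ConfigError(BjscreenError):
    """Invalid pipeline or simulator configuration."""
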