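"""Exception hierarchy for the mobilikit pipeline.

Every stage raises a subclass of :class:`MobilikitError` so callers can
catch pipeline failures without masking programming errors.
"""


class MobilikitError(Exception):
    """Base class for all mobilikit errors."""


class DataIntegrityError(MobilikitError, ValueError):
    """Input data violates a structural invariant (non-monotone time, NaNs...)."""


class NonUniformSamplingError(MobilikitError, ValueError):
    """Operation requires a uniform time base; resample first."""


class QuantityError(MobilikitError, ValueError):
    """Operation applied to the wrong physical quantity (e.g. integrating displacement)."""


class NoContactsError(MobilikitError, ValueError):
    """No chair-contact candidates found; caller should fall back to high-pass correction."""


class NoMovementError(MobilikitError, ValueError):
    """No suprathreshold movement found when segmenting phases."""


class AmbiguousPhaseError(MobilikitError, ValueError):
    """Phase structure does not match the expected task pattern."""


class ConfigError(MobilikitError, ValueError):
    """Invalid simulation or pipeline configuration."""


class ParseError(MobilikitError, ValueError):
    """Malformed trial file; message names file and offending line."""
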