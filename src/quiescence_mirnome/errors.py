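"""Exception hierarchy shared by all analysis stages."""


class QuiescenceMirnomeError(Exception):
    """Base class for all package-specific errors."""


class FormatError(QuiescenceMirnomeError):
    """A file did not conform to the expected on-disk format."""


class ValidationError(QuiescenceMirnomeError, ValueError):
    """An argument violated a documented precondition."""


class DegenerateInputError(ValidationError):
    """Input is technically parseable but statistically degenerate
    (zero variance, too few observations, ...)."""


class DesignError(ValidationError):
    """A design matrix could not be built or is rank-deficient."""


class ConfigError(ValidationError):
    """A configuration object violates its invariants."""
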