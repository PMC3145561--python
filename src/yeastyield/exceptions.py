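"""Exception hierarchy shared across the package."""


class YieldModelError(Exception):
    """Base class for all package-specific errors."""


class ParseError(YieldModelError):
    """A corpus file contains a malformed value; names the row and column."""


class InvariantError(YieldModelError):
    """A record violates a structural invariant (e.g. both OVE dummies set)."""


class DialectError(YieldModelError):
    """Unknown corpus dialect or header mismatch."""


class DomainError(YieldModelError):
    """An argument lies outside the operation's domain."""


class ConfigurationError(YieldModelError):
    """Inconsistent or incomplete configuration (missing coefficient, bad
    frequency spec, variant/coefficient mismatch, ...)."""


class SingularDesignError(YieldModelError):
    """Design matrix is rank deficient; carries the offending column names."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; collinear columns: "
            + ", ".join(self.columns)
        )


class InsufficientDataError(YieldModelError):
    """Fewer observations than coefficients."""
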