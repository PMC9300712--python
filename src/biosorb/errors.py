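"""Exception and warning types shared across the package."""


class BiosorbError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(BiosorbError):
    """A tabular input is missing a required column."""


class ParseError(BiosorbError):
    """A tabular input contains a cell that cannot be interpreted."""


class DomainError(BiosorbError, ValueError):
    """An input value lies outside the physical/mathematical domain of a formula."""


class SingularDesignError(BiosorbError):
    """The regression design matrix is rank deficient."""

    def __init__(self, collinear_terms):
        self.collinear_terms = list(collinear_terms)
        super().__init__(
            "design matrix is rank deficient; collinear terms: "
            + ", ".join(self.collinear_terms)
        )


class ConfigurationError(BiosorbError):
    """A configuration object is internally inconsistent or incomplete."""


class DegenerateDataWarning(UserWarning):
    """Data technically satisfies preconditions but makes an estimate meaningless."""
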