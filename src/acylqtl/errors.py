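"""Exception types shared across the pipeline."""


class AcylQTLError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(AcylQTLError):
    """A configuration value violates its documented constraints."""


class InvalidInputError(AcylQTLError):
    """An input object (map, matrix, table) is structurally unusable."""


class EmptyResultError(AcylQTLError):
    """A filter removed every sample or marker."""


class DegenerateTraitError(AcylQTLError):
    """The trait vector carries no information (constant across samples)."""


class InvalidStandardError(AcylQTLError):
    """The external quantification standard is unusable (non-positive area)."""


class InvalidExpectationError(AcylQTLError):
    """A goodness-of-fit expectation contains a zero expected count."""
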