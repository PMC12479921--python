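"""Exception hierarchy shared by all pipeline stages."""


class ClonoreactError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(ClonoreactError):
    """A file does not conform to its expected dialect (missing column,
    inconsistent dimension header, unreadable structure)."""


class ValidationError(ClonoreactError):
    """Well-formed input carrying values that violate an invariant
    (negative count, frequency outside [0,1], duplicate barcode, ...)."""


class EmptyRepertoireError(ValidationError):
    """A repertoire file contained no productive rearrangement for the
    requested locus."""


class ConfigurationError(ClonoreactError):
    """The analysis cannot proceed because a required parameter is missing
    (e.g. the ex vivo input cell count needed for pseudo-frequencies)."""


class UndefinedStatisticError(ClonoreactError):
    """A statistic is mathematically undefined for the given input
    (clonality of a single clonotype, signed-rank test with no nonzero
    differences)."""


class ParameterError(ClonoreactError):
    """A simulation or analysis parameter is outside its admissible range."""
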