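"""Exception hierarchy shared across the pipeline stages."""


class StrexpandError(Exception):
    """Base class for all package-specific errors."""


class InvalidAlphabetError(StrexpandError, ValueError):
    """A sequence contains characters outside the expected DNA alphabet."""


class UndefinedInputError(StrexpandError, ValueError):
    """An operation was called on input for which it is mathematically undefined."""


class InvalidParameterError(StrexpandError, ValueError):
    """A parameter value is outside its valid domain."""


class ConfigurationError(StrexpandError):
    """The pipeline configuration is incomplete or inconsistent (CLI exit code 2)."""


class DataError(StrexpandError):
    """An input file is malformed or inconsistent with its declared format (CLI exit code 3)."""


class InvalidLocusError(StrexpandError, ValueError):
    """A catalog locus lies outside the bounds of the reference sequence."""


class DegenerateCoreError(StrexpandError):
    """No shared core haplotype exists at the focal marker."""


class CannotEstimateError(StrexpandError):
    """The MRCA age cannot be estimated (e.g. every shared length is censored)."""


class SampleLookupError(StrexpandError, KeyError):
    """A requested sample is absent from the supplied cohort."""
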