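"""Exception hierarchy shared across the package."""


class TsmrError(Exception):
    """Base class for all package errors."""


class FormatError(TsmrError):
    """A file does not conform to the expected tabular layout."""


class ValidationError(TsmrError):
    """A record violates a domain invariant (bad allele, non-positive SE, ...)."""


class ConfigurationError(TsmrError):
    """Inconsistent inputs or options (e.g. an rsid missing from the LD matrix)."""


class InsufficientInstrumentsError(TsmrError):
    """Too few instruments for the requested estimator."""
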