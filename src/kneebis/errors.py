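"""Exception hierarchy shared across the pipeline stages."""


class KneebisError(Exception):
    """Base class for all package errors."""


class ConfigError(KneebisError, ValueError):
    """A configuration field failed validation. Message names the field."""


class FormatError(KneebisError, ValueError):
    """An input file does not conform to the expected dialect."""


class IntegrityError(KneebisError, ValueError):
    """An input file parsed but violates integrity limits (e.g. >1% malformed rows)."""


class DomainError(KneebisError, ValueError):
    """An argument is outside its mathematical domain (e.g. L <= 0)."""


class ReductionError(KneebisError, ValueError):
    """A call period could not be reduced (e.g. zero clean samples)."""


class EstimationError(KneebisError, ValueError):
    """Model estimation cannot proceed (degenerate outcome or design)."""


class UsageError(KneebisError, TypeError):
    """An operation was called with an incompatible object (e.g. ICC on a non-null fit)."""
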