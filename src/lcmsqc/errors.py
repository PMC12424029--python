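"""Exception hierarchy shared across the QC engine."""


class LcmsQcError(Exception):
    """Base class for all package errors."""


class InputError(LcmsQcError):
    """A required input (file, directory) is missing or unreadable."""


class ParseError(LcmsQcError):
    """Malformed data encountered while reading a file."""


class EmptyRunError(LcmsQcError):
    """An mzML run contained no usable spectra."""


class ConfigurationError(LcmsQcError):
    """Invalid user configuration (naming pattern, rule table, ...)."""


class QueryError(LcmsQcError):
    """Invalid query filter (e.g. a broken regular expression)."""


class StorageError(LcmsQcError):
    """The persistent store is unavailable; retryable."""
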