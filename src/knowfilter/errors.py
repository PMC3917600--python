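"""Exception hierarchy shared across the package."""


class KnowledgeError(Exception):
    """Base class for all errors raised by knowfilter."""


class IngestError(KnowledgeError):
    """A knowledge-definition file could not be ingested.

    Carries the offending file path and 1-based line number when the failure
    can be attributed to a specific line.
    """

    def __init__(self, message: str, path=None, line_no: int | None = None):
        self.path = path
        self.line_no = line_no
        if path is not None and line_no is not None:
            message = f"{path}:{line_no}: {message}"
        elif path is not None:
            message = f"{path}: {message}"
        super().__init__(message)


class FinalizedError(KnowledgeError):
    """A mutating operation was attempted on a finalized store."""


class QueryError(KnowledgeError):
    """A query was malformed (unknown entity, unsupported type combination)."""


class ConfigError(KnowledgeError):
    """Invalid configuration file, key, or command-line value."""


class InputError(KnowledgeError):
    """A user-supplied input list could not be used (missing or empty file)."""
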