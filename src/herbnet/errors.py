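"""Exception hierarchy shared across the pipeline stages."""


class HerbnetError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(HerbnetError):
    """A table is missing mandatory columns or has mismatched descriptor names."""


class ParseError(HerbnetError):
    """A file cell or line could not be interpreted; message carries the location."""


class InputError(HerbnetError):
    """A semantically invalid input (empty library, missing score, unset DL, ...)."""


class DomainError(HerbnetError, ValueError):
    """Arguments outside the mathematical domain of an operation (e.g. 0/0 Tanimoto)."""


class VocabularyError(HerbnetError):
    """A disease label outside the declared vocabulary."""


class PartitionConflictError(HerbnetError):
    """A node id appears on both sides of a bipartite network."""


class ConsistencyError(HerbnetError):
    """Cross-referenced tables disagree (e.g. catalog compound absent from a report)."""


class ConfigError(HerbnetError):
    """An invalid generator or pipeline configuration."""
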