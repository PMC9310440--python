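"""Exception hierarchy shared across the package."""


class MitobayesError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(MitobayesError):
    """Malformed configuration file or out-of-range configured value."""


class GraphError(MitobayesError):
    """Influence graph is structurally invalid (cycle, undeclared node)."""


class DomainError(MitobayesError):
    """An argument is outside the documented domain of an operation."""


class SchemaError(MitobayesError):
    """A cohort file violates the CSV schema; names row and column."""


class EvidenceError(MitobayesError):
    """Conditioning evidence matches no record, or all posterior mass is zero."""
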