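"""Exception hierarchy."""


class NoesaError(Exception):
    """Base class for all package errors."""


class ParseError(NoesaError):
    """Malformed input text; carries a line number where possible."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


class TopologyError(NoesaError):
    """Structure violates a topological invariant (atom counts, residue codes...)."""


class SelectionError(NoesaError):
    """A restraint atom selection cannot be resolved against a model."""


class RestraintConflictError(NoesaError):
    """Merged duplicate restraints have incompatible bounds."""


class ConfigError(NoesaError):
    """Invalid or inconsistent run configuration."""
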