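"""Exception hierarchy for gogcn."""


class GogcnError(Exception):
    """Base class for all package-specific errors."""


class OntologyError(GogcnError):
    """Invalid ontology structure or lookup failure."""


class CycleError(OntologyError):
    """A directed cycle was found within one sub-ontology."""

    def __init__(self, cycle):
        self.cycle = list(cycle)
        super().__init__(f"cycle detected among terms: {' -> '.join(self.cycle)}")


class ParseError(GogcnError):
    """Malformed input file; carries a line number where known."""

    def __init__(self, message, line=None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class EmptyIndexError(GogcnError):
    """Term selection or label-matrix construction produced nothing."""
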