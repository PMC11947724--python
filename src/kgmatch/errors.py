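"""Exception hierarchy."""


class KGMatchError(Exception):
    """Base class for all kgmatch errors."""


class GraphValidationError(KGMatchError):
    """A graph, node or edge violates a structural or range invariant."""


class NotADAGError(GraphValidationError):
    """A pattern graph contains a directed cycle."""


class ParseError(KGMatchError):
    """A graph file is malformed; the message names the offending record."""


class DegenerateWeightsError(KGMatchError):
    """Proportional (roulette) weighting is undefined: all weights are zero."""


class InvalidPathError(KGMatchError):
    """A node sequence is not a valid path in the data graph."""
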