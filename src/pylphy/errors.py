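"""Exception hierarchy.

Every error raised by the interpreter derives from :class:`LPhyError` so a
driver (CLI, test harness) can distinguish script problems from genuine bugs.
Parse-time and build-time errors carry enough location information to point
the user at the offending token.
"""

from __future__ import annotations


class LPhyError(Exception):
    """Base class for all interpreter errors."""


class ParseError(LPhyError):
    """Syntax error in a script, with 1-based line/column."""

    def __init__(self, message: str, line: int | None = None, column: int | None = None):
        self.line = line
        self.column = column
        loc = f" (line {line}, column {column})" if line is not None else ""
        super().__init__(message + loc)


class GraphError(LPhyError):
    """Base for errors raised while building or evaluating the model graph."""

    def __init__(self, message: str, node: str | None = None):
        self.node = node
        prefix = f"[node {node!r}] " if node else ""
        super().__init__(prefix + message)


class UnknownGenerator(GraphError):
    pass


class UnknownVariable(GraphError):
    pass


class TypeMismatch(GraphError):
    pass


class DuplicateDefinition(GraphError):
    pass


class ShapeMismatch(GraphError):
    """Observed (clamped) value does not match the generator's output shape."""


class BroadcastError(GraphError):
    """Vectorized arguments disagree on major dimension, or replicates was
    combined with implicitly broadcast arguments."""


class InvalidParameter(LPhyError):
    pass


class LengthMismatch(InvalidParameter):
    pass


class GroupSizeMismatch(InvalidParameter):
    pass


class RateLengthMismatch(InvalidParameter):
    pass


class TooFewTaxa(InvalidParameter):
    pass


class NonConvergence(LPhyError):
    """Simulation event budget exhausted (e.g. structured coalescent with
    zero migration and lineages stranded in separate demes)."""


class SimulationFailed(LPhyError):
    """A generative distribution with a legitimate failure outcome (e.g.
    serially sampled birth-death producing no samples) exhausted its retries."""


class FormatError(LPhyError):
    """Malformed input file (NEXUS/FASTA), with the offending line if known."""

    def __init__(self, message: str, line: str | None = None):
        self.offending_line = line
        suffix = f": {line!r}" if line else ""
        super().__init__(message + suffix)
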