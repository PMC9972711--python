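"""Exception hierarchy.

``LineageError`` is the base for everything raised deliberately by this
package; ``ValidationError`` marks inputs that violate a documented
contract, ``ParseError`` marks files we could not read.
"""


class LineageError(Exception):
    """Base class for errors raised by bcrlineage."""


class ValidationError(LineageError, ValueError):
    """An input violates a documented invariant (bad abundance, duplicate
    id, disconnected graph, missing sequence, ...)."""


class ParseError(LineageError, ValueError):
    """A file could not be parsed as the expected format."""
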