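"""Exception hierarchy shared across the package.

``InputError`` covers invalid arguments and malformed domain objects,
``ParseError`` covers malformed on-disk files (it carries a line number when
one is known), and ``ConstraintError`` covers well-formed requests that no
output can satisfy (e.g. an unachievable sequence-design target).
"""


class StrandfitError(Exception):
    """Base class for all package-specific errors."""


class InputError(StrandfitError, ValueError):
    """An argument violates a documented precondition."""


class ParseError(StrandfitError, ValueError):
    """A file does not conform to its dialect."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ConstraintError(StrandfitError, RuntimeError):
    """A valid request that cannot be satisfied (e.g. design search failed)."""
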