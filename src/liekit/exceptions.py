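"""Exception hierarchy.

All errors raised by liekit derive from :class:`LiekitError`, so callers
(and the CLI) can distinguish validation problems from programming errors.
"""

from __future__ import annotations


class LiekitError(Exception):
    """Base class for all liekit errors."""


class ValidationError(LiekitError):
    """Invalid domain object or argument (bad shapes, non-finite values, ...)."""


class ParseError(LiekitError):
    """A file could not be parsed; carries file path and 1-based line number."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        self.path = path
        self.line = line
        prefix = ""
        if path is not None:
            prefix = f"{path}:" if line is None else f"{path}:{line}:"
        super().__init__(f"{prefix} {message}" if prefix else message)
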