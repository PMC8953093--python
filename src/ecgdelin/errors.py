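"""Exception hierarchy.

``ValidationError`` marks a violated precondition or invariant; ``FormatError``
marks unparseable input naming the offending location; ``InsufficientDataError``
marks inputs that are well-formed but too short to support a decision, so
callers can abstain instead of failing.
"""


class ValidationError(ValueError):
    """A precondition or domain invariant was violated."""


class FormatError(ValueError):
    """A file could not be parsed in its declared format."""


class InsufficientDataError(Exception):
    """Input is valid but too short for the requested analysis."""
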