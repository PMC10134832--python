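"""Shared exception types.

``FormatError`` signals malformed input text (a file that does not follow
its tool's output dialect); ``ValidationError`` signals inputs that parse
but violate a structural contract (cycles, duplicate representatives,
unpropagated counts, ...). Both derive from :class:`ValueError` so callers
that do not care about the distinction can catch one type.
"""


class FormatError(ValueError):
    """Input text does not conform to the expected file dialect."""


class ValidationError(ValueError):
    """Parsed input violates a structural invariant."""
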