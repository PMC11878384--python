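"""Shared validation helpers."""

from __future__ import annotations


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition or invariant.

    The message always names the offending field or file location.
    """


def require(condition: bool, message: str) -> None:
    if not condition:
        raise ValidationError(message)
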