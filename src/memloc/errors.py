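"""Error type shared across the package.

Every anticipated failure carries a stable machine-readable ``code`` so
callers (and the CLI) can branch on it without parsing messages.
"""

from __future__ import annotations


class MemlocError(ValueError):
    """Package error with a stable short code (e.g. ``"cell_too_thin"``)."""

    def __init__(self, code: str, message: str | None = None):
        self.code = code
        super().__init__(message if message is not None else code)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        base = super().__str__()
        return base if base == self.code else f"{self.code}: {base}"
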