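"""Small shared helpers."""

from __future__ import annotations

import math

__all__ = ["round_half_up", "parse_decimal"]


def round_half_up(x: float) -> int:
    """Round to nearest integer with ties going up (printed-table style)."""
    return math.floor(x + 0.5)


def parse_decimal(text: str | float) -> float:
    """Parse a decimal number accepting both comma and point separators.

    European-style figures such as ``"0,029"`` appear in printed distance
    tables; this accepts them alongside ``"0.029"``.
    """
    if isinstance(text, (int, float)):
        return float(text)
    return float(text.strip().replace(",", "."))
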