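"""Small shared helpers: half-up rounding and text normalization."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

#: Characters normalized before numeric parsing. Transcribed tables may carry the
#: typographic minus (U+2212), en-dash used as a minus, or a multiplication sign.
_NUMERIC_TRANSLATION = str.maketrans({"−": "-", "–": "-", "×": "x"})


def round_half_up(value: float, decimals: int = 2) -> float:
    """Round with ties going away from zero (``round`` uses banker's rounding).

    Percentages in reports are conventionally rounded half-up, so 76.475 -> 76.48.
    """
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def normalize_label(text: str) -> str:
    """Canonical form for vocabulary matching: collapse whitespace, casefold."""
    return " ".join(text.split()).casefold()


def normalize_number_text(text: str) -> str:
    """Replace typographic minus/dash variants so ``float()`` can parse the cell."""
    return text.translate(_NUMERIC_TRANSLATION).replace(" ", "")


def try_parse_float(text: str) -> float | None:
    """Parse a numeric cell, tolerating unicode minus signs; None if not numeric."""
    try:
        return float(normalize_number_text(text))
    except ValueError:
        return None
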