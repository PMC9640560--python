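"""Functional-class distribution of a variant catalogue.

A generic tally: given per-class counts (e.g. dbSNP functional classes such as
intron, 3'UTR, 5'UTR, missense, synonymous, frameshift, nonsense, other),
report each class's percentage of the total. Class names are open strings —
this is not a dbSNP client.
"""

from __future__ import annotations

from pathlib import Path

from ._util import round_half_up


def class_percentages(counts: dict[str, int], decimals: int = 2) -> dict[str, float]:
    """Percentage of the total per class, rounded half-up to ``decimals``."""
    if any(c < 0 for c in counts.values()):
        raise ValueError("counts must be non-negative")
    total = sum(counts.values())
    if total == 0:
        raise ValueError("total count is zero")
    return {
        cls: round_half_up(100.0 * n / total, decimals) for cls, n in counts.items()
    }


def read_counts(path: str | Path) -> dict[str, int]:
    """Read a two-column (class, count) delimited table."""
    from .tables import _read_raw

    df = _read_raw(path)
    cls_col, count_col = df.columns[:2]
    return {str(rec[cls_col]): int(rec[count_col]) for _, rec in df.iterrows()}
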