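"""Canonical prediction calls shared by every tool after harmonization.

Three informative values form a total severity order
``STRONGLY_DELETERIOUS > DELETERIOUS > NEUTRAL``; ``UNKNOWN`` is outside the
order and never counts toward any vote.
"""

from __future__ import annotations

import enum


class CanonicalCall(enum.Enum):
    UNKNOWN = "unknown"
    NEUTRAL = "neutral"
    DELETERIOUS = "deleterious"
    STRONGLY_DELETERIOUS = "strongly_deleterious"

    @property
    def severity(self) -> int | None:
        """0 (neutral) .. 2 (strongly deleterious); None for UNKNOWN."""
        return _SEVERITY[self]

    @property
    def is_informative(self) -> bool:
        return self is not CanonicalCall.UNKNOWN

    def at_least(self, other: "CanonicalCall") -> bool:
        """Severity comparison; always False when either side is UNKNOWN."""
        if self.severity is None or other.severity is None:
            return False
        return self.severity >= other.severity

    def __str__(self) -> str:  # compact table rendering
        return self.value


_SEVERITY = {
    CanonicalCall.UNKNOWN: None,
    CanonicalCall.NEUTRAL: 0,
    CanonicalCall.DELETERIOUS: 1,
    CanonicalCall.STRONGLY_DELETERIOUS: 2,
}
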