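"""Amino-acid substitution variants on the TPMT protein.

Human thiopurine S-methyltransferase (TPMT) is a 245-residue enzyme; variants
are written in the conventional ``<ref><position><alt>`` one-letter notation
(e.g. ``W33G``), with residue numbering 1-based on the full UniProt sequence.
The crystal structure lacks residues 1-16; that is handled downstream as
missing structural data, never by renumbering.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Length of the human TPMT protein (UniProt P51580).
TPMT_LENGTH = 245

_SUBSTITUTION_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


class SubstitutionParseError(ValueError):
    """Raised when a substitution string cannot be interpreted."""


@dataclass(frozen=True)
class ProteinVariant:
    """A single amino-acid substitution.

    ``rsid`` (the dbSNP identifier) is provenance only: two records describing
    the same substitution compare equal whether or not an rsid is attached.
    """

    ref_aa: str
    position: int
    alt_aa: str
    rsid: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.ref_aa not in AMINO_ACIDS:
            raise SubstitutionParseError(f"unknown reference amino acid {self.ref_aa!r}")
        if self.alt_aa not in AMINO_ACIDS:
            raise SubstitutionParseError(f"unknown substituting amino acid {self.alt_aa!r}")
        if self.ref_aa == self.alt_aa:
            raise SubstitutionParseError(
                f"reference and substituting amino acid are identical in "
                f"{self.ref_aa}{self.position}{self.alt_aa}"
            )
        if not isinstance(self.position, int) or isinstance(self.position, bool):
            raise SubstitutionParseError(f"position must be an integer, got {self.position!r}")

    def __str__(self) -> str:
        return f"{self.ref_aa}{self.position}{self.alt_aa}"

    @property
    def sort_key(self) -> tuple[int, str, str]:
        return (self.position, self.alt_aa, self.ref_aa)


def parse_substitution(
    text: str,
    *,
    sequence_length: int = TPMT_LENGTH,
    rsid: str | None = None,
) -> ProteinVariant:
    """Parse ``"W33G"``-style notation into a :class:`ProteinVariant`.

    Raises :class:`SubstitutionParseError` naming the offending token for
    malformed strings, identical ref/alt, or positions outside
    ``[1, sequence_length]``.
    """
    m = _SUBSTITUTION_RE.match(text.strip())
    if m is None:
        raise SubstitutionParseError(f"malformed substitution string {text!r}")
    ref, pos_text, alt = m.group(1).upper(), m.group(2), m.group(3).upper()
    position = int(pos_text)
    if not 1 <= position <= sequence_length:
        raise SubstitutionParseError(
            f"position {position} outside [1, {sequence_length}] in {text!r}"
        )
    return ProteinVariant(ref_aa=ref, position=position, alt_aa=alt, rsid=rsid)


def variant_key(variant: object) -> tuple:
    """Deterministic ordering key: position then substituting residue.

    Plain-string identifiers (as produced by the synthetic generator) sort
    after real substitutions, lexicographically.
    """
    if isinstance(variant, ProteinVariant):
        return (0, *variant.sort_key)
    return (1, str(variant))
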