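"""Benchmarking the screen against experimentally characterized variants.

A gold-standard table lists TPMT substitutions with study-level evidence:
each report grades the variant VD ("very dangerous") or D ("dangerous").
Re-detection means the variant passes both stages of the screen run in
benchmark (lenient) mode. Variants with no structural-tool coverage (residues
absent from the crystal structure) are excluded from denominators.

Evidence classes:

* ``very_dangerous`` — at least one VD report;
* ``extremely_deleterious`` — the high-confidence subset. The operational
  membership ships as an explicit boolean column in the evidence fixture
  (the criterion "VD in several studies, or VD with corroborating further
  reports" is not fully decidable from the evidence table alone); when the
  column is absent a documented default rule is applied: >= 2 VD reports, or
  >= 1 VD report with >= 2 additional reports.
* ``all`` — every entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from ._util import round_half_up
from .screening import ScreeningResult

EVIDENCE_CLASSES = ("very_dangerous", "extremely_deleterious", "all")


@dataclass(frozen=True)
class EvidenceReport:
    study: str
    severity: str  # "VD" or "D"

    def __post_init__(self) -> None:
        if self.severity not in ("VD", "D"):
            raise ValueError(f"severity must be VD or D, got {self.severity!r}")


@dataclass(frozen=True)
class GoldStandardEntry:
    variant: object
    evidence: tuple[EvidenceReport, ...]
    very_dangerous: bool = False
    extremely_deleterious: bool = False
    explicit_extreme_flag: bool | None = None
    structural_coverage: bool = True

    def __post_init__(self) -> None:
        if not self.evidence:
            raise ValueError(f"{self.variant}: evidence list is empty")

    @property
    def n_vd(self) -> int:
        return sum(r.severity == "VD" for r in self.evidence)


def default_extreme_rule(entry: GoldStandardEntry) -> bool:
    """Fallback membership rule for the extremely-deleterious class."""
    n_other = len(entry.evidence) - entry.n_vd
    return entry.n_vd >= 2 or (entry.n_vd >= 1 and n_other >= 2)


def classify_evidence(entries: list[GoldStandardEntry]) -> list[GoldStandardEntry]:
    """Set the very-dangerous and extremely-deleterious flags on each entry."""
    out = []
    for e in entries:
        extreme = (
            e.explicit_extreme_flag
            if e.explicit_extreme_flag is not None
            else default_extreme_rule(e)
        )
        out.append(replace(e, very_dangerous=e.n_vd >= 1, extremely_deleterious=extreme))
    return out


def parse_evidence(text: str) -> tuple[EvidenceReport, ...]:
    """Parse ``"VD:77;D:84"``-style evidence strings."""
    reports = []
    for chunk in text.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        severity, _, study = chunk.partition(":")
        reports.append(EvidenceReport(study=study.strip(), severity=severity.strip()))
    return tuple(reports)


def read_gold_table(path: str | Path) -> list[GoldStandardEntry]:
    """Read a gold-standard evidence table (columns: variant, [rsid,] evidence,
    [extremely_deleterious, printed_total]) and classify it."""
    from .tables import _read_raw  # shared dialect handling
    from .variants import parse_substitution

    df = _read_raw(path)
    entries = []
    for _, rec in df.iterrows():
        rsid = rec.get("rsid", "") or None
        if rsid in ("NA", ""):
            rsid = None
        try:
            variant = parse_substitution(rec["variant"], rsid=rsid)
        except ValueError:
            variant = str(rec["variant"])
        explicit = None
        if "extremely_deleterious" in df.columns:
            explicit = str(rec["extremely_deleterious"]).strip().lower() in ("true", "1", "yes")
        entries.append(
            GoldStandardEntry(
                variant=variant,
                evidence=parse_evidence(rec["evidence"]),
                explicit_extreme_flag=explicit,
            )
        )
    return classify_evidence(entries)


@dataclass(frozen=True)
class ClassReport:
    """Re-detection tally for one evidence class."""

    n_total: int
    n_excluded: int
    n_redetected: int
    percentage: float | None  # None when the class is empty after exclusions
    redetected: tuple[str, ...] = ()

    @property
    def denominator(self) -> int:
        return self.n_total - self.n_excluded


@dataclass
class ValidationReport:
    classes: dict[str, ClassReport] = field(default_factory=dict)


def _selector(entry: GoldStandardEntry, cls: str) -> bool:
    if cls == "very_dangerous":
        return entry.very_dangerous
    if cls == "extremely_deleterious":
        return entry.extremely_deleterious
    if cls == "all":
        return True
    raise ValueError(f"unknown evidence class {cls!r}")


def redetection_rate(
    gold: list[GoldStandardEntry],
    results: list[ScreeningResult],
    evidence_class: str = "very_dangerous",
    *,
    decimals: int = 2,
) -> ClassReport:
    """Fraction of a gold-standard class re-detected by the (lenient) screen.

    Entries whose structure panel was non-evaluable are excluded from the
    denominator. Duplicate gold entries for the same substitution are
    de-duplicated before tallying.
    """
    by_variant: dict[str, ScreeningResult] = {str(r.variant): r for r in results}
    seen: set[str] = set()
    n_total = n_excluded = n_redetected = 0
    redetected: list[str] = []
    for entry in gold:
        key = str(entry.variant)
        if key in seen or not _selector(entry, evidence_class):
            continue
        seen.add(key)
        n_total += 1
        result = by_variant.get(key)
        covered = result is not None and result.struct_evaluable and entry.structural_coverage
        if not covered:
            n_excluded += 1
            continue
        if result.stage1_pass and result.stage2_pass:
            n_redetected += 1
            redetected.append(key)
    denom = n_total - n_excluded
    percentage = round_half_up(100.0 * n_redetected / denom, decimals) if denom else None
    return ClassReport(
        n_total=n_total,
        n_excluded=n_excluded,
        n_redetected=n_redetected,
        percentage=percentage,
        redetected=tuple(redetected),
    )


def validate(
    gold: list[GoldStandardEntry],
    results: list[ScreeningResult],
    evidence_classes: tuple[str, ...] = EVIDENCE_CLASSES,
) -> ValidationReport:
    report = ValidationReport()
    for cls in evidence_classes:
        report.classes[cls] = redetection_rate(gold, results, cls)
    return report
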