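"""Tool registry and harmonization rules.

The default panel mirrors the published screen: 12 sequence-based predictors
(label outputs), 8 structure-based stability predictors (label outputs, with
the MuSiC family also supporting numeric thresholds and a "Strongly Decrease"
strong-call tier), and the two CScape oncogenicity predictors (probability
scores in [0, 1]).

Numeric thresholds (exposed in config rather than hard-coded fuzziness):

* PoPMuSiC (ddG-like, kcal/mol): > 0 destabilizing; >= 4.0 strongly so.
* HoTMuSiC (dTm-like, degC):     < 0 destabilizing; <= -10.0 strongly so.
* SNPMuSiC:                      > 0 deleterious;   >= 1.0 strongly so.
* CScape / CScape-somatic:       > 0.5 oncogenic / driver (boundary exclusive).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import yaml

from ._util import normalize_label
from .calls import CanonicalCall


class ToolCategory(str, enum.Enum):
    SEQUENCE = "sequence"
    STRUCTURE = "structure"
    ONCOGENIC = "oncogenic"


class OutputKind(str, enum.Enum):
    LABEL = "label"
    SCORE = "score"


class ScoreDirection(str, enum.Enum):
    HIGHER_WORSE = "higher_worse"
    LOWER_WORSE = "lower_worse"


@dataclass(frozen=True)
class ToolSpec:
    name: str
    category: ToolCategory
    output_kind: OutputKind = OutputKind.LABEL
    strong_call_supported: bool = False


@dataclass(frozen=True)
class HarmonizationRule:
    """Vocabulary and/or numeric rule mapping raw outputs to canonical calls.

    The deleterious cutoff is exclusive ("above 0.5"), the strong cutoff
    inclusive ("close to or greater than 4" is read as >= 4 exactly; no fuzzy
    tolerance is applied).
    """

    tool: str
    deleterious_labels: frozenset[str] = frozenset()
    neutral_labels: frozenset[str] = frozenset()
    strong_labels: frozenset[str] = frozenset()
    score_direction: ScoreDirection | None = None
    deleterious_cutoff: float | None = None
    strong_cutoff: float | None = None

    def __post_init__(self) -> None:
        overlap = (
            (self.deleterious_labels & self.neutral_labels)
            | (self.deleterious_labels & self.strong_labels)
            | (self.neutral_labels & self.strong_labels)
        )
        if overlap:
            raise ValueError(f"label sets overlap for {self.tool}: {sorted(overlap)}")

    @property
    def has_score_rule(self) -> bool:
        return self.score_direction is not None and self.deleterious_cutoff is not None

    def classify_label(self, raw_label: str) -> CanonicalCall | None:
        """Look the label up in the rule's vocabularies; None when absent."""
        label = normalize_label(raw_label)
        if label in self.strong_labels:
            return CanonicalCall.STRONGLY_DELETERIOUS
        if label in self.deleterious_labels:
            return CanonicalCall.DELETERIOUS
        if label in self.neutral_labels:
            return CanonicalCall.NEUTRAL
        return None

    def classify_score(self, score: float) -> CanonicalCall:
        if not self.has_score_rule:
            raise ValueError(f"{self.tool} has no numeric harmonization rule")
        if self.score_direction is ScoreDirection.HIGHER_WORSE:
            deleterious = score > self.deleterious_cutoff
            strong = self.strong_cutoff is not None and score >= self.strong_cutoff
        else:
            deleterious = score < self.deleterious_cutoff
            strong = self.strong_cutoff is not None and score <= self.strong_cutoff
        if strong:
            return CanonicalCall.STRONGLY_DELETERIOUS
        if deleterious:
            return CanonicalCall.DELETERIOUS
        return CanonicalCall.NEUTRAL


# Shared default vocabulary. Single letters are the call codes used in the
# transcribed benchmark table (D / N / SD, plus NA handled as missing upstream).
DEFAULT_DELETERIOUS_LABELS = frozenset(
    normalize_label(s)
    for s in [
        "Deleterious", "Disease", "Effect", "Probably damaging",
        "Possibly damaging", "High", "Medium", "Destabilising",
        "Destabilizing", "Decrease", "Damaging", "Oncogenic", "Driver", "D",
    ]
)
DEFAULT_NEUTRAL_LABELS = frozenset(
    normalize_label(s)
    for s in [
        "Neutral", "Probably benign", "Benign", "Low", "Tolerated",
        "Stabilizing", "Stabilising", "Increase", "Passenger", "N",
    ]
)
DEFAULT_STRONG_LABELS = frozenset(
    normalize_label(s) for s in ["Strongly Decrease", "SD"]
)

SEQUENCE_TOOL_NAMES = (
    "PROVEAN", "PANTHER", "PolyPhen-2", "Mutation Assessor", "Meta-SNP",
    "PMut", "PredictSNP1", "SNAP2", "SuSPect", "SNPs&GO", "PhD-SNP", "SIFT",
)
STRUCTURE_TOOL_NAMES = (
    "CUPSAT", "DUET", "I-Mutant 3.0", "MUpro", "INPS-MD",
    "PoPMuSiC", "HoTMuSiC", "SNPMuSiC",
)
MUSIC_TOOL_NAMES = ("PoPMuSiC", "HoTMuSiC", "SNPMuSiC")
ONCOGENIC_TOOL_NAMES = ("CScape", "CScape-somatic")


@dataclass
class ToolRegistry:
    """Ordered collection of tools plus their harmonization rules.

    Lookup is case-insensitive on tool names. New tools can be registered from
    a YAML config without code changes.
    """

    tools: dict[str, ToolSpec] = field(default_factory=dict)
    rules: dict[str, HarmonizationRule] = field(default_factory=dict)

    def add(self, spec: ToolSpec, rule: HarmonizationRule | None = None) -> None:
        self.tools[spec.name] = spec
        if rule is not None:
            self.rules[spec.name] = rule

    def resolve(self, name: str) -> str | None:
        """Canonical registered name for ``name``, or None if unknown."""
        if name in self.tools:
            return name
        wanted = normalize_label(name)
        for registered in self.tools:
            if normalize_label(registered) == wanted:
                return registered
        return None

    def __contains__(self, name: str) -> bool:
        return self.resolve(name) is not None

    def spec(self, name: str) -> ToolSpec:
        resolved = self.resolve(name)
        if resolved is None:
            raise KeyError(f"tool {name!r} is not registered")
        return self.tools[resolved]

    def rule(self, name: str) -> HarmonizationRule:
        resolved = self.resolve(name)
        if resolved is None:
            raise KeyError(f"tool {name!r} is not registered")
        return self.rules.get(resolved, _default_rule(resolved))

    def names(self, category: ToolCategory | None = None) -> list[str]:
        if category is None:
            return list(self.tools)
        return [n for n, s in self.tools.items() if s.category is category]

    @property
    def sequence_tools(self) -> list[str]:
        return self.names(ToolCategory.SEQUENCE)

    @property
    def structure_tools(self) -> list[str]:
        return self.names(ToolCategory.STRUCTURE)

    @property
    def music_tools(self) -> list[str]:
        return [n for n, s in self.tools.items() if s.strong_call_supported]


def _default_rule(tool: str) -> HarmonizationRule:
    return HarmonizationRule(
        tool=tool,
        deleterious_labels=DEFAULT_DELETERIOUS_LABELS,
        neutral_labels=DEFAULT_NEUTRAL_LABELS,
        strong_labels=DEFAULT_STRONG_LABELS,
    )


def default_registry() -> ToolRegistry:
    """The published 12 + 8 (+2 oncogenic) panel with default rules."""
    reg = ToolRegistry()
    for name in SEQUENCE_TOOL_NAMES:
        reg.add(ToolSpec(name, ToolCategory.SEQUENCE))
    for name in STRUCTURE_TOOL_NAMES:
        strong = name in MUSIC_TOOL_NAMES
        spec = ToolSpec(name, ToolCategory.STRUCTURE, strong_call_supported=strong)
        reg.add(spec)
    base = _default_rule("")
    reg.rules["PoPMuSiC"] = replace(
        base, tool="PoPMuSiC",
        score_direction=ScoreDirection.HIGHER_WORSE,
        deleterious_cutoff=0.0, strong_cutoff=4.0,
    )
    reg.rules["HoTMuSiC"] = replace(
        base, tool="HoTMuSiC",
        score_direction=ScoreDirection.LOWER_WORSE,
        deleterious_cutoff=0.0, strong_cutoff=-10.0,
    )
    reg.rules["SNPMuSiC"] = replace(
        base, tool="SNPMuSiC",
        score_direction=ScoreDirection.HIGHER_WORSE,
        deleterious_cutoff=0.0, strong_cutoff=1.0,
    )
    for name in ONCOGENIC_TOOL_NAMES:
        reg.add(
            ToolSpec(name, ToolCategory.ONCOGENIC, OutputKind.SCORE),
            replace(
                base, tool=name,
                score_direction=ScoreDirection.HIGHER_WORSE,
                deleterious_cutoff=0.5,
            ),
        )
    return reg


def registry_from_yaml(path: str) -> ToolRegistry:
    """Extend/override the default registry from a YAML ``tools`` section.

    Schema per tool::

        tools:
          MyTool:
            category: sequence | structure | oncogenic
            output_kind: label | score
            strong_call_supported: false
            deleterious_labels: [...]
            neutral_labels: [...]
            strong_labels: [...]
            score_direction: higher_worse | lower_worse
            deleterious_cutoff: 0.5
            strong_cutoff: null
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    reg = default_registry()
    for name, cfg in (doc.get("tools") or {}).items():
        cfg = cfg or {}
        spec = ToolSpec(
            name=name,
            category=ToolCategory(cfg.get("category", "sequence")),
            output_kind=OutputKind(cfg.get("output_kind", "label")),
            strong_call_supported=bool(cfg.get("strong_call_supported", False)),
        )
        base = reg.rule(name) if name in reg else _default_rule(name)
        rule = HarmonizationRule(
            tool=name,
            deleterious_labels=frozenset(
                normalize_label(s) for s in cfg.get("deleterious_labels", [])
            ) or base.deleterious_labels,
            neutral_labels=frozenset(
                normalize_label(s) for s in cfg.get("neutral_labels", [])
            ) or base.neutral_labels,
            strong_labels=frozenset(
                normalize_label(s) for s in cfg.get("strong_labels", [])
            ) or base.strong_labels,
            score_direction=(
                ScoreDirection(cfg["score_direction"])
                if "score_direction" in cfg else base.score_direction
            ),
            deleterious_cutoff=cfg.get("deleterious_cutoff", base.deleterious_cutoff),
            strong_cutoff=cfg.get("strong_cutoff", base.strong_cutoff),
        )
        reg.add(spec, rule)
    return reg
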