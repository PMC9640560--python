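"""The two-stage consensus screen.

Stage 1 counts deleterious calls across the 12-tool sequence panel and keeps
variants with at least ``k_seq`` (default 9) such calls. Stage 2 counts
destabilizing calls across the 8-tool structure panel with threshold
``k_struct`` (default 6). The MuSiC-family stability predictors support a
"Strongly Decrease" strong-call tier; in STRICT mode (discovery) they
contribute to the stage-2 vote only when strongly destabilizing, while in
LENIENT mode (benchmark re-detection) an ordinary destabilizing call counts.
A novelty filter removes variants already established as deleterious.

``UNKNOWN`` calls count against the variant (the denominator stays the panel
size) — except that a variant whose entire structure panel is unknown (e.g. a
residue absent from the crystal structure) is flagged non-evaluable rather
than merely failing, so that benchmarks can exclude it from denominators.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import NamedTuple

from .calls import CanonicalCall
from .harmonize import PredictionMatrix
from .registry import ToolRegistry, default_registry
from .variants import ProteinVariant, parse_substitution, variant_key

logger = logging.getLogger(__name__)


class MusicMode(str, enum.Enum):
    STRICT = "strict"    # MuSiC tools vote only on "Strongly Decrease"
    LENIENT = "lenient"  # any destabilizing call votes


def _default_known() -> frozenset[ProteinVariant]:
    return frozenset({parse_substitution("Y240S")})


@dataclass(frozen=True)
class ScreeningConfig:
    """Vote thresholds and mode for the two-stage screen."""

    k_seq: int = 9
    n_seq: int = 12
    k_struct: int = 6
    n_struct: int = 8
    music_mode: MusicMode = MusicMode.STRICT
    known_deleterious: frozenset = field(default_factory=_default_known)

    def __post_init__(self) -> None:
        if not 0 < self.k_seq:
            raise ValueError("k_seq must be positive")
        if not 0 < self.k_struct:
            raise ValueError("k_struct must be positive")
        if self.n_seq <= 0 or self.n_struct <= 0:
            raise ValueError("panel sizes must be positive")

    @classmethod
    def discovery(cls, **overrides) -> "ScreeningConfig":
        return cls(**{"music_mode": MusicMode.STRICT, **overrides})

    @classmethod
    def validation(cls, **overrides) -> "ScreeningConfig":
        """Benchmark mode: lenient MuSiC counting, no novelty filter."""
        defaults = {"music_mode": MusicMode.LENIENT, "known_deleterious": frozenset()}
        return cls(**{**defaults, **overrides})


class VoteResult(NamedTuple):
    vote: int
    passed: bool
    evaluable: bool


@dataclass(frozen=True)
class ScreeningResult:
    variant: object
    seq_vote: int
    struct_vote: int
    stage1_pass: bool
    stage2_pass: bool
    novel: bool
    struct_evaluable: bool = True
    seq_evaluable: bool = True


_DELETERIOUS_SEVERITY = 1
_STRONG_SEVERITY = 2


def _panel_vote(
    row: dict[str, CanonicalCall],
    panel: frozenset[str],
    strict_set: frozenset[str],
    k: int,
) -> VoteResult:
    vote = 0
    informative = 0
    for tool, call in row.items():
        if tool not in panel:
            continue
        severity = call.severity
        if severity is None:
            continue
        informative += 1
        need = _STRONG_SEVERITY if tool in strict_set else _DELETERIOUS_SEVERITY
        if severity >= need:
            vote += 1
    if informative == 0:
        return VoteResult(vote=0, passed=False, evaluable=False)
    return VoteResult(vote=vote, passed=vote >= k, evaluable=True)


def stage1_vote(
    row: dict[str, CanonicalCall],
    config: ScreeningConfig | None = None,
    registry: ToolRegistry | None = None,
) -> VoteResult:
    """Count deleterious-or-stronger calls over the sequence panel.

    ``row`` maps tool name to canonical call; tools outside the registry's
    sequence panel are ignored. A row with no informative sequence call at all
    is non-evaluable (and fails).
    """
    config = config or ScreeningConfig()
    registry = registry or default_registry()
    return _panel_vote(
        row, frozenset(registry.sequence_tools), frozenset(), config.k_seq
    )


def stage2_vote(
    row: dict[str, CanonicalCall],
    config: ScreeningConfig | None = None,
    registry: ToolRegistry | None = None,
) -> VoteResult:
    """Count destabilizing calls over the structure panel.

    STRICT mode demands the strong-call tier from tools that support it
    (the MuSiC family); every other tool votes at DELETERIOUS or stronger.
    """
    config = config or ScreeningConfig()
    registry = registry or default_registry()
    strict = (
        frozenset(registry.music_tools)
        if config.music_mode is MusicMode.STRICT
        else frozenset()
    )
    return _panel_vote(row, frozenset(registry.structure_tools), strict, config.k_struct)


def run_screening(
    seq_matrix: PredictionMatrix,
    struct_matrix: PredictionMatrix,
    config: ScreeningConfig | None = None,
    registry: ToolRegistry | None = None,
    *,
    lazy: bool = True,
) -> list[ScreeningResult]:
    """Run the full two-stage screen.

    With ``lazy=True`` (the discovery pipeline) the structure panel is only
    consulted for stage-1 survivors; ``lazy=False`` evaluates both votes for
    every variant, which benchmark tallies (cumulative 20-tool counts) need.
    Variants present only in the structure matrix are warned about and treated
    as stage-1 failures. Results are ordered by position then substituting
    residue.
    """
    config = config or ScreeningConfig()
    registry = registry or default_registry()
    seq_keys = list(seq_matrix.calls.index)
    seq_key_set = set(seq_keys)
    struct_only = [k for k in struct_matrix.calls.index if k not in seq_key_set]
    if struct_only:
        logger.warning(
            "variants %s present in structure matrix but absent from sequence "
            "matrix; treated as stage-1 failures", struct_only,
        )
    results = []
    seq_index = set(seq_keys)
    struct_index = set(struct_matrix.calls.index)
    seq_rows = seq_matrix.calls.to_dict("index")
    struct_rows = struct_matrix.calls.to_dict("index")
    seq_panel = frozenset(registry.sequence_tools)
    struct_panel = frozenset(registry.structure_tools)
    strict_set = (
        frozenset(registry.music_tools)
        if config.music_mode is MusicMode.STRICT
        else frozenset()
    )
    for key in seq_keys + struct_only:
        variant = seq_matrix.variants.get(key, struct_matrix.variants.get(key, key))
        if key in seq_index:
            s1 = _panel_vote(seq_rows[key], seq_panel, frozenset(), config.k_seq)
        else:
            s1 = VoteResult(vote=0, passed=False, evaluable=False)
        if key in struct_index and (s1.passed or not lazy):
            s2 = _panel_vote(struct_rows[key], struct_panel, strict_set, config.k_struct)
        elif key in struct_index:
            s2 = VoteResult(vote=0, passed=False, evaluable=True)
        else:
            # no structural predictions at all for this variant
            s2 = VoteResult(vote=0, passed=False, evaluable=False)
        stage2_pass = s1.passed and s2.passed
        results.append(
            ScreeningResult(
                variant=variant,
                seq_vote=s1.vote,
                struct_vote=s2.vote,
                stage1_pass=s1.passed,
                stage2_pass=stage2_pass,
                novel=stage2_pass and variant not in config.known_deleterious,
                struct_evaluable=s2.evaluable,
                seq_evaluable=s1.evaluable,
            )
        )
    results.sort(key=lambda r: variant_key(r.variant))
    return results
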