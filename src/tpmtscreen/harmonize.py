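"""Harmonization of heterogeneous predictor outputs onto canonical calls.

Every tool in the panel speaks its own vocabulary ("Deleterious", "Probably
damaging", "Effect", "Destabilising", ...) or emits a score with its own sign
convention. This module maps each raw output onto the shared
:class:`~tpmtscreen.calls.CanonicalCall` scale, keeping the raw value as
per-cell provenance. Unrecognized labels fall into ``UNKNOWN`` with a logged
warning rather than raising: a single exotic label must not abort a screen.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from .calls import CanonicalCall
from .registry import ToolRegistry, default_registry

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RawPrediction:
    """One (variant, tool) cell as read from an input table.

    Exactly one of ``raw_label`` / ``raw_score`` / ``missing`` is populated.
    ``variant`` may be a :class:`~tpmtscreen.variants.ProteinVariant` or any
    hashable identifier (the synthetic generator uses plain strings).
    """

    variant: object
    tool: str
    raw_label: str | None = None
    raw_score: float | None = None
    missing: bool = False

    def __post_init__(self) -> None:
        populated = sum(
            [self.raw_label is not None, self.raw_score is not None, self.missing]
        )
        if populated != 1:
            raise ValueError(
                f"exactly one of raw_label/raw_score/missing must be set "
                f"({self.variant}, {self.tool})"
            )


def harmonize_label(tool: str, raw_label: str, registry: ToolRegistry | None = None) -> CanonicalCall:
    """Map a verbal prediction onto the canonical scale (case/whitespace-insensitive)."""
    registry = registry or default_registry()
    call = registry.rule(tool).classify_label(raw_label)
    if call is None:
        logger.warning("unrecognized label %r from %s mapped to UNKNOWN", raw_label, tool)
        return CanonicalCall.UNKNOWN
    return call


def harmonize_score(tool: str, raw_score: float, registry: ToolRegistry | None = None) -> CanonicalCall:
    """Map a numeric prediction onto the canonical scale via the tool's thresholds."""
    registry = registry or default_registry()
    rule = registry.rule(tool)
    if not rule.has_score_rule:
        raise ValueError(f"{tool} has no numeric harmonization rule")
    if raw_score is None or not math.isfinite(raw_score):
        logger.warning("non-finite score %r from %s mapped to UNKNOWN", raw_score, tool)
        return CanonicalCall.UNKNOWN
    return rule.classify_score(raw_score)


def harmonize(prediction: RawPrediction, registry: ToolRegistry | None = None) -> CanonicalCall:
    """Dispatch one raw prediction through the label or score pathway."""
    registry = registry or default_registry()
    if prediction.missing:
        return CanonicalCall.UNKNOWN
    if prediction.raw_label is not None:
        return harmonize_label(prediction.tool, prediction.raw_label, registry)
    rule = registry.rule(prediction.tool)
    if not rule.has_score_rule:
        logger.warning(
            "numeric value %r for label-only tool %s mapped to UNKNOWN",
            prediction.raw_score, prediction.tool,
        )
        return CanonicalCall.UNKNOWN
    return harmonize_score(prediction.tool, prediction.raw_score, registry)


@dataclass
class PredictionMatrix:
    """Dense variants x tools grid of canonical calls with raw-value provenance.

    ``calls`` and ``raw`` share index (``str(variant)``) and columns (canonical
    tool names); ``aux`` holds non-voting auxiliary columns (e.g. sub-predictor
    components) when present.
    """

    calls: pd.DataFrame
    raw: pd.DataFrame
    variants: dict[str, object] = field(default_factory=dict)
    aux: pd.DataFrame | None = None

    @property
    def n_variants(self) -> int:
        return self.calls.shape[0]

    @property
    def tools(self) -> list[str]:
        return list(self.calls.columns)

    def variant_objects(self) -> list[object]:
        return [self.variants[k] for k in self.calls.index]

    def row(self, variant: object) -> dict[str, CanonicalCall]:
        return self.calls.loc[str(variant)].to_dict()

    def subset(self, tools: list[str]) -> "PredictionMatrix":
        cols = [t for t in tools if t in self.calls.columns]
        return PredictionMatrix(
            calls=self.calls[cols], raw=self.raw[cols], variants=self.variants, aux=self.aux
        )

    def n_unknown(self) -> int:
        return int((self.calls == CanonicalCall.UNKNOWN).to_numpy().sum())


def build_matrix(
    predictions: list[RawPrediction],
    registry: ToolRegistry | None = None,
) -> PredictionMatrix:
    """Assemble raw predictions into a dense :class:`PredictionMatrix`.

    Rows appear in first-seen variant order, columns in registry order
    (restricted to tools that occur in the input); absent cells become
    ``UNKNOWN``.
    """
    registry = registry or default_registry()
    variants: dict[str, object] = {}
    resolved_names: dict[str, str | None] = {}
    call_columns: dict[str, dict[str, CanonicalCall]] = {}
    raw_columns: dict[str, dict[str, object]] = {}
    label_cache: dict[tuple[str, str], CanonicalCall] = {}
    for p in predictions:
        key = str(p.variant)
        variants.setdefault(key, p.variant)
        if p.tool not in resolved_names:
            resolved_names[p.tool] = registry.resolve(p.tool)
        tool = resolved_names[p.tool] or p.tool
        if tool not in call_columns:
            call_columns[tool] = {}
            raw_columns[tool] = {}
        if resolved_names[p.tool] is None:
            call = CanonicalCall.UNKNOWN
        elif p.raw_label is not None:
            cache_key = (tool, p.raw_label)
            if cache_key not in label_cache:
                label_cache[cache_key] = harmonize_label(tool, p.raw_label, registry)
            call = label_cache[cache_key]
        else:
            call = harmonize(p, registry)
        call_columns[tool][key] = call
        raw_columns[tool][key] = None if p.missing else (
            p.raw_label if p.raw_label is not None else p.raw_score
        )
    tools_seen = set(call_columns)
    columns = [t for t in registry.names() if t in tools_seen]
    columns += sorted(tools_seen - set(columns))  # unregistered tools last
    index = list(variants)
    calls = pd.DataFrame(index=index, columns=columns, dtype=object)
    raw = pd.DataFrame(index=index, columns=columns, dtype=object)
    for tool in columns:
        calls[tool] = pd.Series(call_columns[tool], dtype=object).reindex(index)
        raw[tool] = pd.Series(raw_columns[tool], dtype=object).reindex(index)
    calls = calls.where(calls.notna(), CanonicalCall.UNKNOWN)
    return PredictionMatrix(calls=calls, raw=raw, variants=variants)
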