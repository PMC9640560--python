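"""Readers and writers for the pipeline's tabular inputs and outputs.

Input tables are TSV (default) or CSV, in either of two layouts, auto-detected
from the header:

* wide — one row per variant, one column per tool (plus ``variant`` and an
  optional ``rsid`` column; extra ``aux_*`` columns are kept as non-voting
  auxiliary data, any other unknown column is reported and skipped);
* long — one row per (variant, tool) with columns ``variant``, ``tool`` and
  ``value`` (``label``/``score``/``call`` are accepted synonyms).

Cells equal to a configured NA token (default ``NA``, empty, ``-``) become
missing predictions. Typographic minus signs in numeric cells are normalized.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from ._util import normalize_label, round_half_up, try_parse_float
from .harmonize import RawPrediction
from .registry import ToolRegistry, default_registry
from .variants import parse_substitution

logger = logging.getLogger(__name__)

DEFAULT_NA_TOKENS = frozenset({"NA", "", "-"})

_VARIANT_SYNONYMS = {"variant", "snp", "mutation", "substitution"}
_RSID_SYNONYMS = {"rsid", "variant id", "variant_id", "dbsnp"}
_TOOL_SYNONYMS = {"tool"}
_VALUE_SYNONYMS = {"value", "label", "score", "call"}


def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def _read_raw(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep=_sep_for(path), dtype=str, keep_default_na=False, comment="#"
    )


def _is_na(cell: str, na_tokens: frozenset[str]) -> bool:
    return cell.strip().rstrip("*") in na_tokens


def _clean_rsid(cell: str, na_tokens: frozenset[str]) -> str | None:
    cell = cell.strip()
    return None if _is_na(cell, na_tokens) else cell


def _cell_to_prediction(
    variant: object, tool: str, cell: str, na_tokens: frozenset[str]
) -> RawPrediction:
    if _is_na(cell, na_tokens):
        return RawPrediction(variant=variant, tool=tool, missing=True)
    score = try_parse_float(cell)
    if score is not None:
        return RawPrediction(variant=variant, tool=tool, raw_score=score)
    return RawPrediction(variant=variant, tool=tool, raw_label=cell.strip())


def _parse_variant_cell(text: str, rsid: str | None):
    """Substitution strings become ProteinVariant; anything else stays a string."""
    try:
        return parse_substitution(text, rsid=rsid)
    except ValueError:
        return str(text)


def read_prediction_table(
    path: str | Path,
    registry: ToolRegistry | None = None,
    na_tokens: frozenset[str] = DEFAULT_NA_TOKENS,
) -> list[RawPrediction]:
    """Read a wide or long prediction table into raw predictions.

    Duplicate (variant, tool) pairs with conflicting values raise ``ValueError``
    listing the duplicates; identical duplicates are de-duplicated.
    """
    registry = registry or default_registry()
    df = _read_raw(path)
    header = {normalize_label(c): c for c in df.columns}
    is_long = bool(_TOOL_SYNONYMS & header.keys()) and bool(_VALUE_SYNONYMS & header.keys())
    predictions: list[RawPrediction] = []
    if is_long:
        tool_col = next(header[k] for k in header if k in _TOOL_SYNONYMS)
        value_col = next(header[k] for k in header if k in _VALUE_SYNONYMS)
        variant_col = next(header[k] for k in header if k in _VARIANT_SYNONYMS)
        rsid_col = next((header[k] for k in header if k in _RSID_SYNONYMS), None)
        for _, rec in df.iterrows():
            rsid = _clean_rsid(rec[rsid_col], na_tokens) if rsid_col else None
            variant = _parse_variant_cell(rec[variant_col], rsid)
            predictions.append(
                _cell_to_prediction(variant, rec[tool_col].strip(), rec[value_col], na_tokens)
            )
    else:
        variant_col = next((header[k] for k in header if k in _VARIANT_SYNONYMS), None)
        if variant_col is None:
            raise ValueError(f"{path}: no variant column found in header {list(df.columns)}")
        rsid_col = next((header[k] for k in header if k in _RSID_SYNONYMS), None)
        skipped: list[str] = []
        tool_columns: list[tuple[str, str]] = []
        for col in df.columns:
            if col in (variant_col, rsid_col) or col.startswith("aux_"):
                continue
            resolved = registry.resolve(col)
            if resolved is None:
                skipped.append(col)
            else:
                tool_columns.append((col, resolved))
        if skipped:
            logger.warning("%s: skipping unknown tool columns %s", path, skipped)
        for _, rec in df.iterrows():
            rsid = _clean_rsid(rec[rsid_col], na_tokens) if rsid_col else None
            variant = _parse_variant_cell(rec[variant_col], rsid)
            for col, tool in tool_columns:
                predictions.append(_cell_to_prediction(variant, tool, rec[col], na_tokens))

    seen: dict[tuple[str, str], RawPrediction] = {}
    conflicts: list[str] = []
    unique: list[RawPrediction] = []
    for p in predictions:
        key = (str(p.variant), p.tool)
        if key in seen:
            if (seen[key].raw_label, seen[key].raw_score, seen[key].missing) != (
                p.raw_label, p.raw_score, p.missing
            ):
                conflicts.append(f"{key[0]}/{key[1]}")
            continue
        seen[key] = p
        unique.append(p)
    if conflicts:
        raise ValueError(f"{path}: conflicting duplicate predictions for {conflicts}")
    return unique


def read_matrix(
    path: str | Path,
    registry: ToolRegistry | None = None,
    na_tokens: frozenset[str] = DEFAULT_NA_TOKENS,
):
    """Read a table and assemble it into a PredictionMatrix (keeps aux_* columns)."""
    from .harmonize import build_matrix

    registry = registry or default_registry()
    matrix = build_matrix(read_prediction_table(path, registry, na_tokens), registry)
    df = _read_raw(path)
    aux_cols = [c for c in df.columns if c.startswith("aux_")]
    if aux_cols:
        header = {normalize_label(c): c for c in df.columns}
        variant_col = next(header[k] for k in header if k in _VARIANT_SYNONYMS)
        aux = df[aux_cols].copy()
        aux.index = df[variant_col].astype(str)
        matrix.aux = aux
    return matrix


# ---------------------------------------------------------------------------
# report writing


def _write_table(df: pd.DataFrame, path: Path, float_decimals: int) -> None:
    df.to_csv(path, sep=_sep_for(path), index=False, float_format=f"%.{float_decimals}f")


def write_report(result, path: str | Path, *, float_decimals: int = 2) -> None:
    """Write a result object as a delimited table plus a JSON summary sidecar.

    Accepts a list of ScreeningResult, a ValidationReport, a relative-score
    matrix (DataFrame with a ``Total`` column) or a distribution summary
    mapping. Column order is deterministic; percentages use ``float_decimals``.
    """
    from .screening import ScreeningResult  # local import to avoid cycles
    from .validation import ValidationReport

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(result, list) and all(isinstance(r, ScreeningResult) for r in result):
        df = pd.DataFrame(
            {
                "variant": [str(r.variant) for r in result],
                "seq_vote": [r.seq_vote for r in result],
                "struct_vote": [r.struct_vote for r in result],
                "stage1_pass": [r.stage1_pass for r in result],
                "stage2_pass": [r.stage2_pass for r in result],
                "novel": [r.novel for r in result],
                "struct_evaluable": [r.struct_evaluable for r in result],
            }
        )
        summary = {
            "kind": "screening",
            "n_variants": len(result),
            "n_stage1_pass": int(df.stage1_pass.sum()),
            "n_stage2_pass": int(df.stage2_pass.sum()),
            "n_novel": int(df.novel.sum()),
        }
    elif isinstance(result, ValidationReport):
        rows = []
        for name, rep in result.classes.items():
            rows.append(
                {
                    "class": name,
                    "n_total": rep.n_total,
                    "n_excluded": rep.n_excluded,
                    "n_redetected": rep.n_redetected,
                    "percentage": rep.percentage,
                }
            )
        df = pd.DataFrame(rows)
        summary = {"kind": "validation", "classes": rows}
    elif isinstance(result, pd.DataFrame):
        df = result.round(float_decimals).reset_index(names="mutation")
        summary = {"kind": "relative_scores", "categories": list(result.columns)}
        if "Total" in result.columns:
            summary["ranking"] = list(
                result.sort_values("Total", ascending=False).index
            )
    elif isinstance(result, dict):
        df = pd.DataFrame(
            {"class": list(result), "percentage": [round_half_up(v, float_decimals) for v in result.values()]}
        )
        summary = {"kind": "distribution", "classes": {k: df.percentage[i] for i, k in enumerate(result)}}
    else:
        raise TypeError(f"cannot write report for {type(result)!r}")
    _write_table(df, path, float_decimals)
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(summary, fh, indent=2, default=str)


def read_screening_report(path: str | Path) -> pd.DataFrame:
    """Read back a screening report table (round-trip counterpart of write_report)."""
    return pd.read_csv(path, sep=_sep_for(path))
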