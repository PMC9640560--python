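"""Loaders for the reference tables bundled with the package.

The bundled TSVs transcribe the published predictor outputs for human TPMT:
the 53-variant sequence-tool screen, the structural calls for its survivors,
the experimentally characterized benchmark panel with study evidence, the
CScape-family oncogenicity scores, the MM-PBSA binding energies, amyloid
regions, conservation components and per-variant distances. Two files carry
clearly labelled synthetic stand-ins for values only available in
supplementary material; see the file headers.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .harmonize import PredictionMatrix
from .registry import ToolRegistry, default_registry
from .relscore import (
    Category,
    CategoryFeature,
    Direction,
    binding_energy_score,
    nearest_region_distance,
)
from .screening import MusicMode, ScreeningConfig, run_screening
from .tables import _read_raw, read_matrix
from .validation import GoldStandardEntry, read_gold_table
from .variants import parse_substitution

#: The five novel candidate mutations, ordered by residue position.
CANDIDATE_MUTATIONS = ("W33G", "W78R", "V89E", "W150G", "L182P")

WILD_TYPE_SYSTEM = "WT-SAH"


def data_path(name: str) -> Path:
    return Path(resources.files("tpmtscreen.data") / name)


def load_sequence_calls(registry: ToolRegistry | None = None) -> PredictionMatrix:
    """53 variants x 12 sequence tools (the stage-1 survivors table)."""
    return read_matrix(data_path("sequence_tool_calls.tsv"), registry)


def load_structure_calls(registry: ToolRegistry | None = None) -> PredictionMatrix:
    """6 variants x 8 structure tools (+ auxiliary sub-predictor columns)."""
    return read_matrix(data_path("structure_tool_calls.tsv"), registry)


def load_benchmark_sequence_calls(registry: ToolRegistry | None = None) -> PredictionMatrix:
    return read_matrix(data_path("benchmark_sequence_calls.tsv"), registry)


def load_benchmark_structure_calls(registry: ToolRegistry | None = None) -> PredictionMatrix:
    return read_matrix(data_path("benchmark_structure_calls.tsv"), registry)


def load_benchmark_evidence() -> list[GoldStandardEntry]:
    return read_gold_table(data_path("benchmark_evidence.tsv"))


def load_benchmark_printed_totals() -> dict[str, int | None]:
    df = _read_raw(data_path("benchmark_evidence.tsv"))
    out: dict[str, int | None] = {}
    for _, rec in df.iterrows():
        cell = str(rec["printed_total"]).strip()
        out[rec["variant"]] = None if cell in ("NA", "") else int(cell)
    return out


def load_oncogenic_scores() -> pd.DataFrame:
    df = _read_raw(data_path("oncogenic_scores.tsv"))
    df = df.set_index("variant")
    for col in ("CScape", "CScape-somatic"):
        df[col] = df[col].astype(float)
    return df


def load_binding_energies() -> pd.DataFrame:
    df = _read_raw(data_path("binding_energies.tsv")).set_index("system")
    return df.astype(float)


def load_amyloid_regions() -> list[tuple[int, int]]:
    df = _read_raw(data_path("amyloid_regions.tsv"))
    return [(int(r["start"]), int(r["end"])) for _, r in df.iterrows()]


def load_conservation_components() -> pd.DataFrame:
    df = _read_raw(data_path("conservation_components.tsv")).set_index("mutation")
    return df.astype(int)


def load_supplementary_features() -> pd.DataFrame:
    df = _read_raw(data_path("supplementary_synthetic_features.tsv")).set_index("mutation")
    return df.astype(float)


def load_snp_class_counts() -> dict[str, int]:
    from .distribution import read_counts

    return read_counts(data_path("snp_class_counts.tsv"))


def reference_features(
    registry: ToolRegistry | None = None,
    music_mode: MusicMode = MusicMode.STRICT,
) -> list[CategoryFeature]:
    """Assemble the raw per-category feature values for the five candidates.

    Everything derivable from the bundled call/score tables is recomputed here
    (vote counts, summed oncogenic scores, re-baselined binding energies,
    amyloid-region distances); conservation components, pocket impacts and PTM
    distances come from their fixtures.
    """
    registry = registry or default_registry()
    seq = load_sequence_calls(registry)
    struct = load_structure_calls(registry)
    results = {
        str(r.variant): r
        for r in run_screening(
            seq, struct, ScreeningConfig(music_mode=music_mode), registry, lazy=False
        )
    }
    onco = load_oncogenic_scores()
    energies = load_binding_energies()["binding_mean"]
    delta_g = binding_energy_score(
        {m: energies[m] for m in CANDIDATE_MUTATIONS}, energies[WILD_TYPE_SYSTEM]
    )
    regions = load_amyloid_regions()
    cons = load_conservation_components()
    supp = load_supplementary_features()

    features: list[CategoryFeature] = []
    for mut in CANDIDATE_MUTATIONS:
        position = parse_substitution(mut).position
        values = {
            Category.SQBT: results[mut].seq_vote,
            Category.SRBT: results[mut].struct_vote,
            Category.CONSERVATION: int(cons.loc[mut].sum()),
            Category.ONCOGENIC: float(onco.loc[mut, "CScape"] + onco.loc[mut, "CScape-somatic"]),
            Category.BPI: float(supp.loc[mut, "pocket_volume_change"]),
            Category.AFR_DIST: nearest_region_distance(position, regions),
            Category.PTM_DIST: int(supp.loc[mut, "ptm_distance"]),
            Category.MDS: delta_g[mut],
        }
        for category, value in values.items():
            features.append(
                CategoryFeature(
                    mutation=mut,
                    category=category.value,
                    value=float(value),
                    direction=category.direction,
                )
            )
    return features
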