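"""Multi-category relative deleteriousness scoring.

Each candidate mutation carries one raw value per category (consensus vote
counts, cumulative conservation, summed oncogenicity p-scores, binding-pocket
impact, distances to the nearest amyloid-forming region and PTM site, and the
change in ligand binding free energy). Within a category the raw values are
normalized to the worst mutation:

* HIGHER_WORSE categories:  rel = 100 * value / max(value)
* PROXIMITY categories:     rel = 100 - 100 * distance / max(distance)
  (closer to the feature = more deleterious, hence the inversion)

so a score of 100 marks the most deleterious mutation in that category. The
``Total`` aggregate sums a mutation's relative scores across categories and is
itself normalized to its maximum, yielding the overall ranking.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class Direction(str, enum.Enum):
    HIGHER_WORSE = "higher_worse"
    PROXIMITY = "proximity"


class Category(str, enum.Enum):
    SQBT = "SQBT"                    # sequence-based tool vote count
    SRBT = "SRBT"                    # structure-based tool vote count (strict)
    CONSERVATION = "CONSERVATION"    # cumulative conservation score
    ONCOGENIC = "ONCOGENIC"          # summed CScape-family p-scores
    BPI = "BPI"                      # binding-pocket impact (|dVolume|, A^3)
    AFR_DIST = "AFR_DIST"            # residues to nearest amyloid-forming region
    PTM_DIST = "PTM_DIST"            # residues to nearest PTM site
    MDS = "MDS"                      # binding free-energy change (kJ/mol)

    @property
    def direction(self) -> Direction:
        if self in (Category.AFR_DIST, Category.PTM_DIST):
            return Direction.PROXIMITY
        return Direction.HIGHER_WORSE


@dataclass(frozen=True)
class CategoryFeature:
    """One raw feature value for one mutation in one category."""

    mutation: str
    category: str
    value: float
    direction: Direction

    def __post_init__(self) -> None:
        if self.direction is Direction.PROXIMITY:
            if self.value < 0 or self.value != int(self.value):
                raise ValueError(
                    f"{self.mutation}/{self.category}: proximity values are "
                    f"non-negative residue counts, got {self.value}"
                )
        elif not np.isfinite(self.value):
            raise ValueError(f"{self.mutation}/{self.category}: value must be finite")


def nearest_region_distance(position: int, regions: list[tuple[int, int]]) -> int:
    """Residue distance from ``position`` to the nearest inclusive interval.

    0 when the position lies inside any region; otherwise the minimum distance
    to a region boundary.
    """
    if not regions:
        raise ValueError("region list is empty")
    best = None
    for start, end in regions:
        if start > end:
            raise ValueError(f"invalid interval ({start}, {end})")
        if start <= position <= end:
            return 0
        d = start - position if position < start else position - end
        best = d if best is None else min(best, d)
    return best


def binding_energy_score(
    mutant_dg: dict[str, float], wild_type_dg: float
) -> dict[str, float]:
    """Re-baseline binding free energies against the wild-type complex.

    Raw MM-PBSA binding energies are negative (favourable); the normalize-by-
    max recipe is ill-defined on negative values, so the category consumes
    ``dG_mutant - dG_wild_type`` in kJ/mol: larger = weaker binding = more
    deleterious (HIGHER_WORSE).
    """
    if wild_type_dg is None:
        raise ValueError("wild-type binding energy reference is required")
    return {m: dg - wild_type_dg for m, dg in mutant_dg.items()}


def relative_category_scores(features: list[CategoryFeature]) -> pd.DataFrame:
    """Normalize raw feature values to per-category relative scores in [0, 100].

    Categories missing a value for any mutation are skipped entirely (logged).
    Ties at the maximum all receive 100. A category whose maximum is 0 scores
    0 for everyone (warning); negative HIGHER_WORSE values are an error
    directing the caller to re-baseline first.
    """
    if not features:
        raise ValueError("no features supplied")
    mutations = list(dict.fromkeys(f.mutation for f in features))
    by_category: dict[str, dict[str, CategoryFeature]] = {}
    for f in features:
        by_category.setdefault(f.category, {})[f.mutation] = f
    scores = pd.DataFrame(index=mutations, dtype=float)
    for category, per_mut in by_category.items():
        missing = [m for m in mutations if m not in per_mut]
        if missing:
            logger.warning("category %s missing values for %s; skipped", category, missing)
            continue
        direction = next(iter(per_mut.values())).direction
        values = np.array([per_mut[m].value for m in mutations], dtype=float)
        if direction is Direction.HIGHER_WORSE:
            if (values < 0).any():
                raise ValueError(
                    f"category {category} has negative values; re-baseline them "
                    f"(e.g. via binding_energy_score) before relative scoring"
                )
            top = values.max()
            if top == 0:
                logger.warning("category %s has all-zero values; scores set to 0", category)
                rel = np.zeros_like(values)
            else:
                rel = 100.0 * values / top
        else:
            top = values.max()
            rel = np.full_like(values, 100.0) if top == 0 else 100.0 - 100.0 * values / top
        scores[category] = np.clip(rel, 0.0, 100.0)
    return scores


def total_score(scores: pd.DataFrame) -> pd.DataFrame:
    """Append the ``Total`` aggregate: row sums renormalized to their maximum."""
    if "Total" in scores.columns:
        scores = scores.drop(columns="Total")
    totals = scores.sum(axis=1)
    top = totals.max()
    out = scores.copy()
    out["Total"] = 100.0 * totals / top if top > 0 else 0.0
    return out


def ranking(scores: pd.DataFrame) -> list[str]:
    """Mutations ordered from most to least deleterious by Total score."""
    if "Total" not in scores.columns:
        scores = total_score(scores)
    return list(scores.sort_values("Total", ascending=False).index)


def read_features(path: str | Path) -> list[CategoryFeature]:
    """Read a features table with columns mutation, category, value, direction."""
    from .tables import _read_raw

    df = _read_raw(path)
    return [
        CategoryFeature(
            mutation=rec["mutation"],
            category=rec["category"],
            value=float(rec["value"]),
            direction=Direction(rec["direction"]),
        )
        for _, rec in df.iterrows()
    ]


def write_features(features: list[CategoryFeature], path: str | Path) -> None:
    pd.DataFrame(
        {
            "mutation": [f.mutation for f in features],
            "category": [f.category for f in features],
            "value": [f.value for f in features],
            "direction": [f.direction.value for f in features],
        }
    ).to_csv(path, sep="\t", index=False)
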