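"""Synthetic predictor panels with known ground truth, plus exact vote analytics.

The generator emulates the statistical structure the consensus screen assumes:
each variant carries a latent deleterious/benign label; conditional on that
label the tools err independently, label tools with per-tool sensitivity and
specificity, score tools by drawing from truth-conditional Gaussians that are
then harmonized through the tools' numeric thresholds. An optional one-factor
Gaussian-copula correlation knob relaxes conditional independence for
robustness studies.

The analytic twin of the k-of-n vote is the Poisson-binomial tail
``P(sum of independent Bernoulli(p_t) >= k)``, computed exactly by dynamic
programming over the per-tool probabilities (it reduces to the binomial tail
when all p_t are equal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .harmonize import RawPrediction
from .registry import (
    OutputKind,
    ScoreDirection,
    ToolCategory,
    ToolRegistry,
    default_registry,
)
from .screening import MusicMode, ScreeningConfig

DELETERIOUS_LABEL = "Deleterious"
NEUTRAL_LABEL = "Neutral"


@dataclass(frozen=True)
class LabelToolModel:
    """Binary emission model: P(deleterious call | truth)."""

    sensitivity: float = 0.9
    specificity: float = 0.9

    def __post_init__(self) -> None:
        for p in (self.sensitivity, self.specificity):
            if not 0.0 < p < 1.0:
                raise ValueError("sensitivity/specificity must lie in (0, 1)")


@dataclass(frozen=True)
class ScoreToolModel:
    """Two-component Gaussian emission: one component per truth state."""

    mean_deleterious: float
    sd_deleterious: float
    mean_benign: float
    sd_benign: float

    def params(self, truth: int) -> tuple[float, float]:
        return (
            (self.mean_deleterious, self.sd_deleterious)
            if truth
            else (self.mean_benign, self.sd_benign)
        )


def _default_score_models() -> dict[str, ScoreToolModel]:
    # Means/SDs chosen so that a truly deleterious variant is usually called
    # destabilizing but only sometimes strongly so, mirroring how the strong
    # tier behaves as a high-specificity filter.
    return {
        "PoPMuSiC": ScoreToolModel(3.0, 1.5, -0.5, 1.0),
        "HoTMuSiC": ScoreToolModel(-8.0, 3.0, 0.5, 1.0),
        "SNPMuSiC": ScoreToolModel(0.8, 0.5, -0.3, 0.4),
    }


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for a simulated screen."""

    n_variants: int = 1000
    prevalence: float = 0.3
    seed: int = 0
    missing_rate: float = 0.0
    correlation: float = 0.0  # one-factor copula loading in [0, 1)
    label_model: LabelToolModel = LabelToolModel()
    label_overrides: dict[str, LabelToolModel] = field(default_factory=dict)
    score_models: dict[str, ScoreToolModel] = field(default_factory=_default_score_models)

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must lie in [0, 1]")
        if not 0.0 <= self.correlation < 1.0:
            raise ValueError("correlation must lie in [0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")

    def label_model_for(self, tool: str) -> LabelToolModel:
        return self.label_overrides.get(tool, self.label_model)


@dataclass
class SimulationResult:
    truth: np.ndarray                 # 0/1 per variant
    variant_ids: list[str]
    seq_table: pd.DataFrame           # wide raw values (labels)
    struct_table: pd.DataFrame        # wide raw values (labels and scores)

    def predictions(self, registry: ToolRegistry) -> list[RawPrediction]:
        """Flatten both tables into raw predictions for the real pipeline."""
        preds: list[RawPrediction] = []
        for table in (self.seq_table, self.struct_table):
            for tool in table.columns:
                for vid, cell in table[tool].items():
                    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                        preds.append(RawPrediction(variant=vid, tool=tool, missing=True))
                    elif isinstance(cell, str):
                        preds.append(RawPrediction(variant=vid, tool=tool, raw_label=cell))
                    else:
                        preds.append(
                            RawPrediction(variant=vid, tool=tool, raw_score=float(cell))
                        )
        return preds


def simulate_predictions(
    config: SyntheticConfig, registry: ToolRegistry | None = None
) -> SimulationResult:
    """Draw a synthetic panel: truth labels plus raw per-tool prediction tables.

    Same seed, same config => byte-identical tables. Degenerate prevalence
    (0 or 1) is allowed; every variant then shares one truth state.
    """
    registry = registry or default_registry()
    rng = np.random.default_rng(config.seed)
    n = config.n_variants
    truth = (rng.random(n) < config.prevalence).astype(int)
    variant_ids = [f"v{i:06d}" for i in range(n)]
    rho = config.correlation
    z_common = rng.standard_normal(n)  # shared difficulty factor per variant

    def correlated_uniform() -> np.ndarray:
        eps = rng.standard_normal(n)
        return stats.norm.cdf(np.sqrt(rho) * z_common + np.sqrt(1.0 - rho) * eps)

    def emit_labels(tool: str) -> np.ndarray:
        model = config.label_model_for(tool)
        p_call = np.where(truth == 1, model.sensitivity, 1.0 - model.specificity)
        called = correlated_uniform() < p_call
        return np.where(called, DELETERIOUS_LABEL, NEUTRAL_LABEL).astype(object)

    def emit_scores(tool: str) -> np.ndarray:
        model = config.score_models[tool]
        means = np.where(truth == 1, model.mean_deleterious, model.mean_benign)
        sds = np.where(truth == 1, model.sd_deleterious, model.sd_benign)
        gauss = stats.norm.ppf(correlated_uniform())
        return means + sds * gauss

    def build_table(tools: list[str]) -> pd.DataFrame:
        table = pd.DataFrame(index=variant_ids)
        for tool in tools:
            spec = registry.spec(tool)
            if spec.output_kind is OutputKind.SCORE or tool in config.score_models:
                column = emit_scores(tool).astype(object)
            else:
                column = emit_labels(tool)
            if config.missing_rate > 0:
                column = column.copy()
                column[rng.random(n) < config.missing_rate] = None
            table[tool] = column
        return table

    seq = build_table(registry.sequence_tools)
    struct = build_table(registry.structure_tools)
    return SimulationResult(
        truth=truth, variant_ids=variant_ids, seq_table=seq, struct_table=struct
    )


# ---------------------------------------------------------------------------
# exact vote analytics


def poisson_binomial_tail(probabilities: list[float], k: int) -> float:
    """Exact ``P(X >= k)`` for a sum of independent heterogeneous Bernoullis.

    Dynamic programming over the count distribution; O(n^2), exact up to float
    rounding. ``k > n`` is an error; ``k <= 0`` returns 1.
    """
    probs = list(probabilities)
    n = len(probs)
    if k > n:
        raise ValueError(f"k={k} exceeds the number of trials n={n}")
    if k <= 0:
        return 1.0
    pmf = np.zeros(n + 1)
    pmf[0] = 1.0
    for j, p in enumerate(probs):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability out of range: {p}")
        pmf[1 : j + 2] = pmf[1 : j + 2] * (1.0 - p) + pmf[: j + 1] * p
        pmf[0] *= 1.0 - p
    return float(pmf[k:].sum())


def consensus_operating_point(
    probabilities: list[float],
    k: int,
    strict_probabilities: dict[int, float] | None = None,
) -> float:
    """Probability that a k-of-n vote passes given per-tool call probabilities.

    ``strict_probabilities`` optionally replaces the probability at given tool
    indices (e.g. the MuSiC tools' strong-call probabilities in strict mode).
    """
    probs = list(probabilities)
    for idx, p in (strict_probabilities or {}).items():
        probs[idx] = p
    return poisson_binomial_tail(probs, k)


def _score_call_probability(
    tool: str, model: ScoreToolModel, truth: int, registry: ToolRegistry, strong: bool
) -> float:
    rule = registry.rule(tool)
    mean, sd = model.params(truth)
    cutoff = rule.strong_cutoff if strong else rule.deleterious_cutoff
    if rule.score_direction is ScoreDirection.HIGHER_WORSE:
        # boundary handling matches the harmonizer: strong cutoffs inclusive,
        # deleterious cutoffs exclusive -- measure-zero under a Gaussian either way
        return float(stats.norm.sf(cutoff, loc=mean, scale=sd))
    return float(stats.norm.cdf(cutoff, loc=mean, scale=sd))


def tool_vote_probabilities(
    config: SyntheticConfig,
    registry: ToolRegistry,
    category: ToolCategory,
    truth: int,
    music_mode: MusicMode = MusicMode.STRICT,
) -> list[float]:
    """Per-tool probability of contributing to the vote, conditional on truth.

    Missing cells never vote, so each probability is scaled by the observation
    rate.
    """
    probs = []
    for tool in registry.names(category):
        spec = registry.spec(tool)
        if tool in config.score_models:
            strong = spec.strong_call_supported and music_mode is MusicMode.STRICT
            p = _score_call_probability(
                tool, config.score_models[tool], truth, registry, strong
            )
        else:
            model = config.label_model_for(tool)
            p = model.sensitivity if truth else 1.0 - model.specificity
        probs.append(p * (1.0 - config.missing_rate))
    return probs


def analytic_stage_operating_point(
    config: SyntheticConfig,
    registry: ToolRegistry,
    screening: ScreeningConfig,
    stage: int,
    truth: int = 1,
) -> float:
    """Exact pass probability of one vote stage under the synthetic model."""
    if stage == 1:
        probs = tool_vote_probabilities(config, registry, ToolCategory.SEQUENCE, truth)
        return poisson_binomial_tail(probs, screening.k_seq)
    probs = tool_vote_probabilities(
        config, registry, ToolCategory.STRUCTURE, truth, screening.music_mode
    )
    return poisson_binomial_tail(probs, screening.k_struct)


def analytic_two_stage_sensitivity(
    config: SyntheticConfig,
    registry: ToolRegistry | None = None,
    screening: ScreeningConfig | None = None,
    truth: int = 1,
) -> float:
    """Pass probability of the full two-stage screen for a variant of given truth.

    Under conditional independence the stages are independent given the truth
    label, so the joint pass probability is the product of the stage operating
    points (requires ``correlation == 0``).
    """
    registry = registry or default_registry()
    screening = screening or ScreeningConfig()
    s1 = analytic_stage_operating_point(config, registry, screening, 1, truth)
    s2 = analytic_stage_operating_point(config, registry, screening, 2, truth)
    return s1 * s2
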