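"""Relative deleteriousness scoring: normalization, inversion, Total ranking."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tpmtscreen import (
    CategoryFeature,
    Direction,
    binding_energy_score,
    nearest_region_distance,
    ranking,
    relative_category_scores,
    total_score,
)
from tpmtscreen.datasets import (
    CANDIDATE_MUTATIONS,
    load_amyloid_regions,
    load_binding_energies,
    load_oncogenic_scores,
    reference_features,
)

HW = Direction.HIGHER_WORSE
PX = Direction.PROXIMITY


def features_of(category, values, direction=HW):
    return [
        CategoryFeature(mutation=m, category=category, value=v, direction=direction)
        for m, v in values.items()
    ]


class TestNearestRegionDistance:
    @pytest.mark.parametrize(
        "position, expected",
        [(150, 1), (89, 0), (182, 0), (33, 31), (78, 8), (64, 0), (63, 1), (245, 2)],
    )
    def test_distances_on_amyloid_regions(self, position, expected):
        assert nearest_region_distance(position, load_amyloid_regions()) == expected

    def test_empty_region_list_rejected(self):
        with pytest.raises(ValueError):
            nearest_region_distance(10, [])

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            nearest_region_distance(10, [(5, 3)])


class TestBindingEnergyScore:
    def test_rebaseline_against_wild_type(self):
        energies = load_binding_energies()["binding_mean"]
        delta = binding_energy_score(
            {m: energies[m] for m in CANDIDATE_MUTATIONS}, energies["WT-SAH"]
        )
        assert delta["W33G"] == pytest.approx(154.58)
        assert delta["L182P"] == pytest.approx(36.53)
        assert max(delta, key=delta.get) == "W33G"

    def test_mutant_equal_to_wild_type_scores_zero(self):
        assert binding_energy_score({"X1Y": -138.77}, -138.77)["X1Y"] == 0.0

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError):
            binding_energy_score({"X1Y": 1.0}, None)


class TestRelativeCategoryScores:
    def test_oncogenic_worked_example(self):
        onco = load_oncogenic_scores()
        cumulative = (onco["CScape"] + onco["CScape-somatic"]).to_dict()
        scores = relative_category_scores(features_of("ONCOGENIC", cumulative))
        assert scores.loc["W33G", "ONCOGENIC"] == 100.0
        # published worked value 83.942 came from unrounded server scores;
        # the printed six-decimal table gives 83.918
        assert scores.loc["W78R", "ONCOGENIC"] == pytest.approx(83.942, rel=1e-3)

    def test_proximity_inversion(self):
        scores = relative_category_scores(
            features_of("AFR", {"a": 0, "b": 1, "c": 31}, PX)
        )
        assert scores["AFR"].tolist() == pytest.approx([100.0, 100 - 100 / 31, 0.0])

    def test_negative_higher_worse_values_direct_to_rebaseline(self):
        with pytest.raises(ValueError, match="re-baseline"):
            relative_category_scores(features_of("MDS", {"a": -5.0, "b": 3.0}))

    def test_all_zero_category_scores_zero_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            scores = relative_category_scores(features_of("X", {"a": 0.0, "b": 0.0}))
        assert (scores["X"] == 0).all()
        assert "all-zero" in caplog.text

    def test_incomplete_category_is_skipped(self, caplog):
        feats = features_of("A", {"a": 1.0, "b": 2.0}) + [
            CategoryFeature(mutation="a", category="B", value=1.0, direction=HW)
        ]
        with caplog.at_level("WARNING"):
            scores = relative_category_scores(feats)
        assert list(scores.columns) == ["A"]

    def test_proximity_values_must_be_integer_distances(self):
        with pytest.raises(ValueError):
            CategoryFeature(mutation="a", category="P", value=1.5, direction=PX)

    @given(factor=st.floats(min_value=0.01, max_value=1000))
    def test_scale_invariance(self, factor):
        base = {"a": 1.0, "b": 2.5, "c": 4.0}
        scaled = {m: v * factor for m, v in base.items()}
        s1 = relative_category_scores(features_of("C", base))
        s2 = relative_category_scores(features_of("C", scaled))
        assert np.allclose(s1["C"], s2["C"])

    @given(bump=st.floats(min_value=0.0, max_value=5.0))
    def test_monotone_in_raw_value_below_the_maximum(self, bump):
        lo = relative_category_scores(features_of("C", {"a": 2.0, "top": 10.0}))
        hi = relative_category_scores(
            features_of("C", {"a": min(2.0 + bump, 10.0), "top": 10.0})
        )
        assert hi.loc["a", "C"] >= lo.loc["a", "C"] - 1e-12


class TestTotal:
    def test_reference_ranking(self):
        scores = total_score(relative_category_scores(reference_features()))
        assert ranking(scores) == ["W33G", "W150G", "V89E", "L182P", "W78R"]
        assert scores.loc["W33G", "Total"] == 100.0
        assert (scores["Total"] == 100.0).sum() == 1

    def test_higher_worse_category_maximum_is_exactly_100(self):
        # proximity categories reach 100 only when a mutation sits at
        # distance 0 (the inversion is 100 - 100*d/max(d))
        scores = relative_category_scores(reference_features())
        higher_worse = ["SQBT", "SRBT", "CONSERVATION", "ONCOGENIC", "BPI", "MDS"]
        assert np.allclose(scores[higher_worse].max(axis=0), 100.0)
        assert scores["AFR_DIST"].max() == 100.0  # V89E and L182P at distance 0

    def test_single_mutation_totals_100(self):
        scores = total_score(relative_category_scores(features_of("C", {"only": 3.0})))
        assert scores.loc["only", "Total"] == 100.0

    def test_identical_mutations_tie_at_100(self):
        feats = features_of("A", {"x": 2.0, "y": 2.0}) + features_of(
            "B", {"x": 5.0, "y": 5.0}
        )
        scores = total_score(relative_category_scores(feats))
        assert (scores["Total"] == 100.0).all()

    def test_total_invariant_to_category_and_mutation_order(self):
        feats = reference_features()
        reordered = list(reversed(feats))
        t1 = total_score(relative_category_scores(feats))["Total"]
        t2 = total_score(relative_category_scores(reordered))["Total"]
        assert np.allclose(t1.sort_index(), t2.sort_index())
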