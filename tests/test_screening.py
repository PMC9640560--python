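"""Two-stage consensus voting, strict/lenient modes, novelty filter."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from tpmtscreen import (
    CanonicalCall,
    MusicMode,
    ScreeningConfig,
    default_registry,
    run_screening,
    stage1_vote,
    stage2_vote,
)
from tpmtscreen.variants import parse_substitution

C = CanonicalCall
REG = default_registry()
SEQ = REG.sequence_tools
STRUCT = REG.structure_tools
MUSIC = set(REG.music_tools)


def seq_row(calls):
    return dict(zip(SEQ, calls))


def struct_row(calls):
    return dict(zip(STRUCT, calls))


class TestStage1:
    def test_unanimous_row_passes(self, seq_matrix):
        vote = stage1_vote(seq_matrix.row("W33G"))
        assert vote == (12, True, True)

    def test_minimum_passing_row(self, seq_matrix):
        # F66I carries exactly nine damaging-family labels
        vote = stage1_vote(seq_matrix.row("F66I"))
        assert (vote.vote, vote.passed) == (9, True)

    def test_all_neutral_row_fails(self):
        vote = stage1_vote(seq_row([C.NEUTRAL] * 12))
        assert (vote.vote, vote.passed) == (0, False)

    def test_unknown_counts_against_the_variant(self):
        row = seq_row([C.DELETERIOUS] * 8 + [C.UNKNOWN] * 4)
        vote = stage1_vote(row)
        assert (vote.vote, vote.passed) == (8, False)

    def test_fully_unknown_row_is_non_evaluable(self):
        vote = stage1_vote(seq_row([C.UNKNOWN] * 12))
        assert vote.evaluable is False and vote.passed is False


class TestStage2:
    def test_strict_pass_with_strong_music_calls(self, struct_matrix):
        vote = stage2_vote(struct_matrix.row("W33G"), ScreeningConfig())
        assert vote == (8, True, True)

    def test_strict_vs_lenient_separation(self):
        # 5 destabilizing non-MuSiC calls + 3 plain "Decrease" MuSiC calls
        row = struct_row([C.DELETERIOUS] * 5 + [C.DELETERIOUS] * 3)
        strict = stage2_vote(row, ScreeningConfig(music_mode=MusicMode.STRICT))
        lenient = stage2_vote(row, ScreeningConfig(music_mode=MusicMode.LENIENT))
        assert (strict.vote, strict.passed) == (5, False)
        assert (lenient.vote, lenient.passed) == (8, True)

    def test_all_unknown_panel_is_non_evaluable(self, benchmark_struct):
        vote = stage2_vote(benchmark_struct.row("M1V"), ScreeningConfig())
        assert vote.evaluable is False and vote.passed is False

    def test_strong_calls_count_in_lenient_mode_too(self):
        row = struct_row([C.NEUTRAL] * 5 + [C.STRONGLY_DELETERIOUS] * 3)
        lenient = stage2_vote(row, ScreeningConfig(music_mode=MusicMode.LENIENT))
        assert lenient.vote == 3


class TestPipeline:
    def test_reference_discovery_run(self, seq_matrix, struct_matrix, registry):
        results = run_screening(seq_matrix, struct_matrix, ScreeningConfig(), registry)
        stage2 = [str(r.variant) for r in results if r.stage2_pass]
        novel = [str(r.variant) for r in results if r.novel]
        assert stage2 == ["W33G", "W78R", "V89E", "W150G", "L182P", "Y240S"]
        assert novel == ["W33G", "W78R", "V89E", "W150G", "L182P"]

    def test_empty_novelty_filter_keeps_all_passers(self, seq_matrix, struct_matrix, registry):
        config = ScreeningConfig(known_deleterious=frozenset())
        results = run_screening(seq_matrix, struct_matrix, config, registry)
        assert sum(r.novel for r in results) == 6

    def test_threshold_exceeding_panel_yields_empty_pass_set(
        self, seq_matrix, struct_matrix, registry
    ):
        results = run_screening(
            seq_matrix, struct_matrix, ScreeningConfig(k_seq=13), registry
        )
        assert not any(r.stage1_pass for r in results)

    def test_results_ordered_by_position_then_alt(self, seq_matrix, struct_matrix, registry):
        results = run_screening(seq_matrix, struct_matrix, ScreeningConfig(), registry)
        keys = [(r.variant.position, r.variant.alt_aa) for r in results]
        assert keys == sorted(keys)

    def test_struct_only_variant_warns_and_fails_stage1(
        self, struct_matrix, registry, caplog
    ):
        from tpmtscreen.harmonize import build_matrix

        empty_seq = build_matrix([], registry)
        with caplog.at_level("WARNING"):
            results = run_screening(empty_seq, struct_matrix, ScreeningConfig(), registry)
        assert "absent from sequence" in caplog.text
        assert all(not r.stage1_pass and not r.stage2_pass for r in results)

    def test_benchmark_vote_totals_match_printed_cumulative_counts(
        self, benchmark_seq, benchmark_struct, registry
    ):
        """Lenient 20-tool tallies reproduce the published cumulative column.

        Three published totals (A167G, Y240C, Y240S) disagree with their own
        published per-tool calls by one and are excluded from the comparison.
        """
        from tpmtscreen import datasets

        printed = datasets.load_benchmark_printed_totals()
        inconsistent = {"A167G", "Y240C", "Y240S"}
        results = run_screening(
            benchmark_seq, benchmark_struct, ScreeningConfig.validation(),
            registry, lazy=False,
        )
        checked = 0
        for r in results:
            name = str(r.variant)
            expected = printed.get(name)
            if expected is None or name in inconsistent:
                continue
            assert r.seq_vote + r.struct_vote == expected, name
            checked += 1
        assert checked >= 20
        by_name = {str(r.variant): r for r in results}
        assert by_name["L49S"].seq_vote + by_name["L49S"].struct_vote == 20
        assert by_name["R163P"].seq_vote + by_name["R163P"].struct_vote == 19


call_strategy = st.sampled_from(
    [C.NEUTRAL, C.DELETERIOUS, C.STRONGLY_DELETERIOUS, C.UNKNOWN]
)


@given(calls=st.lists(call_strategy, min_size=12, max_size=12))
def test_stage1_vote_agrees_with_exhaustive_count(calls):
    """Brute-force oracle: the vote equals a direct severity census."""
    expected = sum(
        1 for c in calls if c in (C.DELETERIOUS, C.STRONGLY_DELETERIOUS)
    )
    vote = stage1_vote(seq_row(calls))
    assert vote.vote == expected
    if any(c is not C.UNKNOWN for c in calls):
        assert vote.passed == (expected >= 9)


@given(
    calls=st.lists(call_strategy, min_size=8, max_size=8),
    idx=st.integers(min_value=0, max_value=7),
)
def test_vote_monotone_under_severity_upgrade(calls, idx):
    """Raising one call's severity never lowers either stage's vote."""
    upgrade = {
        C.UNKNOWN: C.NEUTRAL,
        C.NEUTRAL: C.DELETERIOUS,
        C.DELETERIOUS: C.STRONGLY_DELETERIOUS,
        C.STRONGLY_DELETERIOUS: C.STRONGLY_DELETERIOUS,
    }
    upgraded = list(calls)
    upgraded[idx] = upgrade[calls[idx]]
    for mode in (MusicMode.STRICT, MusicMode.LENIENT):
        config = ScreeningConfig(music_mode=mode)
        assert (
            stage2_vote(struct_row(upgraded), config).vote
            >= stage2_vote(struct_row(calls), config).vote
        )


@given(calls=st.lists(call_strategy, min_size=8, max_size=8))
def test_strict_pass_subset_of_lenient(calls):
    row = struct_row(calls)
    strict = stage2_vote(row, ScreeningConfig(music_mode=MusicMode.STRICT))
    lenient = stage2_vote(row, ScreeningConfig(music_mode=MusicMode.LENIENT))
    assert strict.vote <= lenient.vote
    if strict.passed:
        assert lenient.passed


@given(k=st.integers(min_value=1, max_value=12))
def test_raising_threshold_never_enlarges_pass_set(k, seq_matrix):
    lo = {
        str(r.variant)
        for r in _screen_with_k(seq_matrix, k)
    }
    hi = {
        str(r.variant)
        for r in _screen_with_k(seq_matrix, min(k + 1, 13))
    }
    assert hi <= lo


def _screen_with_k(seq_matrix, k):
    config = ScreeningConfig(k_seq=k)
    return [
        type("R", (), {"variant": key})
        for key in seq_matrix.calls.index
        if stage1_vote(seq_matrix.row(key), config).passed
    ]


def test_exhaustive_enumeration_oracle_small_panel():
    """Every 2^5 call pattern: pass/fail equals counting the combination."""
    tools = SEQ[:5]
    config = ScreeningConfig(k_seq=3, n_seq=5)
    for pattern in itertools.product([C.NEUTRAL, C.DELETERIOUS], repeat=5):
        row = dict(zip(tools, pattern))
        expected = sum(c is C.DELETERIOUS for c in pattern)
        vote = stage1_vote(row, config)
        assert vote.vote == expected
        assert vote.passed == (expected >= 3)


def test_known_deleterious_matching_ignores_rsid():
    config = ScreeningConfig(
        known_deleterious=frozenset({parse_substitution("Y240S")})
    )
    tagged = parse_substitution("Y240S", rsid="rs1142345")
    assert tagged in config.known_deleterious
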