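"""Read anchoring, QC filters, and guide-pool profiling."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from guideselect.io import ReadRecord
from guideselect.library import expected_position_profile
from guideselect.pool import (
    DropReason,
    EmptyPoolError,
    analyze_reads,
    chance_mismatch_threshold,
    match_read,
    profile_pool,
    qc_filter,
    rank_guides,
    track_enrichment,
)
from guideselect.simulate import (
    ReadSimConfig,
    SimulatedPool,
    pool_to_reads,
    sample_initial_pool,
)


def _read(seq: str, rid: str = "r") -> ReadRecord:
    return ReadRecord(rid, seq)


class TestMatchRead:
    def test_perfect_read_recovers_guide(self, spec21):
        guide = spec21.control_guide
        m = match_read(_read(spec21.reference_construct(guide)), spec21)
        assert m.drop_reason is DropReason.NONE
        assert m.guide_sequence == guide
        assert m.mismatches_outside_guide == 0
        assert m.anchor_multiplicity == 1

    def test_loop_deletion_flags_indel(self, spec21):
        seq = spec21.reference_construct()
        # delete one base inside the loop
        loop_start = len(spec21.flank_5) + len(spec21.target_sequence)
        seq = seq[: loop_start + 5] + seq[loop_start + 6 :]
        m = match_read(_read(seq), spec21)
        assert m.drop_reason is DropReason.INDEL

    def test_duplicated_construct_is_multi_anchor(self, spec21):
        seq = spec21.reference_construct() * 2
        m = match_read(_read(seq), spec21)
        assert m.drop_reason is DropReason.MULTI_ANCHOR
        assert m.anchor_multiplicity > 1

    def test_garbage_read_unanchored(self, spec21):
        m = match_read(_read("ACGT" * 30), spec21)
        assert m.drop_reason is DropReason.UNANCHORED

    def test_short_read_unanchored(self, spec21):
        m = match_read(_read("ACGTACGT"), spec21)
        assert m.drop_reason is DropReason.UNANCHORED

    def test_anchor_tolerates_one_mismatch(self, spec21):
        seq = spec21.reference_construct()
        seq = ("T" if seq[0] != "T" else "G") + seq[1:]  # mutate flank_5 base
        m = match_read(_read(seq), spec21)
        assert m.drop_reason is DropReason.NONE
        assert m.mismatches_outside_guide == 1


class TestQCFilter:
    def _with_loop_mismatches(self, spec, n):
        seq = list(spec.reference_construct())
        loop_start = len(spec.flank_5) + len(spec.target_sequence)
        for i in range(n):
            pos = loop_start + i
            seq[pos] = "A" if seq[pos] != "A" else "C"
        return "".join(seq)

    def test_boundary_of_six_mismatch_rule(self, spec21):
        # exactly six outside mismatches pass; seven are dropped
        m6 = match_read(_read(self._with_loop_mismatches(spec21, 6)), spec21)
        keep, reason = qc_filter(m6)
        assert keep and reason is DropReason.NONE
        m7 = match_read(_read(self._with_loop_mismatches(spec21, 7)), spec21)
        keep, reason = qc_filter(m7)
        assert not keep and reason is DropReason.TOO_MANY_MISMATCHES

    def test_clean_read_kept(self, spec21):
        m = match_read(_read(spec21.reference_construct()), spec21)
        assert qc_filter(m) == (True, DropReason.NONE)


class TestChanceThreshold:
    def test_zero_error_rate(self):
        assert chance_mismatch_threshold(0.0, 100, 1000) == 0

    def test_exact_binomial_tail_oracle(self):
        # brute-force tail sums, independent of scipy
        e, n_sites, n_reads = 0.001, 120, 50_000

        def tail(m):
            return sum(
                math.comb(n_sites, j) * e**j * (1 - e) ** (n_sites - j)
                for j in range(m + 1, n_sites + 1)
            )

        expected = next(m for m in range(n_sites) if n_reads * tail(m) < 1.0)
        assert chance_mismatch_threshold(e, n_sites, n_reads) == expected

    def test_monotone_in_read_count(self):
        ts = [
            chance_mismatch_threshold(0.001, 120, n)
            for n in (10, 1000, 100_000, 10_000_000)
        ]
        assert ts == sorted(ts)


class TestProfilePool:
    def test_uniform_perfect_pool(self, spec21):
        p = profile_pool([spec21.perfect_guide] * 50, spec21)
        mat = p.base_frequency_matrix
        for label in spec21.coords.labels():
            i = spec21.coords.label_to_guide_index(label)
            assert mat.loc[spec21.perfect_guide[i], label] == 1.0
        assert p.mismatch_histogram[0] == 50
        assert p.mismatch_histogram[1:].sum() == 0
        assert p.position0_tally == {"T": 50}

    def test_large_pool_matches_design(self, spec21):
        pool = sample_initial_pool(spec21, 30000, seed=8)
        p = profile_pool(pool.expand(), spec21)
        expected = expected_position_profile(spec21)
        diff = np.abs(
            p.base_frequency_matrix.to_numpy() - expected.to_numpy()
        ).max()
        assert diff < 0.02

    def test_diversity_fractions(self, spec21):
        distinct = [spec21.perfect_guide[:-1] + b for b in "ACGT"]
        p = profile_pool(distinct, spec21)
        assert p.distinct_fraction == 1.0
        assert p.singleton_fraction == 1.0
        p = profile_pool([spec21.perfect_guide] * 100, spec21)
        assert p.distinct_fraction == 0.01
        assert p.singleton_fraction == 0.0

    def test_position0_excluded_from_histogram(self, spec21):
        # the control guide's only deviation is the designed C at label 0
        p = profile_pool([spec21.control_guide] * 10, spec21)
        assert p.mismatch_histogram[0] == 10
        assert p.position0_tally == {"C": 10}

    def test_empty_pool_error(self, spec21):
        with pytest.raises(EmptyPoolError):
            profile_pool([], spec21)

    def test_n_bases_count_as_mismatch_and_renormalize(self, spec21):
        g = "N" + spec21.perfect_guide[1:]
        p = profile_pool([g, spec21.perfect_guide], spec21)
        assert p.mismatch_histogram[1] == 1  # the N counts as a mismatch
        label = spec21.coords.guide_index_to_label(0)
        col = p.base_frequency_matrix[label]
        assert col.sum() == pytest.approx(1.0)  # renormalized over A/C/G/T
        assert col[spec21.perfect_guide[0]] == 1.0


class TestRankGuides:
    def test_count_ordering(self):
        df = rank_guides(["G1"] * 5 + ["G2"] * 3)
        assert list(df["guide"]) == ["G1", "G2"]
        assert list(df["rank"]) == [1, 2]

    def test_lexicographic_tie_break(self):
        df = rank_guides(["B", "A", "C", "A", "C", "B"])
        assert list(df["guide"]) == ["A", "B", "C"]

    def test_top_k_exceeding_distinct(self):
        df = rank_guides(["X", "Y"], top_k=10)
        assert len(df) == 2

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from(["AA", "AC", "AG", "AT"]), min_size=1, max_size=30))
    def test_frequencies_sum_to_one(self, guides):
        df = rank_guides(guides)
        assert df["frequency"].sum() == pytest.approx(1.0)
        assert (df["count"].diff().dropna() <= 0).all()


class TestPipeline:
    def test_exact_recovery_on_error_free_reads(self, spec21):
        pool = sample_initial_pool(spec21, 400, seed=2)
        reads = pool_to_reads(pool, spec21, ReadSimConfig(substitution_rate=0.0))
        profile = analyze_reads(reads, spec21)
        assert profile.guide_counts == pool.counts
        assert profile.n_passing_reads == 400
        assert profile.drop_tally == {}

    def test_drop_tally_conserves_reads(self, spec21, rng):
        pool = sample_initial_pool(spec21, 300, seed=4)
        reads = pool_to_reads(
            pool, spec21, ReadSimConfig(substitution_rate=0.01, indel_rate=0.2), rng
        )
        reads.append(_read("ACGT" * 40, "junk"))
        profile = analyze_reads(reads, spec21)
        assert profile.n_passing_reads + sum(profile.drop_tally.values()) == len(reads)
        assert profile.drop_tally.get("indel", 0) > 0
        assert profile.drop_tally.get("unanchored", 0) >= 1

    def test_track_enrichment_shapes(self, spec21):
        pools = [
            SimulatedPool(Counter({spec21.perfect_guide: 8, spec21.control_guide: 2})),
            SimulatedPool(Counter({spec21.perfect_guide: 2, spec21.control_guide: 8})),
        ]
        profiles = [
            profile_pool(p.expand(), spec21, round_id=f"r{i}")
            for i, p in enumerate(pools)
        ]
        track = track_enrichment(profiles, top_k=2)
        assert track.shape == (2, 2)
        assert (track.sum(axis=0) <= 1.0 + 1e-12).all()
        assert track.loc[spec21.control_guide, "r0"] == 0.2
        assert track.loc[spec21.control_guide, "r1"] == 0.8
        absent = track_enrichment(profiles, sequences=["A" * 21])
        assert (absent.to_numpy() == 0).all()
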