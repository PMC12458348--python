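"""Anchor geometry, transcript filters, normalization, and metagene rules."""

import numpy as np
import pytest

from riboterm import (
    AnchorConfig,
    CoverageProfile,
    FootprintRead,
    assign_anchor,
    build_profile,
    frame_fractions,
    metagene_aggregate,
    normalize_by_cds,
    passes_cds_filters,
)

from conftest import make_transcript


def reads_at(tid, positions, length=29):
    return [FootprintRead(tid, p, length) for p in positions]


class TestAssignAnchor:
    def test_asite_of_minus15_read_is_the_stop_codon(self, small_transcript):
        tx = small_transcript
        read = FootprintRead(tx.transcript_id, tx.stop_start - 15, 30)
        assert assign_anchor(read, AnchorConfig(mode="asite")) == tx.stop_start

    @pytest.mark.parametrize(
        "mode,expected", [("five_prime", 100), ("psite", 112), ("asite", 115), ("three_prime", 128)]
    )
    def test_fixed_offsets_from_five_prime(self, mode, expected):
        read = FootprintRead("tx1", 100, 29)
        assert assign_anchor(read, AnchorConfig(mode=mode)) == expected

    def test_asite_is_always_3nt_downstream_of_psite(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            read = FootprintRead("tx1", int(rng.integers(0, 500)), int(rng.integers(15, 35)))
            psite = assign_anchor(read, AnchorConfig(mode="psite"))
            asite = assign_anchor(read, AnchorConfig(mode="asite"))
            assert asite - psite == 3


class TestBuildProfile:
    def test_no_reads_gives_zero_profile(self, small_transcript):
        profile = build_profile([], small_transcript)
        assert profile.total == 0

    def test_coincident_reads_stack_on_one_position(self, small_transcript):
        reads = reads_at("tx1", [12, 12, 12])
        profile = build_profile(reads, small_transcript)
        assert profile.counts[12] == 3 and profile.total == 3

    def test_totals_match_brute_force_tally(self, small_transcript):
        rng = np.random.default_rng(1)
        tx = small_transcript
        reads = [
            FootprintRead("tx1", int(rng.integers(0, 60)), int(rng.integers(15, 35)),
                          int(rng.integers(0, 4)), int(rng.integers(1, 3)))
            for _ in range(300)
        ]
        anchor = AnchorConfig(mode="psite")
        profile = build_profile(reads, tx, anchor, length_range=(20, 30))
        expected = sum(
            1
            for r in reads
            if r.n_hits == 1 and r.n_mismatches <= 2
            and 20 <= r.length <= 30
            and 0 <= r.five_prime + 12 < tx.length
        )
        assert profile.total == expected

    def test_filtered_reads_never_contribute(self, small_transcript):
        reads = [
            FootprintRead("tx1", 12, 29, n_mismatches=3),
            FootprintRead("tx1", 12, 29, n_hits=2),
            FootprintRead("tx1", 12, 29),
        ]
        profile = build_profile(reads, small_transcript)
        assert profile.total == 1

    def test_length_strata_sum_to_unstratified(self, small_transcript):
        rng = np.random.default_rng(2)
        reads = [
            FootprintRead("tx1", int(rng.integers(0, 60)), int(rng.integers(20, 32)))
            for _ in range(200)
        ]
        full = build_profile(reads, small_transcript)
        strata = [
            build_profile(reads, small_transcript, length_range=lr)
            for lr in [(20, 23), (24, 27), (28, 31)]
        ]
        np.testing.assert_array_equal(
            sum(s.counts for s in strata), full.counts
        )

    def test_wrong_transcript_read_rejected(self, small_transcript):
        with pytest.raises(ValueError, match="tx2"):
            build_profile([FootprintRead("tx2", 0, 29)], small_transcript)


class TestCdsFilters:
    def test_boundary_16_reads_10_percent_coverage_passes(self, transcript_300nt_cds):
        tx = transcript_300nt_cds
        # 30 reads on 30 distinct positions: >= 16 reads, exactly 10% coverage
        positions = [tx.cds_start + 10 * i for i in range(30)]
        counts = np.zeros(tx.length)
        counts[positions] = 1
        profile = CoverageProfile(tx.transcript_id, "five_prime", counts)
        assert passes_cds_filters(profile, tx)

    def test_exactly_16_reads_with_enough_coverage_passes(self):
        tx = make_transcript(utr5=10, n_codons=50, utr3=10, seed=3)  # 150-nt CDS
        counts = np.zeros(tx.length)
        counts[[tx.cds_start + 2 * i for i in range(16)]] = 1  # 16 reads, 16/150 > 10%
        assert passes_cds_filters(CoverageProfile(tx.transcript_id, "five_prime", counts), tx)

    def test_15_cds_reads_fails(self, transcript_300nt_cds):
        tx = transcript_300nt_cds
        counts = np.zeros(tx.length)
        counts[[tx.cds_start + i for i in range(15)]] = 1
        assert not passes_cds_filters(
            CoverageProfile(tx.transcript_id, "five_prime", counts), tx
        )

    def test_concentrated_coverage_fails(self, transcript_300nt_cds):
        tx = transcript_300nt_cds
        counts = np.zeros(tx.length)
        counts[tx.cds_start] = 100  # 1/300 positions covered
        assert not passes_cds_filters(
            CoverageProfile(tx.transcript_id, "five_prime", counts), tx
        )

    def test_utr_reads_do_not_rescue_cds_filters(self, transcript_300nt_cds):
        tx = transcript_300nt_cds
        counts = np.zeros(tx.length)
        counts[:15] = 10  # plenty of 5'UTR signal, nothing in the CDS
        assert not passes_cds_filters(
            CoverageProfile(tx.transcript_id, "five_prime", counts), tx
        )


class TestNormalization:
    def test_uniform_profile_normalizes_to_ones(self, small_transcript):
        profile = CoverageProfile("tx1", "five_prime", np.full(60, 7.0))
        normalized = normalize_by_cds(profile, small_transcript)
        np.testing.assert_allclose(normalized.counts, 1.0)

    def test_stop_window_value_scales_by_cds_mean(self, small_transcript):
        tx = small_transcript
        counts = np.full(60, 2.0)
        counts[tx.stop_start - 15] = 20.0
        # CDS mean = (2*29 + 20) / 30 = 2.6
        normalized = normalize_by_cds(
            CoverageProfile("tx1", "five_prime", counts), tx
        )
        assert normalized.counts[tx.stop_start - 15] == pytest.approx(20 / 2.6)

    @pytest.mark.parametrize("seed", range(5))
    def test_cds_mean_is_one_after_normalization(self, seed):
        tx = make_transcript(utr5=15, n_codons=30, utr3=25, seed=seed)
        rng = np.random.default_rng(seed)
        counts = rng.poisson(3.0, tx.length).astype(float) + (rng.random(tx.length) < 0.5)
        profile = CoverageProfile(tx.transcript_id, "five_prime", counts)
        normalized = normalize_by_cds(profile, tx)
        assert normalized.counts[tx.cds_start : tx.cds_end].mean() == pytest.approx(1.0)

    def test_normalization_is_idempotent(self, small_transcript):
        rng = np.random.default_rng(9)
        profile = CoverageProfile(
            "tx1", "five_prime", rng.poisson(4.0, 60).astype(float) + 1
        )
        once = normalize_by_cds(profile, small_transcript)
        twice = normalize_by_cds(once, small_transcript)
        np.testing.assert_allclose(twice.counts, once.counts)

    def test_zero_cds_counts_is_an_error(self, small_transcript):
        profile = CoverageProfile("tx1", "five_prime", np.zeros(60))
        with pytest.raises(ValueError, match="zero CDS"):
            normalize_by_cds(profile, small_transcript)


class TestMetagene:
    def test_single_uniform_transcript_gives_flat_curve(self, small_transcript):
        tx = small_transcript
        profile = CoverageProfile("tx1", "five_prime", np.ones(60))
        result = metagene_aggregate([profile], {"tx1": tx}, "stop", range(-10, 11))
        in_range = result.n_transcripts_at_offset > 0
        np.testing.assert_allclose(result.mean_density[in_range], 1.0)

    def test_identical_transcripts_equal_single_curve(self, small_transcript):
        tx = small_transcript
        rng = np.random.default_rng(3)
        counts = rng.poisson(2.0, 60).astype(float)
        profiles = [CoverageProfile("tx1", "five_prime", counts) for _ in range(5)]
        single = metagene_aggregate(profiles[:1], {"tx1": tx}, "stop", range(-20, 21))
        many = metagene_aggregate(profiles, {"tx1": tx}, "stop", range(-20, 21))
        np.testing.assert_allclose(many.mean_density, single.mean_density)

    def test_edge_offsets_average_only_covering_transcripts(self):
        # txL has a 60-nt 3'UTR and covers offset +50; txS (20-nt 3'UTR) does not
        txL = make_transcript("txL", utr5=10, n_codons=10, utr3=60, seed=4)
        txS = make_transcript("txS", utr5=10, n_codons=10, utr3=20, seed=5)
        pL = CoverageProfile("txL", "five_prime", np.full(txL.length, 3.0))
        pS = CoverageProfile("txS", "five_prime", np.full(txS.length, 1.0))
        result = metagene_aggregate(
            [pL, pS], {"txL": txL, "txS": txS}, "stop", range(0, 51)
        )
        assert result.density_at(50) == pytest.approx(3.0)  # txL alone
        assert result.density_at(10) == pytest.approx(2.0)  # both transcripts
        assert result.n_transcripts_at_offset[-1] == 1

    def test_empty_profile_set_is_an_error(self, small_transcript):
        with pytest.raises(ValueError):
            metagene_aggregate([], {"tx1": small_transcript}, "stop", range(-5, 6))

    def test_start_alignment_anchors_on_start_codon(self, small_transcript):
        tx = small_transcript
        counts = np.zeros(60)
        counts[tx.cds_start] = 5.0
        profile = CoverageProfile("tx1", "five_prime", counts)
        result = metagene_aggregate([profile], {"tx1": tx}, "start", range(-3, 4))
        assert result.density_at(0) == pytest.approx(5.0)
        assert result.density_at(1) == 0.0


class TestFrameFractions:
    def test_pure_frame0_reads(self, small_transcript):
        tx = small_transcript
        counts = np.zeros(60)
        counts[[tx.cds_start, tx.cds_start + 3, tx.cds_start + 6]] = 4
        profile = CoverageProfile("tx1", "five_prime", counts)
        assert frame_fractions(profile, tx, "cds") == (1.0, 0.0, 0.0)

    def test_fraction_arithmetic(self, small_transcript):
        tx = small_transcript
        counts = np.zeros(60)
        counts[tx.cds_start] = 2
        counts[tx.cds_start + 1] = 1
        counts[tx.cds_start + 2] = 1
        profile = CoverageProfile("tx1", "five_prime", counts)
        assert frame_fractions(profile, tx, "cds") == (0.5, 0.25, 0.25)

    def test_frame_uniform_utr3_reads_near_one_third(self):
        tx = make_transcript(utr5=10, n_codons=10, utr3=21, seed=7)  # balanced frames
        rng = np.random.default_rng(6)
        counts = np.zeros(tx.length)
        counts[tx.cds_end :] = rng.poisson(500.0, tx.utr3_length)
        profile = CoverageProfile("tx1", "five_prime", counts)
        fractions = frame_fractions(profile, tx, "utr3")
        sigma = np.sqrt((1 / 3) * (2 / 3) / counts.sum())
        assert all(abs(f - 1 / 3) < 4 * sigma for f in fractions)
        assert sum(fractions) == pytest.approx(1.0)

    def test_zero_region_counts_is_an_error(self, small_transcript):
        profile = CoverageProfile("tx1", "five_prime", np.zeros(60))
        with pytest.raises(ValueError, match="no counts"):
            frame_fractions(profile, small_transcript, "utr3")
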