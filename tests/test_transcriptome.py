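"""Transcript model, DRACH scanning, region assignment and binning."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from m6atriage.transcriptome import (
    MotifSite,
    Region,
    SegmentBinning,
    TranscriptModel,
    assign_region,
    bin_segments,
    enumerate_drach_pentamers,
    scan_drach,
    select_longest_isoform,
)

# Oligonucleotide with exactly one DRACH window (TGACT at offset 25),
# verified below against the exhaustive window oracle.
PROBE = "AGATAGCGTCCTTCTAGATTTGTGCTGACTGGAGTCACCAGCTCATACTC"


def brute_force_scan(sequence: str) -> list[int]:
    """Oracle: test every 5-mer window against the enumerated pentamer set."""
    pentamers = enumerate_drach_pentamers()
    return [
        i for i in range(len(sequence) - 4) if sequence[i : i + 5] in pentamers
    ]


def make_tx(seq, utr5=0, utr3=0, tx_id="t1"):
    return TranscriptModel(
        transcript_id=tx_id,
        gene_id="g1",
        sequence=seq,
        utr5_len=utr5,
        cds_len=len(seq) - utr5 - utr3,
        utr3_len=utr3,
    )


class TestPentamers:
    def test_cardinality_is_18(self):
        assert len(enumerate_drach_pentamers()) == 18

    def test_membership(self):
        pentamers = enumerate_drach_pentamers()
        assert "GGACT" in pentamers
        assert "CGACT" not in pentamers  # D excludes C

    def test_all_match_consensus(self):
        for p in enumerate_drach_pentamers():
            assert p[0] in "AGT" and p[1] in "AG" and p[2:4] == "AC" and p[4] in "TAC"


class TestScanDrach:
    def test_canonical_ggact(self):
        sites = scan_drach(make_tx("GGACT"))
        assert len(sites) == 1
        assert sites[0].start == 0 and sites[0].a_pos == 2

    def test_probe_sequence_single_site(self):
        sites = scan_drach(make_tx(PROBE))
        assert [s.start for s in sites] == [25]
        assert PROBE[25:30] == "TGACT"
        assert brute_force_scan(PROBE) == [25]

    def test_no_adenosine_no_sites(self):
        assert scan_drach(make_tx("CCCCCCCC")) == []

    def test_short_sequence_empty(self):
        assert scan_drach(make_tx("GGA")) == []

    def test_overlapping_matches_all_reported(self):
        seq = "GGACTGACT"  # GGACT at 0 and TGACT at 4 share one base
        starts = [s.start for s in scan_drach(make_tx(seq))]
        assert starts == brute_force_scan(seq)
        assert starts == [0, 4]

    def test_u_read_as_t(self):
        tx = make_tx("GGACU")
        assert tx.sequence == "GGACT"
        assert len(scan_drach(tx)) == 1

    def test_matches_oracle_on_random_sequences(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=300))
            tx = make_tx(seq)
            assert [s.start for s in scan_drach(tx)] == brute_force_scan(seq)
            pentamers = enumerate_drach_pentamers()
            for s in scan_drach(tx):
                assert seq[s.start : s.start + 5] in pentamers
                assert s.a_pos == s.start + 2


class TestTranscriptModel:
    def test_segment_lengths_must_tile_sequence(self):
        with pytest.raises(ValueError, match="sum"):
            TranscriptModel("t", "g", "ACGTACGT", 2, 3, 2)

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(ValueError, match="invalid"):
            TranscriptModel("t", "g", "ACGNACG", 2, 3, 2)

    def test_cds_minimum_one_codon(self):
        with pytest.raises(ValueError, match="codon"):
            TranscriptModel("t", "g", "ACGT", 1, 2, 1)


class TestAssignRegion:
    @pytest.mark.parametrize(
        "position,expected",
        [
            (0, Region.UTR5),
            (9, Region.UTR5),
            (10, Region.CDS),  # half-open boundary
            (39, Region.CDS),
            (40, Region.UTR3),
            (59, Region.UTR3),
        ],
    )
    def test_boundaries(self, toy_transcript, position, expected):
        assert assign_region(toy_transcript, position) is expected

    def test_out_of_range_raises(self, toy_transcript):
        with pytest.raises(ValueError):
            assign_region(toy_transcript, 60)
        with pytest.raises(ValueError):
            assign_region(toy_transcript, -1)

    def test_motif_region_follows_a_pos(self, toy_transcript):
        regions = {s.start: s.region for s in scan_drach(toy_transcript)}
        assert regions[2] is Region.UTR5
        assert regions[20] is Region.CDS
        assert regions[42] is Region.UTR3


class TestBinning:
    def test_even_division(self):
        edges = SegmentBinning.bin_edges(100, 10)
        assert edges == list(range(0, 101, 10))

    def test_uneven_division_floor_formula(self):
        assert SegmentBinning.bin_edges(10, 3) == [0, 3, 6, 10]

    def test_bin_segments_is_partition(self, toy_transcript):
        binning = SegmentBinning(2, 3, 2)
        mapping = bin_segments(toy_transcript, binning)
        assert mapping.shape == (toy_transcript.length,)
        # contiguous non-decreasing global bins covering 0..n_total-1
        assert set(mapping) == set(range(binning.n_total))
        assert (np.diff(mapping) >= 0).all()

    def test_zero_length_segment_contributes_no_positions(self):
        tx = make_tx("ATGAAACAT", utr5=0, utr3=0)
        mapping = bin_segments(tx, SegmentBinning(1, 3, 1))
        # all positions are CDS bins (offsets 1..3 of the 5-bin layout)
        assert set(mapping) == {1, 2, 3}

    def test_over_binning_rejected(self, toy_transcript):
        with pytest.raises(ValueError, match="bins"):
            bin_segments(toy_transcript, SegmentBinning(11, 3, 2))

    @given(
        length=st.integers(min_value=1, max_value=500),
        n_bins=st.integers(min_value=1, max_value=50),
    )
    @settings(max_examples=200, deadline=None)
    def test_edges_partition_any_segment(self, length, n_bins):
        if n_bins > length:
            return
        edges = SegmentBinning.bin_edges(length, n_bins)
        sizes = np.diff(edges)
        assert edges[0] == 0 and edges[-1] == length
        assert sizes.min() >= 1
        assert sizes.max() - sizes.min() <= 1

    def test_position_to_bin_agrees_with_edges(self, toy_transcript):
        binning = SegmentBinning(2, 3, 4)
        mapping = bin_segments(toy_transcript, binning)
        for pos in range(toy_transcript.length):
            assert binning.global_bin(toy_transcript, pos) == mapping[pos]


class TestLongestIsoform:
    def test_longest_wins(self):
        short = make_tx("A" * 10 + "AAC" + "T" * 7, tx_id="T9")
        long = make_tx("A" * 30 + "AAC" + "T" * 17, tx_id="T8")
        chosen = select_longest_isoform({"g1": [short, long]})
        assert chosen["g1"].transcript_id == "T8"

    def test_single_isoform_identity(self):
        only = make_tx("GGACTGGACT")
        assert select_longest_isoform({"g1": [only]})["g1"] is only

    def test_tie_breaks_lexicographically(self):
        a = make_tx("GGACTGGACT", tx_id="T2")
        b = make_tx("TTTTTGGACT", tx_id="T1")
        assert select_longest_isoform({"g1": [a, b]})["g1"].transcript_id == "T1"

    def test_empty_isoform_list_rejected(self):
        with pytest.raises(ValueError):
            select_longest_isoform({"g1": []})
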