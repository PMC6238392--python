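"""IP/input adjustment, peak calling and methylated-DRACH statistics."""

import numpy as np
import pytest

from m6atriage.m6a_calling import (
    AdjustedProfile,
    Assay,
    Condition,
    CoverageProfile,
    adjust_profile,
    assign_peaks_to_motifs,
    call_peaks,
    merge_coverage_replicates,
    metagene_methylation,
    methylation_summary,
    normalize_profile,
    stress_induced_sites,
)
from m6atriage.transcriptome import MotifSite, Region, SegmentBinning, scan_drach


def profile(counts, tx="t1", assay=Assay.M6A_IP, cond=Condition.CONTROL, lib=1e6):
    return CoverageProfile(
        transcript_id=tx, assay=assay, condition=cond, replicate=1,
        counts=np.asarray(counts, dtype=float), library_size=lib,
    )


def adjusted(values, tx="t1", excluded=False):
    return AdjustedProfile(
        transcript_id=tx, values=np.asarray(values, dtype=float),
        excluded=excluded, reason="LOW_COVERAGE" if excluded else "NONE",
    )


def site(start, tx="t1", region=Region.CDS):
    return MotifSite(transcript_id=tx, start=start, a_pos=start + 2, region=region)


class TestNormalize:
    def test_constant_profile_normalizes_to_one(self):
        assert np.allclose(normalize_profile(np.full(8, 8.0)), 1.0)

    def test_mean_division(self):
        assert np.allclose(normalize_profile([0, 0, 30]), [0, 0, 3.0])

    def test_all_zero_stays_zero(self):
        assert np.allclose(normalize_profile(np.zeros(5)), 0.0)


class TestAdjust:
    def test_identical_ip_and_input_cancel(self):
        counts = [20.0, 40.0, 20.0]
        adj = adjust_profile(profile(counts), profile(counts, assay=Assay.RNA_INPUT))
        assert np.allclose(adj.values, 0.0)
        assert not adj.excluded

    def test_low_coverage_exclusion_on_raw_ip_max(self):
        adj = adjust_profile(
            profile([14.0, 10.0, 2.0]), profile([5.0, 5.0, 5.0])
        )
        assert adj.excluded and adj.reason == "LOW_COVERAGE"

    def test_boundary_15_is_kept(self):
        adj = adjust_profile(profile([15.0, 0.0]), profile([1.0, 1.0]))
        assert not adj.excluded

    def test_two_step_formula(self):
        adj = adjust_profile(profile([30, 10, 20]), profile([5, 10, 15]))
        assert np.allclose(adj.values, [1.0, -0.5, -0.5])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            adjust_profile(profile([20, 20]), profile([1, 1, 1]))


class TestCallPeaks:
    def test_flat_zero_no_peaks(self):
        assert call_peaks(adjusted(np.zeros(100))) == []

    def test_single_plateau(self):
        values = np.zeros(100)
        values[40:60] = 2.0
        peaks = call_peaks(adjusted(values), tau=0.5, min_width=10)
        assert len(peaks) == 1
        assert (peaks[0].start, peaks[0].end, peaks[0].height) == (40, 60, 2.0)

    def test_narrow_run_filtered(self):
        values = np.zeros(100)
        values[10:15] = 2.0
        assert call_peaks(adjusted(values), min_width=10) == []

    def test_excluded_profile_yields_nothing(self):
        values = np.ones(100) * 5
        assert call_peaks(adjusted(values, excluded=True)) == []

    def test_raising_tau_never_widens_coverage(self):
        rng = np.random.default_rng(3)
        values = rng.normal(0, 1, size=500)
        covered = []
        for tau in (0.2, 0.5, 1.0, 2.0):
            peaks = call_peaks(adjusted(values), tau=tau, min_width=3)
            covered.append(sum(p.end - p.start for p in peaks))
        assert covered == sorted(covered, reverse=True)

    def test_run_at_array_edges(self):
        values = np.ones(12) * 2.0
        peaks = call_peaks(adjusted(values), min_width=10)
        assert len(peaks) == 1 and peaks[0].start == 0 and peaks[0].end == 12


class TestAssignPeaks:
    def make_peak(self, start, end):
        from m6atriage.m6a_calling import PeakInterval

        return PeakInterval(transcript_id="t1", start=start, end=end, height=2.0)

    def test_peak_covering_two_motifs_yields_two_calls(self):
        calls = assign_peaks_to_motifs(
            [self.make_peak(0, 50)], [site(10), site(30)], Condition.CONTROL
        )
        assert len(calls) == 2

    def test_peak_without_motif_discarded(self):
        assert assign_peaks_to_motifs(
            [self.make_peak(0, 50)], [site(60)], Condition.CONTROL
        ) == []

    def test_overlapping_peaks_deduplicate_motif(self):
        calls = assign_peaks_to_motifs(
            [self.make_peak(0, 20), self.make_peak(10, 30)],
            [site(12)],
            Condition.CONTROL,
        )
        assert len(calls) == 1

    def test_pentamer_span_intersection_is_half_open(self):
        # motif [10, 15); peak [15, 30) does not intersect, peak [14, 30) does
        assert assign_peaks_to_motifs(
            [self.make_peak(15, 30)], [site(10)], Condition.CONTROL
        ) == []
        assert len(assign_peaks_to_motifs(
            [self.make_peak(14, 30)], [site(10)], Condition.CONTROL
        )) == 1


class TestSummaryAndStressSites:
    def test_ratio(self, toy_transcript):
        motifs = scan_drach(toy_transcript)
        assert len(motifs) == 3
        from m6atriage.m6a_calling import MethylationCall, PeakInterval

        peak = PeakInterval("toy", 0, 10, 1.0)
        calls = [
            MethylationCall(site=motifs[0], condition=Condition.CONTROL, peak=peak)
        ]
        s = methylation_summary(calls, motifs, toy_transcript, Condition.CONTROL)
        assert s.n_predicted == 3 and s.n_methylated == 1
        assert s.ratio == pytest.approx(1 / 3)

    def test_zero_predicted_flagged(self, toy_transcript):
        s = methylation_summary([], [], toy_transcript, Condition.CONTROL)
        assert not s.defined and np.isnan(s.ratio)

    def test_stress_induced_is_gain_only(self):
        from m6atriage.m6a_calling import MethylationCall, PeakInterval

        peak = PeakInterval("t1", 0, 50, 1.0)
        m1, m2 = site(10), site(30)
        c = lambda m, cond: MethylationCall(site=m, condition=cond, peak=peak)
        control = [c(m1, Condition.CONTROL)]
        stress = [c(m1, Condition.STRESS_500), c(m2, Condition.STRESS_500)]
        assert stress_induced_sites(control, stress) == {m2}
        assert stress_induced_sites(stress, stress) == set()
        assert stress_induced_sites(control, []) == set()


class TestMetagene:
    def test_single_bin_ratio(self, toy_transcript):
        from m6atriage.m6a_calling import MethylationCall, PeakInterval

        motifs = scan_drach(toy_transcript)
        binning = SegmentBinning(1, 1, 1)
        peak = PeakInterval("toy", 0, 10, 1.0)
        calls = [MethylationCall(motifs[0], Condition.CONTROL, peak)]
        df = metagene_methylation(
            {"toy": toy_transcript}, {"toy": motifs}, calls, binning
        )
        utr5 = df[df.segment == "UTR5"].iloc[0]
        assert utr5.n_predicted == 1 and utr5.ratio == 1.0
        utr3 = df[df.segment == "UTR3"].iloc[0]
        assert utr3.n_predicted == 1 and utr3.ratio == 0.0

    def test_conservation_of_predicted_counts(self, small_dataset):
        binning = SegmentBinning()
        eligible = {
            tx: m
            for tx, m in small_dataset.transcripts.items()
            if not m.is_spikein and binning.fits(m)
        }
        df = metagene_methylation(eligible, small_dataset.motifs, [], binning)
        expected = sum(len(small_dataset.motifs[tx]) for tx in eligible)
        assert df.n_predicted.sum() == expected

    def test_empty_bins_reported_missing_not_zero(self, toy_transcript):
        motifs = [s for s in scan_drach(toy_transcript) if s.region is Region.UTR5]
        df = metagene_methylation(
            {"toy": toy_transcript}, {"toy": motifs}, [], SegmentBinning(1, 1, 1)
        )
        assert np.isnan(df[df.segment == "CDS"].ratio.iloc[0])


class TestReplicateMerge:
    def test_identical_replicates_merge_to_double(self):
        reps = {
            "t1": profile(np.arange(10.0) + 1),
            "t2": profile(np.arange(10.0) * 3 + 1, tx="t2"),
        }
        merged = merge_coverage_replicates(reps, reps)
        assert np.allclose(merged["t1"].counts, 2 * reps["t1"].counts)
        assert merged["t1"].library_size == 2e6

    def test_discordant_replicates_refused(self):
        rng = np.random.default_rng(5)
        rep1 = {f"t{i}": profile(rng.poisson(5, 50), tx=f"t{i}") for i in range(200)}
        rep2 = {f"t{i}": profile(rng.poisson(5, 50), tx=f"t{i}") for i in range(200)}
        with pytest.raises(ValueError, match="refused"):
            merge_coverage_replicates(rep1, rep2)


def test_identical_ip_input_produces_zero_calls(small_dataset):
    """Null methylation: using the input library as its own IP gives no calls."""
    from m6atriage.m6a_calling import call_transcript

    inp = small_dataset.coverage[(Assay.RNA_INPUT, Condition.CONTROL, 1)]
    total = 0
    for tx, model in small_dataset.transcripts.items():
        _, _, calls = call_transcript(
            inp[tx], inp[tx], small_dataset.motifs[tx], Condition.CONTROL
        )
        total += len(calls)
    assert total == 0
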