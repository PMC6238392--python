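"""RPM/RPKM, ribosome density, translation ratio and metagene densities."""

import math

import numpy as np
import pytest

from m6atriage.m6a_calling import Assay, Condition, CoverageProfile
from m6atriage.ribo_translation import (
    MetageneDensity,
    RtMode,
    TranslationClass,
    TranslationRecord,
    classify_translation,
    compute_rd,
    compute_rpkm,
    compute_rpm,
    compute_rt,
    metagene_density,
    normalize_rd,
    rd_shift,
)
from m6atriage.transcriptome import TranscriptModel


def rpf_profile(counts, tx="t1", lib=1e6):
    return CoverageProfile(
        transcript_id=tx, assay=Assay.RPF, condition=Condition.STRESS_200,
        replicate=1, counts=np.asarray(counts, dtype=float), library_size=lib,
    )


def cds_only_tx(cds_len, utr5=0, utr3=0, tx_id="t1"):
    seq = "A" * (utr5 + cds_len + utr3)
    return TranscriptModel(tx_id, "g", seq, utr5, cds_len, utr3)


class TestAbundance:
    def test_rpm(self):
        assert compute_rpm(10, 1e6) == 10.0

    def test_rpkm(self):
        assert compute_rpkm(100, 1e6, 1000) == 100.0

    def test_zero_reads(self):
        assert compute_rpkm(0, 1e6, 500) == 0.0

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            compute_rpm(1, 0)
        with pytest.raises(ValueError):
            compute_rpkm(1, 1e6, 0)


class TestRibosomeDensity:
    def test_ratio(self):
        assert compute_rd(4, 2) == 2.0
        assert compute_rd(0, 5) == 0.0

    def test_zero_mrna_flagged(self):
        assert math.isnan(compute_rd(3, 0))

    def test_mito_median_baseline(self):
        records = [
            TranslationRecord("m1", Condition.CONTROL, rd_raw=1.0),
            TranslationRecord("m2", Condition.CONTROL, rd_raw=2.0),
            TranslationRecord("m3", Condition.CONTROL, rd_raw=3.0),
            TranslationRecord("n1", Condition.CONTROL, rd_raw=4.0),
        ]
        normalize_rd(records, {"m1", "m2", "m3"})
        assert records[-1].rd_norm == pytest.approx(2.0)
        # mitochondrial genes sit near 1 by construction
        assert records[1].rd_norm == pytest.approx(1.0)

    def test_missing_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            normalize_rd(
                [TranslationRecord("n1", Condition.CONTROL, rd_raw=1.0)], {"m1"}
            )


class TestTranslationRatio:
    def test_all_reads_in_window_is_one(self):
        tx = cds_only_tx(1000)
        counts = np.zeros(1000)
        counts[:100] = 0.5
        assert compute_rt(rpf_profile(counts), tx) == 1.0

    def test_uniform_profile_fraction_vs_literal(self):
        tx = cds_only_tx(1000)
        counts = np.ones(1000)
        assert compute_rt(rpf_profile(counts), tx, RtMode.FRACTION) == pytest.approx(0.1)
        assert compute_rt(rpf_profile(counts), tx, RtMode.LITERAL_RPKM) == pytest.approx(1.0)

    def test_literal_equals_fraction_times_length_ratio(self):
        rng = np.random.default_rng(2)
        tx = cds_only_tx(600, utr5=50, utr3=40)
        counts = np.zeros(690)
        counts[50:650] = rng.poisson(3, 600)
        frac = compute_rt(rpf_profile(counts), tx, RtMode.FRACTION)
        lit = compute_rt(rpf_profile(counts), tx, RtMode.LITERAL_RPKM)
        assert lit == pytest.approx(frac * 600 / 100)
        assert 0.0 <= frac <= 1.0

    def test_window_counted_from_cds_start(self):
        tx = cds_only_tx(500, utr5=200)
        counts = np.zeros(700)
        counts[:200] = 9.0  # UTR5 reads are ignored entirely
        counts[200:300] = 1.0
        assert compute_rt(rpf_profile(counts), tx) == 1.0

    def test_zero_reads_undetected(self):
        tx = cds_only_tx(300)
        assert math.isnan(compute_rt(rpf_profile(np.zeros(300)), tx))

    def test_library_scaling_invariance(self):
        rng = np.random.default_rng(8)
        tx = cds_only_tx(900)
        counts = rng.poisson(2, 900).astype(float)
        a = compute_rt(rpf_profile(counts, lib=1e6), tx)
        b = compute_rt(rpf_profile(counts * 7, lib=7e6), tx)
        assert a == pytest.approx(b)


class TestClassification:
    @pytest.mark.parametrize(
        "r_t,expected",
        [
            (0.05, TranslationClass.TRANSLATED),
            (0.5, TranslationClass.TRANSLATED),  # boundary is inclusive
            (0.51, TranslationClass.STALLED),
            (float("nan"), TranslationClass.UNDETECTED),
        ],
    )
    def test_threshold(self, r_t, expected):
        rec = TranslationRecord("t1", Condition.STRESS_200, r_t=r_t)
        classify_translation([rec])
        assert rec.label is expected


class TestMetageneDensity:
    def test_point_mass_at_start(self):
        tx = cds_only_tx(600, utr5=60)
        counts = np.zeros(660)
        counts[60] = 5.0
        md = metagene_density({"t1": rpf_profile(counts)}, {"t1": tx}, (-50, 500))
        peak = np.flatnonzero(md.mean_density)
        assert md.offsets[peak[0]] == 0
        assert md.cumulative[-1] == pytest.approx(1.0)

    def test_two_point_masses_equal_weight(self):
        tx = cds_only_tx(600, utr5=60)
        c1, c2 = np.zeros(660), np.zeros(660)
        c1[60] = 4.0  # offset 0
        c2[160] = 400.0  # offset 100; equal weight despite 100x reads
        md = metagene_density(
            {"a": rpf_profile(c1, tx="a"), "b": rpf_profile(c2, tx="b")},
            {"a": tx, "b": cds_only_tx(600, utr5=60, tx_id="b")},
        )
        dens = dict(zip(md.offsets, md.mean_density))
        assert dens[0] == pytest.approx(0.5)
        assert dens[100] == pytest.approx(0.5)

    def test_uniform_profile_linear_cumulative(self):
        tx = cds_only_tx(600, utr5=50)
        counts = np.ones(650)
        md = metagene_density({"t1": rpf_profile(counts)}, {"t1": tx}, (-50, 500))
        assert np.all(np.diff(md.cumulative) >= 0)
        diffs = np.diff(md.mean_density)
        assert np.allclose(diffs, 0.0)


class TestRdShift:
    def make(self, rd_by_tx, cond):
        return [
            TranslationRecord(tx, cond, rd_norm=v) for tx, v in rd_by_tx.items()
        ]

    def test_identical_conditions_zero(self):
        recs = self.make({"a": 1.0, "b": 2.0}, Condition.CONTROL)
        assert rd_shift(recs, recs) == 0.0

    def test_exact_fourfold(self):
        control = self.make({"a": 4.0, "b": 8.0}, Condition.CONTROL)
        stress = self.make({"a": 1.0, "b": 2.0}, Condition.STRESS_200)
        assert rd_shift(control, stress) == pytest.approx(2.0)

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError):
            rd_shift(
                self.make({"a": 1.0}, Condition.CONTROL),
                self.make({"b": 1.0}, Condition.STRESS_200),
            )
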