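"""Coverage construction, candidate calling and the dual confidence tests."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from p53peaks.genome import GenomeAssembly, GenomicInterval, ValidationError
from p53peaks.peaks import (
    CoverageTrack,
    FixedThreshold,
    Peak,
    PeakSet,
    PoissonThreshold,
    build_coverage,
    call_candidate_peaks,
    confidence_test_background,
    confidence_test_enrichment,
    dedup_tags,
    filter_high_confidence,
    flag_symmetric_input_overlap,
    read_peak_bed,
)


def frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand"])


@pytest.fixture
def small_assembly():
    return GenomeAssembly("toy", {"chr1": 10_000})


class TestCoverage:
    def test_single_plus_tag_extends_forward(self, small_assembly):
        track = build_coverage(frame([("chr1", 100, "+")]), small_assembly, 700)
        cov = track.chrom_coverage("chr1")
        assert cov[99] == 0 and cov[100] == 1 and cov[799] == 1 and cov[800] == 0

    def test_single_minus_tag_extends_backward(self, small_assembly):
        track = build_coverage(frame([("chr1", 1000, "-")]), small_assembly, 700)
        cov = track.chrom_coverage("chr1")
        # fragment ends at the tag's right edge (pos + 36)
        assert cov[1035] == 1 and cov[1036] == 0
        assert cov[336] == 1 and cov[335] == 0

    def test_two_identical_tags_stack(self, small_assembly):
        track = build_coverage(
            frame([("chr1", 100, "+"), ("chr1", 100, "+")]), small_assembly, 700
        )
        assert track.chrom_coverage("chr1")[400] == 2

    def test_coverage_mass_conservation(self, small_assembly, rng):
        n = 1_000
        tags = frame(
            [
                ("chr1", int(p), "+" if s else "-")
                for p, s in zip(
                    rng.integers(0, 10_000 - 36, size=n), rng.integers(0, 2, size=n)
                )
            ]
        )
        track = build_coverage(tags, small_assembly, 700)
        # every accepted fragment contributes its (possibly edge-truncated) span
        assert track.total_coverage() <= n * 700
        assert track.total_coverage() > n * 700 * 0.9
        interior = tags[(tags.pos >= 700) & (tags.pos <= 10_000 - 736)]
        full_track = build_coverage(interior, small_assembly, 700)
        assert full_track.total_coverage() == len(interior) * 700

    def test_out_of_range_tags_rejected_and_counted(self, small_assembly):
        track = build_coverage(
            frame([("chr1", 9_990, "+"), ("chr1", 100, "+"), ("chrZ", 5, "+")]),
            small_assembly,
            700,
        )
        assert track.n_rejected == 2
        assert track.library_size == 1

    def test_dedup(self):
        tags = frame([("chr1", 5, "+"), ("chr1", 5, "+"), ("chr1", 5, "-")])
        distinct, removed = dedup_tags(tags)
        assert len(distinct) == 2 and removed == 1


class TestCandidateCalling:
    def test_flat_zero_coverage_gives_no_peaks(self, small_assembly):
        track = CoverageTrack(
            small_assembly, {"chr1": np.zeros(10_000, dtype=np.int32)}, 700, 0
        )
        assert len(call_candidate_peaks(track, FixedThreshold(5))) == 0

    def test_rectangular_pileup_leftmost_maximum(self, small_assembly):
        cov = np.zeros(10_000, dtype=np.int32)
        cov[2_000:2_500] = 10
        track = CoverageTrack(small_assembly, {"chr1": cov}, 700, 0)
        (peak,) = call_candidate_peaks(track, FixedThreshold(5))
        assert peak.height == 10
        assert peak.maximum == 2_000  # leftmost position of the plateau
        assert (peak.region.start, peak.region.end) == (2_000, 2_500)

    def test_nearby_runs_merge(self, small_assembly):
        cov = np.zeros(10_000, dtype=np.int32)
        cov[1_000:1_100] = 6
        cov[1_250:1_350] = 8  # gap of 150 < merge_gap
        cov[3_000:3_100] = 7  # far away
        track = CoverageTrack(small_assembly, {"chr1": cov}, 700, 0)
        peaks = call_candidate_peaks(track, FixedThreshold(5), merge_gap=200)
        assert len(peaks) == 2
        assert peaks.peaks[0].maximum == 1_250

    def test_recovers_planted_pileups_matching_brute_force(self, small_assembly, rng):
        cov = rng.poisson(2.0, size=10_000).astype(np.int32)
        planted = sorted(rng.choice(np.arange(200, 9_800, 180), 50, replace=False))
        for p in planted:
            cov[p : p + 30] += 40
        track = CoverageTrack(small_assembly, {"chr1": cov}, 700, 0)
        t = 20
        peaks = call_candidate_peaks(track, FixedThreshold(t), merge_gap=50)
        # brute-force scan of the array: runs >= t merged at < 50 bp gaps
        runs, start = [], None
        for i, v in enumerate(cov):
            if v >= t and start is None:
                start = i
            elif v < t and start is not None:
                runs.append([start, i])
                start = None
        if start is not None:
            runs.append([start, len(cov)])
        merged = []
        for s, e in runs:
            if merged and s - merged[-1][1] < 50:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        assert len(peaks) == len(merged)
        for peak, (s, e) in zip(peaks, merged):
            assert (peak.region.start, peak.region.end) == (s, e)
            assert peak.maximum == s + int(np.argmax(cov[s:e]))

    def test_poisson_threshold_is_smallest_h_below_q(self):
        from scipy import stats

        cov = np.full(100_000, 3, dtype=np.int32)
        rule = PoissonThreshold(q=1e-4)
        h = rule.threshold(cov)
        assert stats.poisson.sf(h - 1, 3.0) < 1e-4
        assert stats.poisson.sf(h - 2, 3.0) >= 1e-4


def _exact_binom_upper_tail(k, n, p=Fraction(1, 2)):
    return sum(
        Fraction(comb(n, i)) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1)
    )


class TestEnrichmentConfidence:
    def _tracks(self, small_assembly, chip_cov, input_cov, lib=1000):
        chip = CoverageTrack(small_assembly, {"chr1": chip_cov}, 700, lib)
        inp = CoverageTrack(small_assembly, {"chr1": input_cov}, 700, lib)
        return chip, inp

    def test_strong_enrichment_matches_exact_summation(self, small_assembly):
        # 100 ChIP vs 10 Input fragments in the region, equal libraries
        chip_cov = np.zeros(10_000, dtype=np.int64)
        input_cov = np.zeros(10_000, dtype=np.int64)
        chip_cov[1_000:1_700] = 100
        input_cov[1_000:1_700] = 10
        chip, inp = self._tracks(small_assembly, chip_cov, input_cov)
        peak = Peak(GenomicInterval("chr1", 1_000, 1_700), 1_000, 100.0)
        conf = confidence_test_enrichment(peak, chip, inp)
        exact = 1 - _exact_binom_upper_tail(100, 111)
        assert conf > 0.99
        assert conf == pytest.approx(float(exact), abs=1e-12)

    def test_no_enrichment_fails_at_99(self, small_assembly):
        cov = np.zeros(10_000, dtype=np.int64)
        cov[1_000:1_700] = 50
        chip, inp = self._tracks(small_assembly, cov, cov.copy())
        peak = Peak(GenomicInterval("chr1", 1_000, 1_700), 1_000, 50.0)
        conf = confidence_test_enrichment(peak, chip, inp)
        # binomial symmetry at p = 1/2: equal counts sit near the median
        assert conf == pytest.approx(0.5, abs=0.1)
        assert conf < 0.99

    def test_zero_chip_coverage_gives_zero_confidence(self, small_assembly):
        chip_cov = np.zeros(10_000, dtype=np.int64)
        input_cov = np.zeros(10_000, dtype=np.int64)
        input_cov[1_000:1_700] = 5
        chip, inp = self._tracks(small_assembly, chip_cov, input_cov)
        peak = Peak(GenomicInterval("chr1", 1_000, 1_700), 1_000, 0.0)
        assert confidence_test_enrichment(peak, chip, inp) <= 0.5

    def test_library_scaling_shifts_success_probability(self, small_assembly):
        cov = np.zeros(10_000, dtype=np.int64)
        cov[1_000:1_700] = 50
        chip = CoverageTrack(small_assembly, {"chr1": cov}, 700, 1_000)
        inp = CoverageTrack(small_assembly, {"chr1": cov.copy()}, 700, 4_000)
        peak = Peak(GenomicInterval("chr1", 1_000, 1_700), 1_000, 50.0)
        # same raw counts but a 4x deeper input library: strong enrichment
        assert confidence_test_enrichment(peak, chip, inp) > 0.99


class TestBackgroundConfidence:
    def _input_track(self, small_assembly, rng):
        cov = rng.poisson(5.0, size=10_000).astype(np.int32)
        return CoverageTrack(small_assembly, {"chr1": cov}, 700, 1_000)

    def test_dominant_peak_scores_one(self, small_assembly, rng):
        inp = self._input_track(small_assembly, rng)
        peak = Peak(GenomicInterval("chr1", 500, 1_200), 600, 1e6)
        assert confidence_test_background(peak, inp, 1_000, seed=7) == 1.0

    def test_zero_height_scores_bottom(self, small_assembly, rng):
        inp = self._input_track(small_assembly, rng)
        peak = Peak(GenomicInterval("chr1", 500, 1_200), 600, 0.0)
        assert confidence_test_background(peak, inp, 1_000, seed=7) <= 1e-3

    def test_seeded_reproducibility(self, small_assembly, rng):
        inp = self._input_track(small_assembly, rng)
        peak = Peak(GenomicInterval("chr1", 500, 1_200), 600, 12.0)
        a = confidence_test_background(peak, inp, 1_000, seed=42)
        b = confidence_test_background(peak, inp, 1_000, seed=42)
        assert a == b

    def test_too_few_samples_rejected(self, small_assembly, rng):
        inp = self._input_track(small_assembly, rng)
        peak = Peak(GenomicInterval("chr1", 500, 1_200), 600, 12.0)
        with pytest.raises(ValidationError):
            confidence_test_background(peak, inp, 50, seed=1)

    def test_peak_wider_than_chromosome_rejected(self):
        tiny = GenomeAssembly("t", {"chr1": 400})
        inp = CoverageTrack(tiny, {"chr1": np.zeros(400, dtype=np.int32)}, 700, 10)
        wide = Peak(GenomicInterval("chr1", 0, 499), 0, 1.0)
        with pytest.raises(ValidationError):
            confidence_test_background(wide, inp, 100, seed=1)


class TestSymmetricInputFlag:
    def _set(self, assembly, specs, label):
        peaks = [
            Peak(GenomicInterval("chr1", m - 100, m + 100), m, h) for m, h in specs
        ]
        return PeakSet(label, assembly, peaks)

    def test_close_equal_input_peak_flags(self, small_assembly):
        chip = self._set(small_assembly, [(2_000, 50.0)], "chip")
        inp = self._set(small_assembly, [(2_010, 50.0)], "inp")
        (peak,) = flag_symmetric_input_overlap(chip, inp)
        assert peak.input_symmetric_overlap

    def test_distant_input_peak_does_not_flag(self, small_assembly):
        chip = self._set(small_assembly, [(2_000, 50.0)], "chip")
        inp = self._set(small_assembly, [(7_000, 50.0)], "inp")
        (peak,) = flag_symmetric_input_overlap(chip, inp)
        assert not peak.input_symmetric_overlap

    def test_tall_chip_peak_escapes_flag(self, small_assembly):
        chip = self._set(small_assembly, [(2_000, 500.0)], "chip")
        inp = self._set(small_assembly, [(2_010, 50.0)], "inp")
        (peak,) = flag_symmetric_input_overlap(chip, inp, max_height_ratio=2.0)
        assert not peak.input_symmetric_overlap

    def test_matches_all_pairs_brute_force(self, small_assembly, rng):
        chip_maxima = np.sort(rng.choice(np.arange(300, 9_700, 250), 20, replace=False))
        inp_maxima = np.sort(rng.choice(np.arange(300, 9_700, 250), 15, replace=False))
        chip = self._set(
            small_assembly,
            [(int(m), float(h)) for m, h in zip(chip_maxima, rng.uniform(10, 100, 20))],
            "chip",
        )
        inp = self._set(
            small_assembly,
            [(int(m), float(h)) for m, h in zip(inp_maxima, rng.uniform(10, 100, 15))],
            "inp",
        )
        flagged = flag_symmetric_input_overlap(chip, inp, 100, 2.0)
        for peak in flagged:
            expected = any(
                abs(ip.maximum - peak.maximum) <= 100
                and peak.height / ip.height <= 2.0
                for ip in inp
            )
            assert peak.input_symmetric_overlap == expected


class TestHighConfidenceFilter:
    def _peak(self, assembly, m, conf_e, conf_b, flagged):
        return Peak(
            GenomicInterval("chr1", m - 50, m + 50),
            m,
            10.0,
            conf_e,
            conf_b,
            flagged,
        )

    def test_both_tests_and_no_flag_required(self, small_assembly):
        peaks = PeakSet(
            "c",
            small_assembly,
            [
                self._peak(small_assembly, 1_000, 0.999, 0.999, False),  # kept
                self._peak(small_assembly, 2_000, 0.999, 0.98, False),   # dropped
                self._peak(small_assembly, 3_000, 0.999, 0.999, True),   # dropped
            ],
        )
        hc = filter_high_confidence(peaks, 0.99)
        assert [p.maximum for p in hc] == [1_000]
        assert all(p.high_confidence for p in hc)

    def test_unpopulated_confidence_rejected(self, small_assembly):
        peaks = PeakSet(
            "c",
            small_assembly,
            [Peak(GenomicInterval("chr1", 950, 1_050), 1_000, 10.0)],
        )
        with pytest.raises(ValidationError):
            filter_high_confidence(peaks)

    def test_hc_is_subset_of_candidates(self, hct_run):
        cand = {(p.region.chrom, p.maximum) for p in hct_run.candidates}
        hc = {(p.region.chrom, p.maximum) for p in hct_run.high_confidence}
        assert hc <= cand
        assert len(hct_run.high_confidence) <= len(hct_run.candidates)


class TestPeakSetIO:
    def test_bed_round_trip(self, small_assembly, tmp_path):
        peaks = PeakSet(
            "c",
            small_assembly,
            [
                Peak(GenomicInterval("chr1", 950, 1_050), 1_000, 10.0, 0.999, 0.991),
                Peak(GenomicInterval("chr1", 2_950, 3_050), 3_000, 7.0, 0.5, 0.2, True),
            ],
        )
        p = tmp_path / "peaks.bed"
        peaks.write_bed(p)
        again = read_peak_bed(p, small_assembly, "c")
        assert again.to_frame().equals(peaks.to_frame())

    def test_overlapping_peaks_rejected(self, small_assembly):
        with pytest.raises(ValidationError):
            PeakSet(
                "c",
                small_assembly,
                [
                    Peak(GenomicInterval("chr1", 100, 300), 150, 5.0),
                    Peak(GenomicInterval("chr1", 250, 400), 300, 5.0),
                ],
            )

    def test_deterministic_serialization(self, null_run, tmp_path):
        a, b = tmp_path / "a.bed", tmp_path / "b.bed"
        null_run.candidates.write_bed(a)
        null_run.candidates.write_bed(b)
        assert a.read_bytes() == b.read_bytes()
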