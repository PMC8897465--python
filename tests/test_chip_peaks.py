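"""Track arithmetic, the threshold peak caller, and peak-set analyses.

The peak caller is checked bit-for-bit against an independent
brute-force enumeration (enriched bins -> runs -> gap merge -> length
filter) written as plain Python loops.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitobook.chip_peaks import (
    Peak,
    PeakSet,
    annotate_peaks,
    annotation_proportions,
    call_peaks,
    classify_peaks,
    count_motif,
    mean_replicates,
    metagene_matrix,
    rescale_rpm,
    subtract_input,
)
from mitobook.io_formats import BedRecord, CoverageTrack, GenomeIntervals

from _oracles import as_tuples, oracle_call_peaks, oracle_count


def track(vals, bin_size=50, chrom="chr1", origin=0):
    return CoverageTrack(bin_size, {chrom: np.asarray(vals, float)},
                         {chrom: origin})


# ---------------------------------------------------------------------------


class TestTrackArithmetic:
    def test_rpm_direct_scaling(self):
        out = rescale_rpm(track([2.0, 4.0]), 2_000_000)
        np.testing.assert_array_equal(out.values["chr1"], [1.0, 2.0])

    def test_rpm_identity_at_one_million(self):
        out = rescale_rpm(track([3.0, 7.0]), 1_000_000)
        np.testing.assert_array_equal(out.values["chr1"], [3.0, 7.0])

    def test_rpm_linearity(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(0, 100, 50)
        a = rescale_rpm(track(3.0 * v), 123_456).values["chr1"]
        b = 3.0 * rescale_rpm(track(v), 123_456).values["chr1"]
        np.testing.assert_allclose(a, b)

    def test_rpm_rejects_bad_library(self):
        with pytest.raises(ValueError):
            rescale_rpm(track([1.0]), 0)

    def test_subtract_floors_at_zero(self):
        out = subtract_input(track([5.0, 1.0]), track([2.0, 3.0]))
        np.testing.assert_array_equal(out.values["chr1"], [3.0, 0.0])

    def test_subtract_without_floor(self):
        out = subtract_input(track([5.0, 1.0]), track([2.0, 3.0]),
                             floor_at_zero=False)
        np.testing.assert_array_equal(out.values["chr1"], [3.0, -2.0])

    def test_subtract_zero_input_is_identity(self):
        out = subtract_input(track([5.0, 1.0]), track([0.0, 0.0]))
        np.testing.assert_array_equal(out.values["chr1"], [5.0, 1.0])

    def test_subtract_grid_mismatch(self):
        with pytest.raises(ValueError):
            subtract_input(track([1.0]), track([1.0], bin_size=25))
        with pytest.raises(ValueError):
            subtract_input(track([1.0]), track([1.0], chrom="chr2"))

    def test_mean_single_track_identity(self):
        out = mean_replicates([track([1.0, 2.0])])
        np.testing.assert_array_equal(out.values["chr1"], [1.0, 2.0])

    def test_mean_of_two(self):
        out = mean_replicates([track([0.0, 2.0]), track([2.0, 0.0])])
        np.testing.assert_array_equal(out.values["chr1"], [1.0, 1.0])

    def test_mean_of_copies_is_original(self):
        rng = np.random.default_rng(1)
        v = rng.uniform(0, 10, 30)
        out = mean_replicates([track(v)] * 5)
        np.testing.assert_allclose(out.values["chr1"], v)


class TestCallPeaks:
    VALUES = [10, 120, 130, 5, 5, 140, 150, 150, 10, 10]

    def test_gap_merge_example(self):
        ps = call_peaks(track(self.VALUES), 100, min_run=50, max_gap=200)
        assert as_tuples(ps) == oracle_call_peaks(
            self.VALUES, 50, 0, 100, 50, 200
        )
        assert [(p.start, p.end) for p in ps] == [(50, 400)]

    def test_small_gap_keeps_peaks_distinct(self):
        ps = call_peaks(track(self.VALUES), 100, min_run=50, max_gap=50)
        assert [(p.start, p.end) for p in ps] == [(50, 150), (250, 400)]

    def test_all_below_threshold(self):
        assert len(call_peaks(track([1.0, 2.0, 3.0]), 100)) == 0

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValueError):
            call_peaks(track([1.0]), 1, min_run=-1)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10**6),
        threshold=st.sampled_from([50.0, 100.0]),
        min_run=st.sampled_from([0, 50, 100, 150]),
        max_gap=st.sampled_from([0, 50, 200, 500]),
        origin_bins=st.integers(0, 5),
    )
    def test_matches_oracle_on_random_tracks(
        self, seed, threshold, min_run, max_gap, origin_bins
    ):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(0, 200, size=60)
        tr = track(vals, origin=origin_bins * 50)
        ps = call_peaks(tr, threshold, min_run, max_gap)
        assert as_tuples(ps) == oracle_call_peaks(
            list(vals), 50, origin_bins * 50, threshold, min_run, max_gap
        )

    def test_zero_gap_equals_enriched_runs(self):
        rng = np.random.default_rng(7)
        vals = rng.uniform(0, 200, size=100)
        ps = call_peaks(track(vals), 100, min_run=100, max_gap=0)
        # every peak must be a maximal run of enriched bins
        for p in ps:
            s, e = p.start // 50, p.end // 50
            assert np.all(vals[s:e] >= 100)
            assert s == 0 or vals[s - 1] < 100
            assert e == len(vals) or vals[e] < 100
            assert (e - s) * 50 >= 100

    def test_raising_threshold_never_adds_basepairs(self):
        rng = np.random.default_rng(11)
        vals = rng.uniform(0, 200, size=200)
        bps = [
            call_peaks(track(vals), thr, 50, 200).total_bp()
            for thr in (25, 50, 100, 150, 190)
        ]
        assert bps == sorted(bps, reverse=True)


class TestClassify:
    @staticmethod
    def ps(*spans):
        return PeakSet([Peak("chr1", s, e, 1.0, 1) for s, e in spans])

    def test_single_bp_overlap_is_retained(self):
        cls = classify_peaks(self.ps((0, 100)), self.ps((99, 150)))
        assert cls.counts() == {
            "interphase_only": 0, "mitotically_retained": 1, "mitosis_only": 0,
        }

    def test_half_open_adjacency_is_no_overlap(self):
        cls = classify_peaks(self.ps((0, 100)), self.ps((100, 150)))
        assert cls.counts() == {
            "interphase_only": 1, "mitotically_retained": 0, "mitosis_only": 1,
        }

    def test_random_sets_match_pairwise_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = self.ps(*[(s, s + w) for s, w in zip(
                rng.integers(0, 5000, 15), rng.integers(1, 300, 15))])
            b = self.ps(*[(s, s + w) for s, w in zip(
                rng.integers(0, 5000, 15), rng.integers(1, 300, 15))])
            cls = classify_peaks(a, b)
            retained = sum(
                any(p.start < q.end and q.start < p.end for q in b) for p in a
            )
            mito_only = sum(
                not any(p.start < q.end and q.start < p.end for p in a)
                for q in b
            )
            assert len(cls.mitotically_retained) == retained
            assert len(cls.interphase_only) == len(a.peaks) - retained
            assert len(cls.mitosis_only) == mito_only

    def test_rule_is_symmetric_in_arguments(self):
        # a-peak is retained vs b  <=>  it is NOT "other-set only" when the
        # same rule runs with the arguments swapped
        rng = np.random.default_rng(5)
        a = self.ps(*[(int(s), int(s) + 100) for s in rng.integers(0, 3000, 10)])
        b = self.ps(*[(int(s), int(s) + 100) for s in rng.integers(0, 3000, 10)])
        ab = classify_peaks(a, b)
        ba = classify_peaks(b, a)

        def keys(ps):
            return {(p.start, p.end) for p in ps}

        assert keys(ab.mitotically_retained) == keys(a) - keys(ba.mitosis_only)


def oracle_count(seq, motif, overlapping=True, both=True):
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rc = "".join(comp[c] for c in reversed(motif))
    pats = [motif] + ([rc] if both and rc != motif else [])
    n = 0
    for pat in pats:
        i = 0
        while i + len(pat) <= len(seq):
            if seq[i : i + len(pat)] == pat:
                n += 1
                i += 1 if overlapping else len(pat)
            else:
                i += 1
    return n


class TestCountMotif:
    @staticmethod
    def one_peak(seq):
        ps = PeakSet([Peak("c", 0, len(seq), 1.0, 1)])
        return ps, {"c": seq}

    @pytest.mark.parametrize(
        "seq,expected",
        [("GAGAGAG", 2), ("CTCTC", 1), ("TTTTT", 0)],
    )
    def test_known_sequences(self, seq, expected):
        ps, genome = self.one_peak(seq)
        assert count_motif(ps, genome)["count"].iloc[0] == expected
        assert oracle_count(seq, "GAGAG") == expected

    def test_non_overlapping_convention(self):
        ps, genome = self.one_peak("GAGAGAGAG")  # overlapping: 3, packed: 1
        assert count_motif(ps, genome, overlapping=True)["count"].iloc[0] == 3
        assert count_motif(ps, genome, overlapping=False)["count"].iloc[0] == 1

    def test_single_strand_convention(self):
        ps, genome = self.one_peak("CTCTC")
        assert count_motif(ps, genome, both_strands=False)["count"].iloc[0] == 0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10**6), overlapping=st.booleans(),
           both=st.booleans())
    def test_matches_sliding_window_oracle(self, seed, overlapping, both):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), 120))
        # plant a (GA)_k array to exercise self-overlap
        k = int(rng.integers(3, 8))
        pos = int(rng.integers(0, 120 - 2 * k))
        seq = seq[:pos] + "GA" * k + seq[pos + 2 * k:]
        ps, genome = self.one_peak(seq)
        got = count_motif(ps, genome, overlapping=overlapping,
                          both_strands=both)["count"].iloc[0]
        assert got == oracle_count(seq, "GAGAG", overlapping, both)

    def test_peak_beyond_chromosome_rejected(self):
        ps = PeakSet([Peak("c", 0, 10, 1.0, 1)])
        with pytest.raises(ValueError):
            count_motif(ps, {"c": "ACGT"})


class TestAnnotate:
    def test_tss_flank_overlap_is_promoter(self):
        ps = PeakSet([Peak("c", 0, 100, 1.0, 1)])
        tss = GenomeIntervals([BedRecord("c", 150, 151)])
        df = annotate_peaks(ps, tss, GenomeIntervals([]), tss_flank=100)
        assert df["label"].iloc[0] == "promoter"

    def test_promoter_takes_precedence_over_enhancer(self):
        ps = PeakSet([Peak("c", 0, 100, 1.0, 1)])
        tss = GenomeIntervals([BedRecord("c", 50, 51)])
        enh = GenomeIntervals([BedRecord("c", 0, 100)])
        df = annotate_peaks(ps, tss, enh)
        assert df["label"].iloc[0] == "promoter"

    def test_proportions_sum_to_one(self):
        ps = PeakSet([Peak("c", i * 1000, i * 1000 + 100, 1.0, 1)
                      for i in range(6)])
        tss = GenomeIntervals([BedRecord("c", 1050, 1051)])
        enh = GenomeIntervals([BedRecord("c", 3000, 3100)])
        props = annotation_proportions(annotate_peaks(ps, tss, enh))
        assert props.sum() == pytest.approx(1.0)
        assert props["promoter"] == pytest.approx(1 / 6)
        assert props["enhancer"] == pytest.approx(1 / 6)

    def test_random_instances_match_bruteforce(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            ps = PeakSet([
                Peak("c", int(s), int(s) + int(w), 1.0, 1)
                for s, w in zip(rng.integers(0, 5000, 10),
                                rng.integers(10, 400, 10))
            ])
            tss = GenomeIntervals([
                BedRecord("c", int(s), int(s) + 1)
                for s in rng.integers(0, 5000, 5)
            ])
            enh = GenomeIntervals([
                BedRecord("c", int(s), int(s) + int(w))
                for s, w in zip(rng.integers(0, 5000, 5),
                                rng.integers(50, 500, 5))
            ])
            df = annotate_peaks(ps, tss, enh, tss_flank=100)
            for p, label in zip(ps, df["label"]):
                prom = any(
                    p.start < t.start + 100 and t.start - 100 < p.end
                    for t in tss
                )
                enh_hit = any(p.start < e.end and e.start < p.end for e in enh)
                expect = ("promoter" if prom
                          else "enhancer" if enh_hit else "other")
                assert label == expect


class TestMetagene:
    def test_uniform_track_gives_constant_profile(self):
        tr = track(np.full(100, 7.0))
        ps = PeakSet([Peak("chr1", 1000, 1500, 1.0, 1),
                      Peak("chr1", 2500, 3000, 1.0, 1)])
        mat, prof = metagene_matrix(tr, ps, flank=1000)
        np.testing.assert_allclose(prof, 7.0)

    def test_column_count_is_grid_arithmetic(self):
        tr = track(np.zeros(100))
        ps = PeakSet([Peak("chr1", 1000, 1200, 1.0, 1)])
        mat, _ = metagene_matrix(tr, ps, flank=1000)
        assert mat.shape == (1, 2 * 1000 // 50)

    def test_single_peak_profile_equals_row(self):
        rng = np.random.default_rng(2)
        tr = track(rng.uniform(0, 10, 100))
        ps = PeakSet([Peak("chr1", 2000, 2400, 1.0, 1)])
        mat, prof = metagene_matrix(tr, ps, flank=500)
        np.testing.assert_array_equal(mat[0], prof)

    def test_out_of_bounds_zero_filled(self):
        tr = track(np.full(10, 3.0))
        ps = PeakSet([Peak("chr1", 0, 100, 1.0, 1)])
        mat, _ = metagene_matrix(tr, ps, flank=1000)
        # center 50: window [-950, 1050) puts the 10 on-track bins at
        # columns 19..28; everything else is off the track and zero
        assert mat[0, 0] == 0.0
        np.testing.assert_array_equal(mat[0, 19:29], 3.0)
        assert mat[0, -1] == 0.0
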