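"""ROSE-style stitching, tangent cutoff and VSEL semantics."""

import numpy as np
import pytest

from velpipe import (
    Direction,
    GenomicInterval,
    Tissue,
    call_sample_super_enhancers,
    call_vsels,
    merge_intervals,
    se_gene_recurrence,
    select_recurrence_threshold,
    stitch_enhancers,
    tangent_cutoff,
)
from velpipe.superenhancers import StitchedEnhancer
from velpipe.vel import VELRecord

from conftest import iv, make_track, tss


class TestStitchEnhancers:
    TSS = [tss("g", "chr1", 200_000)]

    def test_within_stitch_window_merges(self):
        got = stitch_enhancers(
            [iv("chr1", 1000, 2000), iv("chr1", 10_000, 11_000)], self.TSS
        )
        assert len(got) == 1
        assert got[0].interval == iv("chr1", 1000, 11_000)
        assert got[0].n_constituents == 2

    def test_beyond_stitch_window_stays_split(self):
        got = stitch_enhancers(
            [iv("chr1", 1000, 2000), iv("chr1", 15_100, 16_000)], self.TSS
        )
        assert [se.n_constituents for se in got] == [1, 1]

    def test_tss_proximal_peaks_excluded_first(self):
        got = stitch_enhancers(
            [iv("chr1", 199_000, 199_500), iv("chr1", 300_000, 301_000)], self.TSS
        )
        assert [se.interval for se in got] == [iv("chr1", 300_000, 301_000)]

    def test_zero_distance_reduces_to_merge(self):
        peaks = [iv("chr1", 0, 100), iv("chr1", 50, 200), iv("chr1", 400, 500)]
        got = stitch_enhancers(peaks, self.TSS, stitch_distance=0)
        assert [se.interval for se in got] == merge_intervals(peaks)


class TestTangentCutoff:
    def test_quadratic_curve_analytic_tangent(self):
        # signal_i = i^2 on ranks 0..100 rescales to y = x^2; the slope-1
        # tangent touches at x = 0.5, i.e. scaled signal 0.25 -> raw 2500,
        # leaving exactly the 50 regions above it super
        signals = [i**2 for i in range(101)]
        cutoff, flags = tangent_cutoff(signals)
        assert cutoff == 2500
        assert flags.sum() == 50
        assert all(signals[i] > 2500 for i in np.flatnonzero(flags))

    def test_discrete_slope_oracle(self):
        rng = np.random.default_rng(1)
        s = np.sort(rng.lognormal(0, 1.2, 200))
        cutoff, flags = tangent_cutoff(s)
        y = (s - s.min()) / (s.max() - s.min())
        slopes = np.diff(y) * (len(s) - 1)
        first = np.flatnonzero(slopes > 1 + 1e-9)[0]
        assert cutoff == s[first]
        assert np.array_equal(flags, s > cutoff)

    def test_linear_signals_have_no_super(self):
        cutoff, flags = tangent_cutoff(np.arange(50) * 3.0 + 7.0)
        assert flags.sum() == 0

    def test_single_outlier_is_the_only_super(self):
        signals = [5.0] * 30 + [500.0]
        _, flags = tangent_cutoff(signals)
        assert flags.sum() == 1 and flags[-1]

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        s = rng.lognormal(0, 1, 150)
        _, base = tangent_cutoff(s)
        for _ in range(100):
            a, b = rng.uniform(0.1, 10), rng.uniform(-5, 5)
            _, flags = tangent_cutoff(a * s + b)
            assert np.array_equal(flags, base)

    def test_all_equal_warns_and_flags_none(self):
        with pytest.warns(UserWarning):
            _, flags = tangent_cutoff([4.0, 4.0, 4.0])
        assert flags.sum() == 0

    def test_raising_top_signal_never_demotes_it(self):
        rng = np.random.default_rng(4)
        s = np.sort(rng.lognormal(0, 1, 60))
        _, flags = tangent_cutoff(s)
        if flags[-1]:
            s2 = s.copy()
            s2[-1] *= 5
            _, flags2 = tangent_cutoff(s2)
            assert flags2[-1]

    def test_too_few_regions_rejected(self):
        with pytest.raises(ValueError):
            tangent_cutoff([1.0, 2.0])


class TestCallSampleSuperEnhancers:
    def test_planted_cluster_is_flagged_super(self):
        # one 3-peak high-signal cluster among scattered background peaks
        rng = np.random.default_rng(0)
        tss_list = [tss("g", "chr1", 5_000_000)]
        peaks, frags = [], []
        for k in range(20):  # background singletons, modest signal
            s = 100_000 + k * 40_000
            peaks.append(iv("chr1", s, s + 1000))
            frags += [("chr1", int(x), int(x) + 36, "+")
                      for x in rng.integers(s, s + 900, 20)]
        cluster = [iv("chr1", 2_000_000 + o, 2_000_000 + o + 1000) for o in (0, 4000, 8000)]
        for p in cluster:
            peaks.append(p)
            frags += [("chr1", int(x), int(x) + 36, "+")
                      for x in rng.integers(p.start, p.end - 100, 400)]
        # pair each background singleton so it forms a >=2-peak candidate
        extra = [iv("chr1", p.start + 2000, p.start + 2500) for p in peaks[:20]]
        for p in extra:
            peaks.append(p)
            frags += [("chr1", int(x), int(x) + 36, "+")
                      for x in rng.integers(p.start, p.end - 100, 10)]
        track = make_track(frags, library_size=len(frags), peaks=sorted(peaks))
        ses = call_sample_super_enhancers(track, tss_list)
        supers = [se for se in ses if se.is_super]
        assert len(supers) >= 1
        cluster_region = iv("chr1", 2_000_000, 2_009_000 + 1000)
        assert any(se.interval.overlaps(cluster_region) for se in supers)
        # ranks are a permutation of 1..N following the signal sort
        ranks = sorted(se.rank for se in ses)
        assert ranks == list(range(1, len(ses) + 1))
        by_rank = sorted(ses, key=lambda se: se.rank)
        signals = [se.signal for se in by_rank]
        assert signals == sorted(signals)

    def test_singletons_not_super_by_default(self):
        rng = np.random.default_rng(2)
        tss_list = [tss("g", "chr1", 9_000_000)]
        peaks, frags = [], []
        for k in range(10):
            s = 100_000 + k * 50_000
            peaks.append(iv("chr1", s, s + 1000))
            n = 500 if k == 9 else 20
            frags += [("chr1", int(x), int(x) + 36, "+")
                      for x in rng.integers(s, s + 900, n)]
        track = make_track(frags, library_size=len(frags), peaks=peaks)
        ses = call_sample_super_enhancers(track, tss_list)
        assert all(se.n_constituents == 1 for se in ses)
        assert not any(se.is_super for se in ses)

    def test_too_few_regions_is_error(self):
        track = make_track([("chr1", 0, 36, "+")], peaks=[iv("chr1", 0, 1000)])
        with pytest.raises(ValueError, match="stitched regions"):
            call_sample_super_enhancers(track, [tss("g", "chr1", 8_000_000)])


class TestVselThresholdSemantics:
    def test_cutoff_point_nine(self):
        # fraction(5) = 0.92 >= 0.9 while fraction(<5) falls short
        recs = []
        for k in range(25):
            recs.append(
                VELRecord(
                    locus=iv("chr1", k * 1000, k * 1000 + 100),
                    direction=Direction.GAIN,
                    recurrence=5,
                    p_adj=0.01 if k < 23 else 0.5,
                )
            )
        for k in range(10):
            recs.append(
                VELRecord(
                    locus=iv("chr2", k * 1000, k * 1000 + 100),
                    direction=Direction.GAIN,
                    recurrence=k % 4 + 1,
                    p_adj=0.5,
                )
            )
        r_star, _ = select_recurrence_threshold(recs, alpha=0.05, target_fraction=0.9)
        assert r_star == 5


class TestCallVsels:
    def test_patient_below_min_vsels_excluded(self, small_cohort):
        _, tracks, truth = small_cohort
        se_sets = {
            t.patient_id: {}
            for t in tracks
        }
        for t in tracks:
            se_sets[t.patient_id][t.tissue.value] = truth.se_intervals
        res = call_vsels(se_sets, tracks, min_vsels_per_patient=10**6)
        assert all(r.excluded for r in res.qc)
        assert res.records == []

    def test_identical_inputs_yield_no_significant_vsels(self, small_cohort):
        # native == tumor loci with the same signal: every fc is ~1
        _, tracks, truth = small_cohort
        natives = [t for t in tracks if t.tissue is Tissue.NATIVE]
        se_sets = {
            t.patient_id: {"tumor": truth.se_intervals, "native": truth.se_intervals}
            for t in natives
        }
        # pair each native track with itself under two sample ids
        from velpipe import Mark, SampleTrack

        mirrored = []
        for t in natives:
            mirrored.append(t)
            mirrored.append(
                SampleTrack(
                    sample_id=t.sample_id + "_as_tumor",
                    patient_id=t.patient_id,
                    tissue=Tissue.TUMOR,
                    mark=Mark.H3K27AC,
                    peaks=list(t.peaks),
                    fragments=t.fragments,
                    library_size=t.library_size,
                )
            )
        res = call_vsels(se_sets, mirrored, min_vsels_per_patient=0)
        assert res.significant_records() == []


class TestSEGeneRecurrence:
    def test_tumor_minus_native_and_sorting(self):
        tss_list = [tss("gA", "chr1", 10_000), tss("gB", "chr1", 500_000)]
        se_a = StitchedEnhancer(iv("chr1", 20_000, 40_000), 3, is_super=True)
        se_b = StitchedEnhancer(iv("chr1", 480_000, 520_000), 3, is_super=True)
        se_none = StitchedEnhancer(iv("chr1", 480_000, 520_000), 3, is_super=False)
        sample_ses = {
            "t1": [se_a, se_b],
            "t2": [se_a],
            "n1": [se_b],
            "n2": [se_none],  # not super: does not count
        }
        tissues = {"t1": "tumor", "t2": "tumor", "n1": "native", "n2": "native"}
        recs = se_gene_recurrence(sample_ses, tissues, tss_list)
        by_gene = {r.gene_id: r for r in recs}
        assert by_gene["gA"].recurrence_tumor == 2
        assert by_gene["gA"].recurrence_native == 0
        assert by_gene["gA"].variant_recurrence == 2
        assert by_gene["gB"].variant_recurrence == 1 - 1
        assert [r.gene_id for r in recs] == ["gA", "gB"]

    def test_brute_force_recount_on_toy_cohort(self):
        rng = np.random.default_rng(5)
        tss_list = [tss(f"g{k}", "chr1", 100_000 * (k + 1)) for k in range(8)]
        sample_ses, tissues = {}, {}
        for s in range(5):
            sid = f"s{s}"
            tissues[sid] = "tumor" if s < 3 else "native"
            ses = []
            for _ in range(rng.integers(1, 4)):
                k = int(rng.integers(0, 8))
                pos = 100_000 * (k + 1) + int(rng.integers(-20_000, 10_000))
                ses.append(StitchedEnhancer(iv("chr1", pos, pos + 15_000), 2, is_super=True))
            sample_ses[sid] = ses
        recs = se_gene_recurrence(sample_ses, tissues, tss_list, max_distance=50_000)
        # oracle: per sample, gene hit iff TSS inside an SE or nearest within 50 kb
        from velpipe.superenhancers import _se_genes

        for rec in recs:
            rt = sum(
                1
                for sid, ses in sample_ses.items()
                if tissues[sid] == "tumor"
                and rec.gene_id in _se_genes([s.interval for s in ses], tss_list, 50_000)
            )
            rn = sum(
                1
                for sid, ses in sample_ses.items()
                if tissues[sid] == "native"
                and rec.gene_id in _se_genes([s.interval for s in ses], tss_list, 50_000)
            )
            assert (rec.recurrence_tumor, rec.recurrence_native) == (rt, rn)
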