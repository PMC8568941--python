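"""ROSE-style super-enhancer identification and variant super-enhancer loci.

TSS-distal H3K27ac peaks within 12.5 kb of each other are stitched into
candidate regions; regions are ranked by total H3K27ac signal and the ranked
curve, rescaled to the unit square, is cut where its discrete slope first
exceeds 1 (the slope-1 tangent point). Regions above the cut are
super-enhancers (SEs). Variant super-enhancer loci (VSELs) are called with
the same pipeline as VELs, on stitched-SE loci, with a per-patient minimum
of 10 VSELs and a significant-fraction cutoff of 0.9.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import TSSRecord, _tss_windows, _overlaps_any
from .intervals import (
    GenomicInterval,
    Mark,
    SampleTrack,
    Tissue,
    build_signal_matrix,
    compute_rpm,
    merge_intervals,
)
from . import vel as _vel
from .vel import Direction, VELRecord, VELResult, qc_filter_patients

__all__ = [
    "StitchedEnhancer",
    "SEGeneRecord",
    "stitch_enhancers",
    "tangent_cutoff",
    "call_sample_super_enhancers",
    "call_vsels",
    "se_gene_recurrence",
]

DEFAULT_STITCH_DISTANCE = 12_500
DEFAULT_TSS_EXCLUSION = 2_500


@dataclass
class StitchedEnhancer:
    """A stitched enhancer region with its signal rank and super flag."""

    interval: GenomicInterval
    n_constituents: int
    signal: float = 0.0  # region-summed RPM (per-bp density x length)
    rank: int = 0  # ascending by signal, 1..N
    is_super: bool = False


@dataclass
class SEGeneRecord:
    gene_id: str
    recurrence_tumor: int
    recurrence_native: int

    @property
    def variant_recurrence(self) -> int:
        return self.recurrence_tumor - self.recurrence_native


def stitch_enhancers(
    peaks: Sequence[GenomicInterval],
    tss: Sequence[TSSRecord],
    stitch_distance: int = DEFAULT_STITCH_DISTANCE,
    tss_exclusion: int = DEFAULT_TSS_EXCLUSION,
) -> list[StitchedEnhancer]:
    """Stitch TSS-distal peaks within ``stitch_distance`` into candidate regions.

    Peaks overlapping the +/-``tss_exclusion`` window of any TSS are removed
    first; the remainder are merged with gap = stitch_distance and the number
    of constituent peaks per region recorded. Singleton regions are retained
    (flagged by n_constituents = 1); by convention the SE candidate set is
    regions of two or more peaks.
    """
    windows = _tss_windows(tss, tss_exclusion) if tss else {}
    distal = [p for p in peaks if not _overlaps_any(windows, p)]
    merged = merge_intervals(distal, gap=stitch_distance)
    counts = [0] * len(merged)
    by_chrom: dict[str, list[tuple[int, GenomicInterval]]] = {}
    for i, iv in enumerate(merged):
        by_chrom.setdefault(iv.chrom, []).append((i, iv))
    starts = {
        chrom: np.array([iv.start for _, iv in rows])
        for chrom, rows in by_chrom.items()
    }
    for peak in distal:
        rows = by_chrom[peak.chrom]
        st = starts[peak.chrom]
        k = int(np.searchsorted(st, peak.end, side="left")) - 1
        # stitched regions are disjoint; each peak lies inside exactly one
        counts[rows[k][0]] += 1
    return [
        StitchedEnhancer(interval=iv, n_constituents=c)
        for iv, c in zip(merged, counts)
    ]


def tangent_cutoff(signals: Sequence[float]) -> tuple[float, np.ndarray]:
    """Slope-1 tangent cut of the ranked signal curve.

    Signals are sorted ascending; rank and signal are rescaled to [0, 1] and
    the cutoff is the signal at the left end of the first segment whose
    discrete slope exceeds 1. Returns (cutoff_signal, boolean super flags in
    input order), with is_super <=> signal > cutoff (strict, so ties at the
    cutoff stay non-super). All-equal signals yield zero super-enhancers with
    a warning.
    """
    s = np.asarray(signals, dtype=float)
    n = s.size
    if n < 3:
        raise ValueError("need >= 3 regions for the tangent cut")
    smin, smax = s.min(), s.max()
    if smax == smin:
        warnings.warn("all signals identical; no super-enhancers", stacklevel=2)
        return float(smax), np.zeros(n, dtype=bool)
    order = np.argsort(s, kind="stable")
    y = (s[order] - smin) / (smax - smin)
    # x spacing is uniform 1/(n-1): slope_i = (y[i+1]-y[i]) * (n-1)
    slopes = np.diff(y) * (n - 1)
    # strict ">" with a float guard so exactly-linear curves stay below
    above = np.flatnonzero(slopes > 1.0 + 1e-9)
    if above.size == 0:
        return float(smax), np.zeros(n, dtype=bool)
    cutoff = float(s[order][above[0]])
    return cutoff, s > cutoff


def call_sample_super_enhancers(
    track: SampleTrack,
    tss: Sequence[TSSRecord],
    stitch_distance: int = DEFAULT_STITCH_DISTANCE,
    tss_exclusion: int = DEFAULT_TSS_EXCLUSION,
    extension: int = 200,
    min_constituents: int = 2,
) -> list[StitchedEnhancer]:
    """Rank one sample's stitched regions by total signal and flag SEs.

    Region signal is the region-summed RPM (per-bp density x region length),
    the ROSE ranking convention, so long high-signal clusters rank top. The
    tangent cut is applied to the candidate set (regions with at least
    ``min_constituents`` peaks); singletons keep is_super = False.
    """
    if track.mark is not Mark.H3K27AC:
        raise ValueError("super-enhancer calling requires an H3K27ac track")
    stitched = stitch_enhancers(track.peaks, tss, stitch_distance, tss_exclusion)
    if len(stitched) < 3:
        raise ValueError(f"only {len(stitched)} stitched regions; need >= 3")
    for se in stitched:
        se.signal = compute_rpm(se.interval, track, extension) * len(se.interval)
    order = np.argsort([se.signal for se in stitched], kind="stable")
    for rank, idx in enumerate(order, start=1):
        stitched[idx].rank = rank
    candidates = [se for se in stitched if se.n_constituents >= min_constituents]
    if len(candidates) >= 3:
        _, flags = tangent_cutoff([se.signal for se in candidates])
        for se, flag in zip(candidates, flags):
            se.is_super = bool(flag)
    return stitched


def call_vsels(
    se_sets: Mapping[str, Mapping[str, Sequence[GenomicInterval]]],
    tracks: Sequence[SampleTrack],
    fc_threshold: float = 2.0,
    pseudocount: float = 0.5,
    min_vsels_per_patient: int = 10,
    alpha: float = 0.05,
    target_fraction: float = 0.9,
    extension: int = 200,
) -> VELResult:
    """Variant super-enhancer loci: the VEL pipeline on stitched-SE loci.

    ``se_sets`` maps patient_id -> {"tumor": SE intervals, "native": SE
    intervals} (typically the is_super regions of each sample). Per-pair
    fold-change calls, exclusion of patients with fewer than
    ``min_vsels_per_patient`` calls, cohort merge + recurrence, paired
    t-test + per-direction BH, and threshold selection at fraction 0.9.
    """
    loci_by_patient = {
        pid: merge_intervals(
            list(sets.get("tumor", [])) + list(sets.get("native", []))
        )
        for pid, sets in se_sets.items()
    }
    loci_by_patient = {pid: loci for pid, loci in loci_by_patient.items() if loci}
    if not loci_by_patient:
        raise ValueError("no super-enhancer loci in any patient")
    union_loci = sorted(
        {iv for loci in loci_by_patient.values() for iv in loci},
        key=lambda iv: (iv.chrom, iv.start, iv.end),
    )
    k27 = [t for t in tracks if t.mark is Mark.H3K27AC]
    signal = build_signal_matrix(union_loci, k27, extension)
    pair_calls = _vel.call_pair_vels(
        loci_by_patient, signal, fc_threshold, pseudocount
    )

    vsel_counts = {pid: 0 for pid in loci_by_patient}
    for call in pair_calls:
        vsel_counts[call.patient_id] += 1
    peak_counts = {
        pid: (len(loci), len(loci)) for pid, loci in loci_by_patient.items()
    }
    qc = qc_filter_patients(
        peak_counts, vsel_counts, min_peaks=0, min_vels=min_vsels_per_patient
    )
    retained = {r.patient_id for r in qc if not r.excluded}
    kept = [c for c in pair_calls if c.patient_id in retained]
    if not kept:
        return VELResult(
            records=[], qc=qc, thresholds={}, threshold_tables={}, pair_calls=pair_calls
        )
    merged = _vel.merge_and_count(kept)
    retained_tracks = [t for t in k27 if t.patient_id in retained]
    signal_merged = build_signal_matrix(
        [iv for iv, _, _ in merged], retained_tracks, extension
    )
    records, thresholds, tables = _vel.score_merged_loci(
        merged, signal_merged, alpha, target_fraction
    )
    return VELResult(
        records=records,
        qc=qc,
        thresholds=thresholds,
        threshold_tables=tables,
        signal=signal_merged,
        pair_calls=pair_calls,
    )


def _se_genes(
    intervals: Sequence[GenomicInterval],
    tss: Sequence[TSSRecord],
    max_distance: int,
) -> set[str]:
    """Genes assigned to a sample's SE set: TSS inside the SE, plus the
    nearest TSS within max_distance of the SE midpoint."""
    from .annotation import assign_genes

    genes: set[str] = set()
    nearest = assign_genes(intervals, tss, max_distance)
    for iv in intervals:
        genes.update(nearest[iv])
        for rec in tss:
            if rec.interval.chrom == iv.chrom and iv.start <= rec.position < iv.end:
                genes.add(rec.gene_id)
    return genes


def se_gene_recurrence(
    sample_ses: Mapping[str, Sequence[StitchedEnhancer]],
    tissues: Mapping[str, Tissue | str],
    tss: Sequence[TSSRecord],
    max_distance: int = 50_000,
) -> list[SEGeneRecord]:
    """Per-gene SE recurrence in tumor minus native samples.

    Each sample's super-enhancers are assigned to genes; a gene's recurrence
    in a tissue group is the number of samples whose SE set hits it. Output
    is sorted by variant recurrence (tumor - native) descending, ties by
    gene_id.
    """
    rec_t: dict[str, int] = {}
    rec_n: dict[str, int] = {}
    for sample_id, ses in sample_ses.items():
        supers = [se.interval for se in ses if se.is_super]
        genes = _se_genes(supers, tss, max_distance)
        bucket = rec_t if Tissue(tissues[sample_id]) is Tissue.TUMOR else rec_n
        for g in genes:
            bucket[g] = bucket.get(g, 0) + 1
    records = [
        SEGeneRecord(g, rec_t.get(g, 0), rec_n.get(g, 0))
        for g in set(rec_t) | set(rec_n)
    ]
    records.sort(key=lambda r: (-r.variant_recurrence, r.gene_id))
    return records
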