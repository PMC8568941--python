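"""Promoter/enhancer annotation relative to transcription start sites.

Active promoters are H3K4me3 peaks overlapping the +/-2.5 kb window around a
TSS; active enhancers are H3K27ac peaks lying entirely outside every such
window. Cohort-level "significant" elements are merged loci supported by
peaks from at least two samples of the same tissue type.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import (
    GenomicInterval,
    Mark,
    SampleTrack,
    Tissue,
    merge_intervals,
    read_bed,
)

__all__ = [
    "TSSRecord",
    "AnnotatedPeakSet",
    "read_tss",
    "classify_peaks",
    "annotate_track",
    "significant_elements",
    "saturation_curve",
    "assign_genes",
]

DEFAULT_TSS_WINDOW = 2500


@dataclass(frozen=True)
class TSSRecord:
    """A transcription start site: a width-1 interval tagged with its gene."""

    gene_id: str
    interval: GenomicInterval
    strand: str = "+"

    def __post_init__(self) -> None:
        if len(self.interval) != 1:
            raise ValueError("TSS interval must have width exactly 1")

    @property
    def position(self) -> int:
        return self.interval.start


@dataclass
class AnnotatedPeakSet:
    """One sample's peaks split into TSS-proximal promoters and distal enhancers."""

    sample_id: str
    promoters: list[GenomicInterval]
    enhancers: list[GenomicInterval]

    def __post_init__(self) -> None:
        overlap = set(self.promoters) & set(self.enhancers)
        if overlap:
            raise ValueError(f"peaks in both promoter and enhancer sets: {overlap}")


def read_tss(path) -> list[TSSRecord]:
    """Read TSS records from BED6 (name column = gene_id) or a 2+-column TSV.

    TSV columns: gene_id, chrom, position (0-based), optional strand.
    """
    records: list[TSSRecord] = []
    with open(path) as fh:
        first = fh.readline()
    fields = first.rstrip("\n").split("\t")
    is_bed = len(fields) >= 3 and fields[1].isdigit() and fields[2].isdigit()
    if is_bed:
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                f = line.rstrip("\n").split("\t")
                pos = int(f[1])
                strand = f[5] if len(f) >= 6 and f[5] in "+-" else "+"
                gene = f[3] if len(f) >= 4 else f"tss_{len(records)}"
                records.append(
                    TSSRecord(gene, GenomicInterval(f[0], pos, pos + 1), strand)
                )
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
        for _, row in df.iterrows():
            pos = int(row.iloc[2]) if len(row) >= 3 else int(row.iloc[1])
            chrom = row.iloc[1] if len(row) >= 3 else "chr1"
            strand = row.get("strand", "+") if "strand" in df.columns else "+"
            records.append(
                TSSRecord(str(row.iloc[0]), GenomicInterval(chrom, pos, pos + 1), strand)
            )
    return records


def _tss_windows(tss: Sequence[TSSRecord], window: int) -> dict[str, np.ndarray]:
    """Per-chromosome sorted [pos-window, pos+window) windows, merged."""
    wins: dict[str, list[GenomicInterval]] = {}
    for rec in tss:
        lo = max(0, rec.position - window)
        wins.setdefault(rec.interval.chrom, []).append(
            GenomicInterval(rec.interval.chrom, lo, rec.position + window)
        )
    out = {}
    for chrom, ivs in wins.items():
        merged = merge_intervals(ivs)
        out[chrom] = np.array([(iv.start, iv.end) for iv in merged], dtype=np.int64)
    return out


def _overlaps_any(windows: dict[str, np.ndarray], iv: GenomicInterval) -> bool:
    arr = windows.get(iv.chrom)
    if arr is None or not len(arr):
        return False
    starts, ends = arr[:, 0], arr[:, 1]
    # windows are merged & sorted: candidate is the last window starting before iv.end
    k = np.searchsorted(starts, iv.end, side="left") - 1
    return k >= 0 and ends[k] > iv.start


def classify_peaks(
    peaks: Sequence[GenomicInterval],
    mark: Mark | str,
    tss: Sequence[TSSRecord],
    window: int = DEFAULT_TSS_WINDOW,
    sample_id: str = "",
) -> AnnotatedPeakSet:
    """Split one sample's peaks into promoters and enhancers.

    A peak is TSS-proximal iff it overlaps [tss - window, tss + window) for
    any TSS (any-overlap rule, half-open). H3K4me3 proximal peaks become
    promoters; H3K27ac non-proximal peaks become enhancers; other
    combinations are discarded.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    if not tss:
        raise ValueError("TSS list is empty; classification undefined")
    mark = Mark(mark)
    windows = _tss_windows(tss, window)
    promoters: list[GenomicInterval] = []
    enhancers: list[GenomicInterval] = []
    for peak in peaks:
        proximal = _overlaps_any(windows, peak)
        if mark is Mark.H3K4ME3 and proximal:
            promoters.append(peak)
        elif mark is Mark.H3K27AC and not proximal:
            enhancers.append(peak)
    return AnnotatedPeakSet(sample_id=sample_id, promoters=promoters, enhancers=enhancers)


def annotate_track(
    track: SampleTrack, tss: Sequence[TSSRecord], window: int = DEFAULT_TSS_WINDOW
) -> AnnotatedPeakSet:
    return classify_peaks(track.peaks, track.mark, tss, window, sample_id=track.sample_id)


def _support_counts(
    merged: Sequence[GenomicInterval],
    peak_sets: Mapping[str, Sequence[GenomicInterval]],
) -> np.ndarray:
    """Number of distinct samples with >= 1 bp of peak overlap per merged locus."""
    counts = np.zeros(len(merged), dtype=int)
    by_chrom: dict[str, list[tuple[int, GenomicInterval]]] = {}
    for i, iv in enumerate(merged):
        by_chrom.setdefault(iv.chrom, []).append((i, iv))
    starts = {
        chrom: np.array([iv.start for _, iv in rows])
        for chrom, rows in by_chrom.items()
    }
    for _, peaks in peak_sets.items():
        hit: set[int] = set()
        for peak in peaks:
            rows = by_chrom.get(peak.chrom)
            if not rows:
                continue
            st = starts[peak.chrom]
            # merged loci are disjoint & sorted: scan loci starting before peak.end
            k = int(np.searchsorted(st, peak.end, side="left")) - 1
            while k >= 0:
                idx, iv = rows[k]
                if iv.end <= peak.start:
                    break
                hit.add(idx)
                k -= 1
        for idx in hit:
            counts[idx] += 1
    return counts


def significant_elements(
    annotated: Sequence[AnnotatedPeakSet],
    element: str = "enhancers",
    min_samples: int = 2,
    return_support: bool = False,
):
    """Cohort-level merged loci supported by >= min_samples distinct samples.

    All samples' elements (``"enhancers"`` or ``"promoters"``) are merged with
    gap=0; a merged locus is kept iff peaks from at least ``min_samples``
    distinct samples overlap it.
    """
    if len(annotated) < min_samples:
        raise ValueError(
            f"need >= {min_samples} annotated sets, got {len(annotated)}"
        )
    peak_sets = {a.sample_id or str(i): getattr(a, element) for i, a in enumerate(annotated)}
    merged = merge_intervals([iv for peaks in peak_sets.values() for iv in peaks])
    counts = _support_counts(merged, peak_sets)
    kept = [(iv, int(c)) for iv, c in zip(merged, counts) if c >= min_samples]
    if return_support:
        return [iv for iv, _ in kept], [c for _, c in kept]
    return [iv for iv, _ in kept]


def saturation_curve(
    per_sample_enhancers: Sequence[Sequence[GenomicInterval]],
    reference: Sequence[GenomicInterval],
    n_permutations: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Discovery saturation: % of reference loci found in growing sample unions.

    For each random permutation of sample order and each prefix length k, the
    fraction of reference loci overlapped by the cumulative peak union is
    computed; the mean over permutations is reported as a percentage. Each
    per-permutation curve is monotone non-decreasing in k.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if not reference:
        raise ValueError("reference set is empty")
    rng = np.random.default_rng(seed)
    n = len(per_sample_enhancers)
    ref_by_chrom: dict[str, list[tuple[int, GenomicInterval]]] = {}
    for i, iv in enumerate(reference):
        ref_by_chrom.setdefault(iv.chrom, []).append((i, iv))
    for rows in ref_by_chrom.values():
        rows.sort(key=lambda t: t[1].start)
    ref_starts = {
        chrom: np.array([iv.start for _, iv in rows])
        for chrom, rows in ref_by_chrom.items()
    }
    ref_maxlen = {
        chrom: max(len(iv) for _, iv in rows) for chrom, rows in ref_by_chrom.items()
    }

    def covered_by(peaks: Sequence[GenomicInterval]) -> set[int]:
        found: set[int] = set()
        for peak in peaks:
            rows = ref_by_chrom.get(peak.chrom)
            if not rows:
                continue
            st = ref_starts[peak.chrom]
            max_len = ref_maxlen[peak.chrom]
            k = int(np.searchsorted(st, peak.end, side="left")) - 1
            # reference loci may overlap each other; bounded left scan
            while k >= 0 and peak.start - st[k] < max_len:
                idx, iv = rows[k]
                if iv.overlaps(peak):
                    found.add(idx)
                k -= 1
        return found

    per_sample_cover = [covered_by(peaks) for peaks in per_sample_enhancers]
    fractions = np.zeros((n_permutations, n))
    for p in range(n_permutations):
        order = rng.permutation(n)
        seen: set[int] = set()
        for k, j in enumerate(order):
            seen |= per_sample_cover[j]
            fractions[p, k] = len(seen) / len(reference)
    return pd.DataFrame(
        {
            "n_samples": np.arange(1, n + 1),
            "mean_pct_discovered": fractions.mean(axis=0) * 100.0,
        }
    )


def assign_genes(
    loci: Sequence[GenomicInterval],
    tss: Sequence[TSSRecord],
    max_distance: int = 100_000,
) -> dict[GenomicInterval, list[str]]:
    """Assign each locus to the gene(s) of the nearest TSS within max_distance.

    Distance is locus midpoint to TSS position; exact ties report every tied
    gene, sorted by gene_id. Loci with no TSS in range map to an empty list.
    """
    if max_distance <= 0:
        raise ValueError("max_distance must be > 0")
    by_chrom: dict[str, tuple[np.ndarray, list[str]]] = {}
    for chrom in {r.interval.chrom for r in tss}:
        recs = sorted(
            (r for r in tss if r.interval.chrom == chrom), key=lambda r: r.position
        )
        by_chrom[chrom] = (np.array([r.position for r in recs]), [r.gene_id for r in recs])
    out: dict[GenomicInterval, list[str]] = {}
    for locus in loci:
        entry = by_chrom.get(locus.chrom)
        if entry is None:
            out[locus] = []
            continue
        positions, genes = entry
        mid = locus.midpoint
        dists = np.abs(positions - mid)
        best = dists.min()
        if best > max_distance:
            out[locus] = []
        else:
            out[locus] = sorted({genes[i] for i in np.flatnonzero(dists == best)})
    return out
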