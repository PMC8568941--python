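"""Variant enhancer locus (VEL) calling from paired tumor/native H3K27ac signal.

A VEL is an enhancer whose signal changes more than 2-fold between a
patient's tumor and matched native tissue ("gain" = higher in tumor,
"lost" = lower). Per-pair calls are merged across the cohort; each merged
locus gets a recurrence (number of supporting patients), a two-sided paired
t-test across all retained pairs, and a Benjamini-Hochberg adjusted p-value.
The recurrence threshold r* is the smallest recurrence at which the
cumulative set of loci (recurrence >= r*) is at least 95% significant
(90% for the super-enhancer and subgroup analyses).
"""

from __future__ import annotations

import enum
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotation import TSSRecord, annotate_track
from .intervals import (
    GenomicInterval,
    SampleTrack,
    SignalMatrix,
    Tissue,
    build_signal_matrix,
    merge_intervals,
)

__all__ = [
    "Direction",
    "PairVELCall",
    "VELRecord",
    "QCReport",
    "VELConfig",
    "VELResult",
    "qc_filter_patients",
    "call_pair_vels",
    "merge_and_count",
    "paired_t_test",
    "bh_adjust",
    "select_recurrence_threshold",
    "subgroup_specific_vels",
    "run_vel_pipeline",
]


class Direction(str, enum.Enum):
    GAIN = "gain"
    LOST = "lost"


@dataclass(frozen=True)
class PairVELCall:
    """One patient's variant-enhancer call at one locus."""

    patient_id: str
    locus: GenomicInterval
    direction: Direction
    fc: float  # tumor/native signal ratio (pseudocounted)

    def __post_init__(self) -> None:
        if self.fc <= 0:
            raise ValueError("fold change must be positive")


@dataclass
class VELRecord:
    """A merged variant locus with recurrence and significance statistics."""

    locus: GenomicInterval
    direction: Direction
    recurrence: int
    t_stat: float = float("nan")
    p_raw: float = float("nan")
    p_adj: float = float("nan")
    significant: bool = False


@dataclass
class QCReport:
    patient_id: str
    n_peaks_tumor: int
    n_peaks_native: int
    n_vels: int
    excluded: bool
    reason: str = ""

    def __post_init__(self) -> None:
        if self.excluded and not self.reason:
            raise ValueError("excluded patients must carry a reason")


@dataclass
class VELConfig:
    """Tunable parameters of the VEL pipeline.

    Defaults follow the published genome-scale analysis; the QC minima scale
    with the size of the peak universe and should be reduced proportionally
    for small simulated genomes.
    """

    fc_threshold: float = 2.0
    pseudocount: float = 0.5  # RPM added to both tissues in the fold change
    alpha: float = 0.05
    target_fraction: float = 0.95
    min_peaks: int = 2500
    min_vels: int = 500
    tss_window: int = 2500
    extension: int = 200


@dataclass
class VELResult:
    """Output of :func:`run_vel_pipeline`."""

    records: list[VELRecord]
    qc: list[QCReport]
    thresholds: dict[Direction, int | None]
    threshold_tables: dict[Direction, pd.DataFrame]
    signal: SignalMatrix | None = None
    pair_calls: list[PairVELCall] = field(default_factory=list)

    def significant_records(self, direction: Direction | None = None) -> list[VELRecord]:
        return [
            r
            for r in self.records
            if r.significant and (direction is None or r.direction == direction)
        ]

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "chrom": r.locus.chrom,
                "start": r.locus.start,
                "end": r.locus.end,
                "direction": r.direction.value,
                "recurrence": r.recurrence,
                "t_stat": r.t_stat,
                "p_raw": r.p_raw,
                "p_adj": r.p_adj,
                "significant": r.significant,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows)


def qc_filter_patients(
    peak_counts: Mapping[str, tuple[int, int]],
    vel_counts: Mapping[str, int],
    min_peaks: int = 2500,
    min_vels: int = 500,
) -> list[QCReport]:
    """Flag patients failing the peak-number or VEL-number minima.

    ``peak_counts`` maps patient_id -> (n_peaks_tumor, n_peaks_native);
    ``vel_counts`` maps patient_id -> gain+lost VEL count. Exclusion is
    strict "less than": a patient at exactly the minimum is retained.
    """
    reports = []
    for pid in sorted(peak_counts):
        if pid not in vel_counts:
            raise ValueError(f"patient {pid} has no VEL count (unpaired?)")
        n_t, n_n = peak_counts[pid]
        n_v = vel_counts[pid]
        reasons = []
        if min(n_t, n_n) < min_peaks:
            reasons.append(f"peak count {min(n_t, n_n)} < {min_peaks}")
        if n_v < min_vels:
            reasons.append(f"VEL count {n_v} < {min_vels}")
        reports.append(
            QCReport(
                patient_id=pid,
                n_peaks_tumor=n_t,
                n_peaks_native=n_n,
                n_vels=n_v,
                excluded=bool(reasons),
                reason="; ".join(reasons),
            )
        )
    return reports


def call_pair_vels(
    enhancers: Mapping[str, Sequence[GenomicInterval]],
    signal: SignalMatrix,
    fc_threshold: float = 2.0,
    pseudocount: float = 0.5,
) -> list[PairVELCall]:
    """Per-patient gain/lost calls at each of the patient's enhancer loci.

    fc = (RPM_tumor + pseudocount) / (RPM_native + pseudocount); a locus is a
    gain iff fc > fc_threshold, lost iff fc < 1/fc_threshold (both strict).
    """
    if fc_threshold <= 1:
        raise ValueError("fc_threshold must be > 1")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    calls: list[PairVELCall] = []
    for patient_id, loci in enhancers.items():
        if patient_id not in signal.pairing:
            raise ValueError(f"patient {patient_id} not paired in signal matrix")
        tumor_id, native_id = signal.pairing[patient_id]
        jt, jn = signal.sample_col(tumor_id), signal.sample_col(native_id)
        for locus in loci:
            row = signal.values[signal.locus_row(locus)]
            num, den = row[jt] + pseudocount, row[jn] + pseudocount
            if den == 0:  # only possible at pseudocount 0
                if num == 0:
                    continue
                fc = float("inf")
            else:
                fc = num / den
            if fc > fc_threshold:
                calls.append(PairVELCall(patient_id, locus, Direction.GAIN, fc))
            elif fc != 0 and 1.0 / fc > fc_threshold:
                calls.append(PairVELCall(patient_id, locus, Direction.LOST, fc))
    return calls


def merge_and_count(
    calls: Sequence[PairVELCall],
) -> list[tuple[GenomicInterval, Direction, int]]:
    """Merge same-direction calls (gap=0) and count distinct supporting patients."""
    if not calls:
        raise ValueError("no VEL calls to merge")
    out: list[tuple[GenomicInterval, Direction, int]] = []
    for direction in (Direction.GAIN, Direction.LOST):
        dcalls = [c for c in calls if c.direction == direction]
        if not dcalls:
            continue
        merged = merge_intervals([c.locus for c in dcalls])
        by_chrom: dict[str, list[tuple[int, GenomicInterval]]] = {}
        for i, iv in enumerate(merged):
            by_chrom.setdefault(iv.chrom, []).append((i, iv))
        starts = {
            chrom: np.array([iv.start for _, iv in rows])
            for chrom, rows in by_chrom.items()
        }
        supporters: list[set[str]] = [set() for _ in merged]
        for call in dcalls:
            rows = by_chrom.get(call.locus.chrom)
            st = starts[call.locus.chrom]
            # merged loci are disjoint & sorted; every call lies within one
            k = int(np.searchsorted(st, call.locus.end, side="left")) - 1
            while k >= 0:
                idx, iv = rows[k]
                if iv.end <= call.locus.start:
                    break
                supporters[idx].add(call.patient_id)
                k -= 1
        out.extend(
            (iv, direction, len(sup)) for iv, sup in zip(merged, supporters)
        )
    return out


def paired_t_test(
    tumor_values: Sequence[float], native_values: Sequence[float]
) -> tuple[float, float]:
    """Two-sided paired t-test on tumor - native differences.

    t = mean(d) / (sd(d)/sqrt(n)) with the n-1 sample standard deviation;
    p from Student's t with n-1 df. Degenerate zero-variance differences
    return p=1 (all-zero) or p=0 (constant non-zero shift) by convention.
    """
    d = np.asarray(tumor_values, dtype=float) - np.asarray(native_values, dtype=float)
    n = d.size
    if n < 2 or len(tumor_values) != len(native_values):
        raise ValueError("need equal-length vectors with n >= 2")
    sd = d.std(ddof=1)
    m = d.mean()
    if sd == 0:
        if m == 0:
            return 0.0, 1.0
        return float(np.sign(m)) * float("inf"), 0.0
    t = m / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adj_(i) = min_{j>=i} p_(j) * m / j on the sorted vector, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    np.clip(adj_sorted, 0.0, 1.0, out=adj_sorted)
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj


def select_recurrence_threshold(
    records: Sequence[VELRecord],
    alpha: float = 0.05,
    target_fraction: float = 0.95,
) -> tuple[int | None, pd.DataFrame]:
    """Smallest recurrence r* whose cumulative set is >= target_fraction significant.

    For each candidate r (1..max recurrence), fraction(r) is the share of
    records with recurrence >= r having p_adj < alpha. Returns (r*, table);
    r* is None when no candidate reaches the target.
    """
    if not 0 < target_fraction <= 1:
        raise ValueError("target_fraction must be in (0, 1]")
    if not records:
        raise ValueError("no records")
    rec = np.array([r.recurrence for r in records])
    sig = np.array([r.p_adj < alpha for r in records])
    rows = []
    r_star: int | None = None
    for r in range(1, int(rec.max()) + 1):
        mask = rec >= r
        n = int(mask.sum())
        frac = float(sig[mask].mean()) if n else float("nan")
        rows.append({"recurrence": r, "n_records": n, "fraction_significant": frac})
        if r_star is None and n and frac >= target_fraction:
            r_star = r
    return r_star, pd.DataFrame(rows)


def subgroup_specific_vels(
    gain_vels: Sequence[GenomicInterval],
    signal: SignalMatrix,
    cms_labels: Mapping[str, str],
    ratio: float = 1.5,
) -> dict[str, list[GenomicInterval]]:
    """Gain VELs whose mean tumor signal in one subgroup exceeds ratio x every other.

    ``cms_labels`` maps tumor sample_id -> subgroup label. A locus is
    specific to subgroup S iff its mean RPM over S tumor samples is strictly
    greater than ratio times the mean of each other subgroup; a locus can be
    specific to at most one subgroup.
    """
    if ratio <= 1:
        raise ValueError("ratio must be > 1")
    groups: dict[str, list[int]] = {}
    for sample_id, label in cms_labels.items():
        groups.setdefault(label, []).append(signal.sample_col(sample_id))
    if len(groups) < 2:
        raise ValueError("need >= 2 subgroups")
    for label, cols in groups.items():
        if not cols:
            raise ValueError(f"subgroup {label} has no tumor samples")
    labels = sorted(groups)
    out: dict[str, list[GenomicInterval]] = {label: [] for label in labels}
    for locus in gain_vels:
        row = signal.values[signal.locus_row(locus)]
        means = {label: float(row[groups[label]].mean()) for label in labels}
        for label in labels:
            if all(
                means[label] > ratio * means[other]
                for other in labels
                if other != label
            ):
                out[label].append(locus)
                break  # specific to at most one subgroup
    return out


def _patient_enhancer_loci(
    tracks: Sequence[SampleTrack], tss: Sequence[TSSRecord], tss_window: int
) -> tuple[dict[str, list[GenomicInterval]], dict[str, tuple[int, int]]]:
    """Per-patient merged enhancer loci (tumor U native) and raw peak counts."""
    by_patient: dict[str, dict[Tissue, SampleTrack]] = {}
    for track in tracks:
        by_patient.setdefault(track.patient_id, {})[track.tissue] = track
    loci: dict[str, list[GenomicInterval]] = {}
    peak_counts: dict[str, tuple[int, int]] = {}
    for pid, pair in by_patient.items():
        if Tissue.TUMOR not in pair or Tissue.NATIVE not in pair:
            raise ValueError(f"patient {pid} lacks a tumor/native pair")
        tum, nat = pair[Tissue.TUMOR], pair[Tissue.NATIVE]
        enh = []
        for track in (tum, nat):
            enh.extend(annotate_track(track, tss, tss_window).enhancers)
        loci[pid] = merge_intervals(enh)
        peak_counts[pid] = (len(tum.peaks), len(nat.peaks))
    return loci, peak_counts


def score_merged_loci(
    merged: Sequence[tuple[GenomicInterval, Direction, int]],
    signal: SignalMatrix,
    alpha: float,
    target_fraction: float,
) -> tuple[list[VELRecord], dict[Direction, int | None], dict[Direction, pd.DataFrame]]:
    """Paired t-test + per-direction BH + recurrence threshold on merged loci."""
    records = [
        VELRecord(locus=iv, direction=d, recurrence=r) for iv, d, r in merged
    ]
    for rec in records:
        tumor, native = signal.paired_vectors(rec.locus)
        rec.t_stat, rec.p_raw = paired_t_test(tumor, native)
    thresholds: dict[Direction, int | None] = {}
    tables: dict[Direction, pd.DataFrame] = {}
    for direction in (Direction.GAIN, Direction.LOST):
        drecs = [r for r in records if r.direction == direction]
        if not drecs:
            thresholds[direction] = None
            tables[direction] = pd.DataFrame(
                columns=["recurrence", "n_records", "fraction_significant"]
            )
            continue
        adj = bh_adjust([r.p_raw for r in drecs])
        for r, a in zip(drecs, adj):
            r.p_adj = float(a)
        r_star, table = select_recurrence_threshold(drecs, alpha, target_fraction)
        thresholds[direction] = r_star
        tables[direction] = table
        for r in drecs:
            r.significant = (
                r_star is not None and r.p_adj < alpha and r.recurrence >= r_star
            )
    return records, thresholds, tables


def run_vel_pipeline(
    tracks: Sequence[SampleTrack],
    tss: Sequence[TSSRecord],
    config: VELConfig | None = None,
) -> VELResult:
    """End-to-end VEL calling on a paired H3K27ac cohort.

    Steps: per-sample enhancer annotation -> per-patient merged enhancer loci
    -> per-pair fold-change calls -> patient QC (peak and VEL minima) ->
    cohort merge + recurrence -> paired t-test and per-direction BH over all
    retained pairs -> recurrence-threshold selection and significance flags.
    """
    cfg = config or VELConfig()
    loci_by_patient, peak_counts = _patient_enhancer_loci(tracks, tss, cfg.tss_window)

    # quantify each patient's own loci via one matrix over the union
    union_loci = sorted(
        {iv for loci in loci_by_patient.values() for iv in loci},
        key=lambda iv: (iv.chrom, iv.start, iv.end),
    )
    signal_pairs = build_signal_matrix(union_loci, tracks, cfg.extension)
    pair_calls = call_pair_vels(
        loci_by_patient, signal_pairs, cfg.fc_threshold, cfg.pseudocount
    )

    vel_counts = {pid: 0 for pid in loci_by_patient}
    for call in pair_calls:
        vel_counts[call.patient_id] += 1
    qc = qc_filter_patients(peak_counts, vel_counts, cfg.min_peaks, cfg.min_vels)
    retained = {r.patient_id for r in qc if not r.excluded}
    if not retained:
        return VELResult(
            records=[], qc=qc, thresholds={}, threshold_tables={}, pair_calls=pair_calls
        )

    kept_calls = [c for c in pair_calls if c.patient_id in retained]
    if not kept_calls:
        return VELResult(
            records=[], qc=qc, thresholds={}, threshold_tables={}, pair_calls=pair_calls
        )
    merged = merge_and_count(kept_calls)
    retained_tracks = [t for t in tracks if t.patient_id in retained]
    signal_merged = build_signal_matrix(
        [iv for iv, _, _ in merged], retained_tracks, cfg.extension
    )
    records, thresholds, tables = score_merged_loci(
        merged, signal_merged, cfg.alpha, cfg.target_fraction
    )
    return VELResult(
        records=records,
        qc=qc,
        thresholds=thresholds,
        threshold_tables=tables,
        signal=signal_merged,
        pair_calls=pair_calls,
    )
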