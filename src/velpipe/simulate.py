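"""Synthetic paired tumor/native H3K27ac cohort generator.

Emulates the statistical structure the VEL/VSEL analysis assumes: a toy
genome with TSS annotations and non-overlapping enhancer loci, planted gain
and lost variant loci of configurable effect size carried by a fixed
fraction of patients, planted super-enhancer clusters (three peaks within
the stitching distance at 10x background signal), optional CMS-style
subgroup structure, and negative-binomial per-locus fragment counts.

All randomness flows from ``SimConfig.seed``; the same config yields
byte-identical output. Peak calls are emitted as the true loci a sample
expresses (count above a detection floor), mimicking a peak caller's
sensitivity without implementing one.
"""

from __future__ import annotations

import os
from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import TSSRecord
from .intervals import (
    Fragment,
    FragmentSet,
    GenomicInterval,
    Mark,
    SampleTrack,
    Tissue,
    write_bed,
)

__all__ = ["SimConfig", "GroundTruth", "simulate_cohort", "plant_subgroup_signal", "write_fixture"]

READ_LENGTH = 36


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe a desk-scale paired cohort: 40 tumor/native pairs over
    a 60-Mb single-chromosome genome with 2,000 one-kb enhancers, 200 planted
    gain and 50 planted lost variant loci at a 3x tumor:native signal ratio
    carried by 75% of patients, and 10 three-peak super-enhancer clusters
    (6 of them gaining in tumors). Counts are negative-binomial with variance
    mu + dispersion * mu^2.
    """

    seed: int = 0
    n_patients: int = 40
    genome: list[tuple[str, int]] = field(default_factory=lambda: [("chr1", 60_000_000)])
    n_enhancers: int = 2000
    n_tss: int = 400
    planted_gain: int = 200
    planted_lost: int = 50
    effect_ratio: float = 3.0
    recurrence_fraction: float = 0.75
    n_planted_ses: int = 10
    n_se_gain: int = 6
    se_span: int = 10_000
    subgroups: dict[str, float] | None = None
    n_subgroup_specific: int = 0
    subgroup_boost: float = 3.0
    nb_dispersion: float = 0.05
    base_rate: float = 50.0
    library_size: int = 250_000  # per-sample total reads; padded with background
    enhancer_width: int = 1000
    detection_floor: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.recurrence_fraction <= 1:
            raise ValueError("recurrence_fraction must be in (0, 1]")
        if self.effect_ratio < 1:
            raise ValueError("effect_ratio must be >= 1")
        if min(self.n_enhancers, self.planted_gain, self.planted_lost,
               self.n_planted_ses, self.n_tss, self.n_patients) < 0:
            raise ValueError("counts must be >= 0")
        if self.planted_gain + self.planted_lost + (self.n_subgroup_specific or 0) > self.n_enhancers:
            raise ValueError("more planted loci than enhancers")
        if self.subgroups is not None and abs(sum(self.subgroups.values()) - 1) > 1e-9:
            raise ValueError("subgroup shares must sum to 1")


@dataclass
class GroundTruth:
    """What was planted where: the oracle for recovery tests."""

    enhancers: list[GenomicInterval]
    tss: list[TSSRecord]
    gain_loci: list[GenomicInterval]
    lost_loci: list[GenomicInterval]
    carriers: dict[GenomicInterval, list[str]]  # planted locus -> patient ids
    se_clusters: list[list[GenomicInterval]]  # each: the 3 constituent peaks
    se_gain_clusters: list[int]  # indices into se_clusters that gain in tumors
    subgroup_specific: dict[GenomicInterval, str]
    subgroup_of_patient: dict[str, str]
    peak_sets: dict[str, list[GenomicInterval]]  # sample_id -> emitted peaks

    @property
    def se_intervals(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(p[0].chrom, p[0].start, p[-1].end)
            for p in self.se_clusters
        ]


def _layout_genome(cfg: SimConfig, rng: np.random.Generator):
    """Place TSS, enhancers and SE clusters left-to-right with random gaps.

    Elements are shuffled, then laid out sequentially with gaps drawn uniform
    in [4 kb, 12 kb], which keeps every enhancer > 2.5 kb from every TSS and
    separates neighbouring elements by more than the peak-merge gap while the
    order along the chromosome stays random.
    """
    specs: list[tuple[str, int]] = (
        [("tss", i) for i in range(cfg.n_tss)]
        + [("enh", i) for i in range(cfg.n_enhancers)]
        + [("se", i) for i in range(cfg.n_planted_ses)]
    )
    rng.shuffle(specs)
    tss: list[TSSRecord | None] = [None] * cfg.n_tss
    enhancers: list[GenomicInterval | None] = [None] * cfg.n_enhancers
    clusters: list[list[GenomicInterval] | None] = [None] * cfg.n_planted_ses
    chrom_iter = iter(cfg.genome)
    chrom, length = next(chrom_iter)
    cursor = 10_000
    for kind, idx in specs:
        gap = int(rng.integers(4_000, 12_000))
        cursor += gap
        if kind == "tss":
            span = 1
        elif kind == "enh":
            span = cfg.enhancer_width
        else:
            span = cfg.se_span
        while cursor + span + 10_000 > length:
            nxt = next(chrom_iter, None)
            if nxt is None:
                raise ValueError("genome too small to place all loci without overlap")
            chrom, length = nxt
            cursor = 10_000 + int(rng.integers(4_000, 12_000))
        if kind == "tss":
            tss[idx] = TSSRecord(
                f"gene_{idx:04d}",
                GenomicInterval(chrom, cursor, cursor + 1),
                "+" if rng.random() < 0.5 else "-",
            )
        elif kind == "enh":
            enhancers[idx] = GenomicInterval(chrom, cursor, cursor + span)
        else:
            # three constituent peaks evenly spread across the cluster span
            w = cfg.enhancer_width
            offsets = np.linspace(0, cfg.se_span - w, 3).astype(int)
            clusters[idx] = [
                GenomicInterval(chrom, cursor + int(o), cursor + int(o) + w)
                for o in offsets
            ]
        cursor += span
    return list(tss), list(enhancers), list(clusters)


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws with variance mean + dispersion * mean^2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_cohort(cfg: SimConfig) -> tuple[list[SampleTrack], GroundTruth]:
    """Generate paired H3K27ac SampleTracks plus the planted ground truth."""
    rng = np.random.default_rng(cfg.seed)
    tss, enhancers, clusters = _layout_genome(cfg, rng)

    patients = [f"P{i:03d}" for i in range(cfg.n_patients)]
    n_carriers = int(np.ceil(cfg.recurrence_fraction * cfg.n_patients))

    # planted loci: the first planted_gain + planted_lost enhancers after a
    # seeded shuffle of the enhancer list
    enh_order = rng.permutation(cfg.n_enhancers)
    gain_loci = [enhancers[i] for i in enh_order[: cfg.planted_gain]]
    lost_loci = [
        enhancers[i]
        for i in enh_order[cfg.planted_gain : cfg.planted_gain + cfg.planted_lost]
    ]
    subgroup_pool = [
        enhancers[i]
        for i in enh_order[
            cfg.planted_gain + cfg.planted_lost :
            cfg.planted_gain + cfg.planted_lost + (cfg.n_subgroup_specific or 0)
        ]
    ]

    carriers: dict[GenomicInterval, list[str]] = {}
    for locus in gain_loci + lost_loci:
        order = rng.permutation(cfg.n_patients)
        carriers[locus] = sorted(patients[i] for i in order[:n_carriers])

    se_gain_idx = sorted(
        int(i) for i in rng.permutation(cfg.n_planted_ses)[: cfg.n_se_gain]
    )
    se_carriers: dict[int, set[str]] = {}
    for ci in se_gain_idx:
        order = rng.permutation(cfg.n_patients)
        se_carriers[ci] = {patients[i] for i in order[:n_carriers]}

    subgroup_of_patient: dict[str, str] = {}
    subgroup_specific: dict[GenomicInterval, str] = {}
    if cfg.subgroups:
        labels = sorted(cfg.subgroups)
        # deterministic proportional assignment on a seeded patient shuffle
        shuffled = [patients[i] for i in rng.permutation(cfg.n_patients)]
        counts = {lab: int(round(cfg.subgroups[lab] * cfg.n_patients)) for lab in labels}
        while sum(counts.values()) < cfg.n_patients:
            counts[labels[0]] += 1
        while sum(counts.values()) > cfg.n_patients:
            counts[max(labels, key=lambda l: counts[l])] -= 1
        pos = 0
        for lab in labels:
            for pid in shuffled[pos : pos + counts[lab]]:
                subgroup_of_patient[pid] = lab
            pos += counts[lab]
        for j, locus in enumerate(subgroup_pool):
            subgroup_specific[locus] = labels[j % len(labels)]

    # per-locus universe: enhancers + SE constituent peaks
    all_loci: list[GenomicInterval] = list(enhancers)
    locus_kind: list[tuple[str, int]] = [("enh", i) for i in range(len(enhancers))]
    for ci, cluster in enumerate(clusters):
        for peak in cluster:
            all_loci.append(peak)
            locus_kind.append(("se", ci))
    gain_set = {iv: carriers[iv] for iv in gain_loci}
    lost_set = {iv: carriers[iv] for iv in lost_loci}

    tracks: list[SampleTrack] = []
    peak_sets: dict[str, list[GenomicInterval]] = {}
    for pid in patients:
        for tissue in (Tissue.TUMOR, Tissue.NATIVE):
            mean = np.full(len(all_loci), cfg.base_rate)
            for li, (kind, ki) in enumerate(locus_kind):
                locus = all_loci[li]
                if kind == "se":
                    mean[li] = cfg.base_rate * 10.0
                    if (
                        tissue is Tissue.TUMOR
                        and ki in se_carriers
                        and pid in se_carriers[ki]
                    ):
                        mean[li] *= cfg.effect_ratio
                elif tissue is Tissue.TUMOR:
                    # subgroup-specific boosts are added afterwards by
                    # plant_subgroup_signal, not here
                    if locus in gain_set and pid in carriers[locus]:
                        mean[li] = cfg.base_rate * cfg.effect_ratio
                    elif locus in lost_set and pid in carriers[locus]:
                        mean[li] = cfg.base_rate / cfg.effect_ratio
            counts = _nb_counts(rng, mean, cfg.nb_dispersion)
            sample_id = f"{pid}_{'T' if tissue is Tissue.TUMOR else 'N'}"
            chroms: list[str] = []
            starts_all: list[np.ndarray] = []
            for li, locus in enumerate(all_loci):
                c = int(counts[li])
                if c == 0:
                    continue
                lo = max(0, locus.start - 100)
                hi = locus.end + 100 - READ_LENGTH
                pos = rng.integers(lo, hi, size=c)
                starts_all.append(np.sort(pos))
                chroms.extend([locus.chrom] * c)
            # pad with genome-wide background reads to the nominal depth, as
            # in real libraries where peak reads are a minor share of the
            # total; keeps tumor and native library sizes comparable so RPM
            # normalisation introduces no spurious compositional shift
            n_signal = int(counts.sum())
            n_bg = max(0, cfg.library_size - n_signal)
            if n_bg:
                g_lens = np.array([L for _, L in cfg.genome], dtype=float)
                per_chrom = rng.multinomial(n_bg, g_lens / g_lens.sum())
                for (gchrom, glen), c in zip(cfg.genome, per_chrom):
                    if c == 0:
                        continue
                    pos = rng.integers(0, glen - READ_LENGTH, size=int(c))
                    starts_all.append(np.sort(pos))
                    chroms.extend([gchrom] * int(c))
            if starts_all:
                starts = np.concatenate(starts_all)
                strands = np.where(
                    rng.random(starts.size) < 0.5, "+", "-"
                ).astype("U1")
                frags = FragmentSet.from_arrays(
                    chroms, starts, starts + READ_LENGTH, strands, sample_id=sample_id
                )
            else:
                frags = FragmentSet(sample_id=sample_id)
            peaks = sorted(
                locus
                for li, locus in enumerate(all_loci)
                if counts[li] >= cfg.detection_floor
            )
            lib = max(1, len(frags))
            track = SampleTrack(
                sample_id=sample_id,
                patient_id=pid,
                tissue=tissue,
                mark=Mark.H3K27AC,
                peaks=peaks,
                fragments=frags,
                library_size=lib,
                cms=subgroup_of_patient.get(pid),
            )
            tracks.append(track)
            peak_sets[sample_id] = peaks

    truth = GroundTruth(
        enhancers=enhancers,
        tss=tss,
        gain_loci=gain_loci,
        lost_loci=lost_loci,
        carriers=carriers,
        se_clusters=clusters,
        se_gain_clusters=se_gain_idx,
        subgroup_specific=subgroup_specific,
        subgroup_of_patient=subgroup_of_patient,
        peak_sets=peak_sets,
    )
    return tracks, truth


def plant_subgroup_signal(
    tracks: Sequence[SampleTrack],
    truth: GroundTruth,
    cfg: SimConfig,
) -> list[SampleTrack]:
    """Boost designated loci in tumor samples of their assigned subgroup.

    No-op when the config declares no subgroups. Each subgroup-specific locus
    gains extra negative-binomial fragments in the tumor samples of its
    subgroup so its mean rises to ``subgroup_boost`` x the other subgroups'.
    Randomness derives from ``cfg.seed`` on a separate stream, so repeated
    application with the same inputs is deterministic.
    """
    if not cfg.subgroups:
        return list(tracks)
    for label, share in cfg.subgroups.items():
        if share * cfg.n_patients < 2:
            raise ValueError(f"subgroup {label} has fewer than 2 patients")
    rng = np.random.default_rng([cfg.seed, 7_777])
    boosted = []
    for track in tracks:
        if (
            track.tissue is not Tissue.TUMOR
            or track.patient_id not in truth.subgroup_of_patient
        ):
            boosted.append(track)
            continue
        label = truth.subgroup_of_patient[track.patient_id]
        targets = [
            iv for iv, lab in truth.subgroup_specific.items() if lab == label
        ]
        if not targets:
            boosted.append(track)
            continue
        extra: list[Fragment] = []
        for locus in targets:
            c = int(_nb_counts(rng, np.array([cfg.base_rate * (cfg.subgroup_boost - 1)]),
                               cfg.nb_dispersion)[0])
            if c == 0:
                continue
            lo = max(0, locus.start - 100)
            hi = locus.end + 100 - READ_LENGTH
            pos = rng.integers(lo, hi, size=c)
            for p in np.sort(pos):
                strand = "+" if rng.random() < 0.5 else "-"
                extra.append(
                    Fragment(
                        GenomicInterval(locus.chrom, int(p), int(p) + READ_LENGTH, strand),
                        track.sample_id,
                    )
                )
        frags = FragmentSet.from_fragments(
            list(track.fragments) + extra, sample_id=track.sample_id
        )
        boosted.append(
            SampleTrack(
                sample_id=track.sample_id,
                patient_id=track.patient_id,
                tissue=track.tissue,
                mark=track.mark,
                peaks=list(track.peaks),
                fragments=frags,
                library_size=len(frags),
                cms=track.cms,
            )
        )
    return boosted


def write_fixture(tracks: Sequence[SampleTrack], truth: GroundTruth, out_dir) -> dict[str, str]:
    """Write the cohort as the plain-text file tree the readers consume.

    Emits per-sample peak BEDs and tagAlign fragment files, a sample sheet
    TSV (with CMS labels when present), a TSS BED6, and ground-truth TSVs.
    Returns a map of logical name -> path.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths: dict[str, str] = {}
    rows = []
    for track in tracks:
        peaks_name = f"{track.sample_id}.peaks.bed"
        frags_name = f"{track.sample_id}.tagAlign"
        write_bed(os.path.join(out_dir, peaks_name), track.peaks)
        with open(os.path.join(out_dir, frags_name), "w") as fh:
            for fr in track.fragments:
                iv = fr.interval
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tN\t1000\t{iv.strand}\n")
        rows.append(
            {
                "sample_id": track.sample_id,
                "patient_id": track.patient_id,
                "tissue": track.tissue.value,
                "mark": track.mark.value,
                "path_peaks": peaks_name,
                "path_fragments": frags_name,
                "library_size": track.library_size,
                "cms": track.cms or "",
            }
        )
    sheet = os.path.join(out_dir, "samples.tsv")
    pd.DataFrame(rows).to_csv(sheet, sep="\t", index=False)
    paths["sample_sheet"] = sheet

    tss_path = os.path.join(out_dir, "tss.bed")
    with open(tss_path, "w") as fh:
        for rec in truth.tss:
            iv = rec.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{rec.gene_id}\t0\t{rec.strand}\n")
    paths["tss"] = tss_path

    truth_path = os.path.join(out_dir, "truth_vels.tsv")
    with open(truth_path, "w") as fh:
        fh.write("chrom\tstart\tend\tdirection\tcarriers\n")
        for direction, loci in (("gain", truth.gain_loci), ("lost", truth.lost_loci)):
            for iv in loci:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{direction}\t"
                    f"{','.join(truth.carriers[iv])}\n"
                )
    paths["truth_vels"] = truth_path

    se_path = os.path.join(out_dir, "truth_ses.tsv")
    with open(se_path, "w") as fh:
        fh.write("chrom\tstart\tend\tgaining\n")
        for ci, iv in enumerate(truth.se_intervals):
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{int(ci in truth.se_gain_clusters)}\n"
            )
    paths["truth_ses"] = se_path
    return paths
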