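"""Genomic interval model, BED/tagAlign I/O and RPM signal quantification.

Coordinates are 0-based half-open (BED convention) everywhere in memory;
1-based coordinates appear only in human-facing report output.

Region-level "signal" is the mean per-base coverage of 200-bp-extended
fragments across the region, normalised per million mapped reads (RPM per
bp), so values are comparable across loci of different lengths.
"""

from __future__ import annotations

import enum
from collections.abc import Iterable, Iterator, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "Fragment",
    "FragmentSet",
    "Tissue",
    "Mark",
    "SampleTrack",
    "SignalMatrix",
    "BedParseError",
    "read_bed",
    "write_bed",
    "read_tagalign",
    "read_sample_sheet",
    "load_cohort",
    "merge_intervals",
    "compute_rpm",
    "build_signal_matrix",
]

_VALID_STRANDS = frozenset({"+", "-", "."})


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A genomic locus in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must be > start, got [{self.start}, {self.end})"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"strand must be one of +, -, . (got {self.strand!r})")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class Fragment:
    """One aligned sequencing fragment belonging to a sample."""

    interval: GenomicInterval
    sample_id: str = ""


class Tissue(str, enum.Enum):
    TUMOR = "tumor"
    NATIVE = "native"


class Mark(str, enum.Enum):
    H3K27AC = "H3K27ac"
    H3K4ME3 = "H3K4me3"


class FragmentSet:
    """Column-oriented store of fragments, chromosome-keyed for fast coverage.

    Iterating yields :class:`Fragment` objects; internally fragments live in
    numpy arrays (start, end, strand) per chromosome so that extended-fragment
    coverage over thousands of regions stays cheap.
    """

    def __init__(
        self,
        by_chrom: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]] | None = None,
        sample_id: str = "",
    ) -> None:
        # by_chrom: chrom -> (starts int64, ends int64, strands array of '+'/'-'/'.')
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = (
            dict(by_chrom) if by_chrom else {}
        )
        self.sample_id = sample_id

    @classmethod
    def from_fragments(cls, fragments: Iterable[Fragment], sample_id: str = "") -> "FragmentSet":
        buckets: dict[str, list[tuple[int, int, str]]] = {}
        sid = sample_id
        for fr in fragments:
            iv = fr.interval
            buckets.setdefault(iv.chrom, []).append((iv.start, iv.end, iv.strand))
            if not sid:
                sid = fr.sample_id
        by_chrom = {}
        for chrom, rows in buckets.items():
            arr = np.asarray(rows, dtype=object)
            starts = np.asarray([r[0] for r in rows], dtype=np.int64)
            ends = np.asarray([r[1] for r in rows], dtype=np.int64)
            strands = np.asarray([r[2] for r in rows], dtype="U1")
            by_chrom[chrom] = (starts, ends, strands)
        return cls(by_chrom, sample_id=sid)

    @classmethod
    def from_arrays(
        cls,
        chroms: Sequence[str],
        starts: np.ndarray,
        ends: np.ndarray,
        strands: np.ndarray,
        sample_id: str = "",
    ) -> "FragmentSet":
        chrom_arr = np.asarray(chroms)
        by_chrom = {}
        for chrom in np.unique(chrom_arr):
            m = chrom_arr == chrom
            by_chrom[str(chrom)] = (
                np.asarray(starts, dtype=np.int64)[m],
                np.asarray(ends, dtype=np.int64)[m],
                np.asarray(strands, dtype="U1")[m],
            )
        return cls(by_chrom, sample_id=sample_id)

    def __len__(self) -> int:
        return sum(len(s) for s, _, _ in self._by_chrom.values())

    def __iter__(self) -> Iterator[Fragment]:
        for chrom in sorted(self._by_chrom):
            starts, ends, strands = self._by_chrom[chrom]
            for s, e, st in zip(starts, ends, strands):
                yield Fragment(
                    GenomicInterval(chrom, int(s), int(e), str(st)), self.sample_id
                )

    def chroms(self) -> list[str]:
        return sorted(self._by_chrom)

    def arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray] | None:
        return self._by_chrom.get(chrom)


@dataclass
class SampleTrack:
    """One ChIP-seq sample: its peak set, fragments and library size."""

    sample_id: str
    patient_id: str
    tissue: Tissue
    mark: Mark
    peaks: list[GenomicInterval]
    fragments: FragmentSet
    library_size: int
    cms: str | None = None
    _ext_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")
        self.tissue = Tissue(self.tissue)
        self.mark = Mark(self.mark)
        self.peaks = sorted(self.peaks)

    def extended_index(self, extension: int) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome (starts, ends) of extended fragments, sorted by start.

        Each fragment is replaced by the ``extension``-bp window running 3'-ward
        from its 5' end (strand "." treated as "+"), clipped at position 0.
        With ``extension`` = 0 the original fragment interval is used.
        """
        cached = self._ext_cache.get(extension)
        if cached is not None:
            return cached
        index: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom in self.fragments.chroms():
            starts, ends, strands = self.fragments.arrays(chrom)
            if extension > 0:
                minus = strands == "-"
                ext_start = np.where(minus, ends - extension, starts)
                ext_end = np.where(minus, ends, starts + extension)
                np.clip(ext_start, 0, None, out=ext_start)
            else:
                ext_start, ext_end = starts.copy(), ends.copy()
            order = np.argsort(ext_start, kind="stable")
            index[chrom] = (ext_start[order], ext_end[order])
        self._ext_cache[extension] = index
        return index


@dataclass
class SignalMatrix:
    """Loci x samples matrix of RPM signal with tumor/native pairing metadata."""

    loci: list[GenomicInterval]
    sample_ids: list[str]
    values: np.ndarray
    pairing: dict[str, tuple[str, str]]  # patient_id -> (tumor sample, native sample)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.loci), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.loci)} loci x {len(self.sample_ids)} samples"
            )
        if np.any(self.values < 0):
            raise ValueError("RPM values must be non-negative")
        ids = set(self.sample_ids)
        for patient, (t, n) in self.pairing.items():
            if t == n or t not in ids or n not in ids:
                raise ValueError(f"invalid pairing for patient {patient}: {(t, n)}")
        self._locus_index = {
            (iv.chrom, iv.start, iv.end): i for i, iv in enumerate(self.loci)
        }
        self._sample_index = {s: j for j, s in enumerate(self.sample_ids)}

    def locus_row(self, locus: GenomicInterval) -> int:
        return self._locus_index[(locus.chrom, locus.start, locus.end)]

    def sample_col(self, sample_id: str) -> int:
        return self._sample_index[sample_id]

    def value(self, locus: GenomicInterval, sample_id: str) -> float:
        return float(self.values[self.locus_row(locus), self.sample_col(sample_id)])

    def paired_vectors(self, locus: GenomicInterval) -> tuple[np.ndarray, np.ndarray]:
        """Tumor and native RPM vectors across all paired patients at a locus."""
        row = self.values[self.locus_row(locus)]
        tumor = np.array([row[self._sample_index[t]] for t, _ in self.pairing.values()])
        native = np.array([row[self._sample_index[n]] for _, n in self.pairing.values()])
        return tumor, native

    def to_dataframe(self) -> pd.DataFrame:
        idx = [str(iv) for iv in self.loci]
        return pd.DataFrame(self.values, index=idx, columns=self.sample_ids)


class BedParseError(ValueError):
    """Raised when a BED-like line cannot be parsed."""


def _is_header(line: str) -> bool:
    return (
        not line.strip()
        or line.startswith(("#", "track", "browser"))
    )


def read_bed(path, min_columns: int = 3) -> list[GenomicInterval]:
    """Read intervals from a BED3/BED6/narrowPeak file.

    Columns beyond the sixth are ignored; track/browser/comment lines are
    skipped. Raises :class:`BedParseError` naming the offending line on
    malformed records (non-integer coordinates, end <= start, too few fields).
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if _is_header(line):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < max(min_columns, 3):
                raise BedParseError(
                    f"{path}:{lineno}: expected >= {max(min_columns, 3)} columns, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates {fields[1]!r}, {fields[2]!r}"
                ) from exc
            strand = fields[5] if len(fields) >= 6 and fields[5] in _VALID_STRANDS else "."
            try:
                out.append(GenomicInterval(fields[0], start, end, strand))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(path, intervals: Iterable[GenomicInterval], scores: Sequence | None = None) -> None:
    """Write intervals as BED (BED3, or BED6 with optional column-5 scores)."""
    intervals = list(intervals)
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            if scores is not None or iv.strand != ".":
                score = scores[i] if scores is not None else 0
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t{score}\t{iv.strand}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_tagalign(path, sample_id: str = "") -> FragmentSet:
    """Read a tagAlign (BED6 of aligned fragments) file into a FragmentSet."""
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    strands: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if _is_header(line):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >= 3 columns")
            try:
                s, e = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if e <= s:
                raise BedParseError(f"{path}:{lineno}: end <= start")
            chroms.append(fields[0])
            starts.append(s)
            ends.append(e)
            strands.append(fields[5] if len(fields) >= 6 and fields[5] in "+-" else ".")
    return FragmentSet.from_arrays(
        chroms,
        np.asarray(starts, dtype=np.int64),
        np.asarray(ends, dtype=np.int64),
        np.asarray(strands, dtype="U1"),
        sample_id=sample_id,
    )


def read_sample_sheet(path) -> pd.DataFrame:
    """Read the cohort sample sheet TSV.

    Required columns: sample_id, patient_id, tissue, mark, path_peaks,
    path_fragments; optional: library_size, cms.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "patient_id", "tissue", "mark", "path_peaks", "path_fragments"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return df


def load_cohort(sheet_path, base_dir=None) -> list[SampleTrack]:
    """Load SampleTracks for every row of a sample sheet.

    Relative peak/fragment paths resolve against ``base_dir`` (default: the
    sheet's directory). library_size defaults to the fragment count unless the
    sheet overrides it.
    """
    import os

    sheet = read_sample_sheet(sheet_path)
    base = base_dir if base_dir is not None else os.path.dirname(os.fspath(sheet_path))
    tracks = []
    for _, row in sheet.iterrows():
        peaks = read_bed(os.path.join(base, row["path_peaks"]))
        frags = read_tagalign(os.path.join(base, row["path_fragments"]), row["sample_id"])
        lib = row.get("library_size")
        lib = int(lib) if lib is not None and not pd.isna(lib) else len(frags)
        tracks.append(
            SampleTrack(
                sample_id=row["sample_id"],
                patient_id=row["patient_id"],
                tissue=Tissue(row["tissue"]),
                mark=Mark(row["mark"]),
                peaks=peaks,
                fragments=frags,
                library_size=lib,
                cms=row.get("cms") if "cms" in sheet.columns and not pd.isna(row.get("cms")) else None,
            )
        )
    return tracks


def merge_intervals(
    intervals: Iterable[GenomicInterval], gap: int = 0
) -> list[GenomicInterval]:
    """Merge intervals whose separation on the same chromosome is <= gap.

    Output is sorted by (chrom, start) and covers the gap-closed union of the
    input. gap=0 gives the plain union (touching intervals merge).
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start - merged[-1].end <= gap:
            if iv.end > merged[-1].end:
                merged[-1] = GenomicInterval(iv.chrom, merged[-1].start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def _region_coverage_sum(
    index: dict[str, tuple[np.ndarray, np.ndarray]], region: GenomicInterval,
    max_len: int,
) -> int:
    """Total base overlap between extended fragments and a region."""
    arrs = index.get(region.chrom)
    if arrs is None:
        return 0
    starts, ends = arrs
    # candidates: start < region.end and end > region.start; since fragment
    # length <= max_len, start > region.start - max_len is necessary for overlap
    lo = np.searchsorted(starts, region.start - max_len, side="right")
    hi = np.searchsorted(starts, region.end, side="left")
    if hi <= lo:
        return 0
    s = starts[lo:hi]
    e = ends[lo:hi]
    ov = np.minimum(e, region.end) - np.maximum(s, region.start)
    return int(ov[ov > 0].sum())


def compute_rpm(
    region: GenomicInterval, track: SampleTrack, extension: int = 200
) -> float:
    """Mean per-bp extended-fragment coverage of a region, in RPM per bp.

    Fragments are extended ``extension`` bp 3'-ward from their 5' start
    (clipped at 0; strand "." treated as "+"); the summed base overlap with
    the region is divided by the region length and normalised per million
    mapped reads.
    """
    if extension < 0:
        raise ValueError("extension must be >= 0")
    if len(region) == 0:
        raise ValueError("zero-length region")
    index = track.extended_index(extension)
    max_len = extension if extension > 0 else _max_fragment_len(track)
    total = _region_coverage_sum(index, region, max_len)
    return total / len(region) * 1e6 / track.library_size


def _max_fragment_len(track: SampleTrack) -> int:
    m = 1
    for chrom in track.fragments.chroms():
        starts, ends, _ = track.fragments.arrays(chrom)
        if len(starts):
            m = max(m, int((ends - starts).max()))
    return m


def build_signal_matrix(
    loci: Sequence[GenomicInterval],
    tracks: Sequence[SampleTrack],
    extension: int = 200,
) -> SignalMatrix:
    """RPM matrix over loci x tracks, with tumor/native pairing metadata.

    Raises if a patient contributes two tumor or two native samples of the
    same mark (ambiguous pairing).
    """
    if not loci:
        raise ValueError("loci must be non-empty")
    marks = {t.mark for t in tracks}
    if len(marks) > 1:
        raise ValueError(f"tracks mix marks: {sorted(m.value for m in marks)}")
    values = np.zeros((len(loci), len(tracks)))
    for j, track in enumerate(tracks):
        index = track.extended_index(extension)
        max_len = extension if extension > 0 else _max_fragment_len(track)
        scale = 1e6 / track.library_size
        for i, region in enumerate(loci):
            total = _region_coverage_sum(index, region, max_len)
            values[i, j] = total / len(region) * scale

    by_patient: dict[str, dict[Tissue, str]] = {}
    for track in tracks:
        slot = by_patient.setdefault(track.patient_id, {})
        if track.tissue in slot:
            raise ValueError(
                f"patient {track.patient_id} has two {track.tissue.value} samples"
            )
        slot[track.tissue] = track.sample_id
    pairing = {
        pid: (slot[Tissue.TUMOR], slot[Tissue.NATIVE])
        for pid, slot in by_patient.items()
        if Tissue.TUMOR in slot and Tissue.NATIVE in slot
    }
    return SignalMatrix(
        loci=list(loci),
        sample_ids=[t.sample_id for t in tracks],
        values=values,
        pairing=pairing,
    )
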