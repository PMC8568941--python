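"""Core regulatory circuitry (CRC) degree networks for SE-associated TFs.

For a transcription factor TFi, the IN degree is the number of TFs with a
binding-motif hit inside TFi's proximal super-enhancer or promoter regions;
the OUT degree is the number of TF-associated super-enhancer regions
containing a hit of TFi; total degree = IN + OUT. Candidate master
regulators are ranked by the tumor-minus-native total-degree delta.

Motif hits are normally consumed from a FIMO/HOMER-style TSV; a small
log-odds PWM scanner is included so synthetic tests need no external
scanner.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import GenomicInterval

__all__ = [
    "CRCNode",
    "MotifHit",
    "read_motif_hits",
    "compute_degrees",
    "rank_delta",
    "edge_list",
    "scan_pwm",
]

MOTIF_HIT_COLUMNS = ["tf", "chrom", "start", "end"]


@dataclass
class CRCNode:
    """One TF's degrees within a tissue group's circuitry."""

    tf_id: str
    in_degree: int
    out_degree: int
    group: str = ""

    @property
    def total_degree(self) -> int:
        return self.in_degree + self.out_degree


@dataclass(frozen=True)
class MotifHit:
    """A PWM match: 0-based offset on the given strand, with its log2-odds score."""

    offset: int
    strand: str
    score: float


def read_motif_hits(path) -> pd.DataFrame:
    """Read a motif-hit TSV with columns tf, chrom, start, end[, score, strand]."""
    df = pd.read_csv(path, sep="\t")
    missing = set(MOTIF_HIT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"motif hit table missing columns: {sorted(missing)}")
    return df


def _hits_by_tf(hits: pd.DataFrame) -> dict[str, set[tuple[str, int, int]]]:
    out: dict[str, set[tuple[str, int, int]]] = {}
    for row in hits.itertuples(index=False):
        out.setdefault(str(row.tf), set()).add(
            (str(row.chrom), int(row.start), int(row.end))
        )
    return out


def _overlaps(region: GenomicInterval, hit: tuple[str, int, int]) -> bool:
    chrom, start, end = hit
    return region.chrom == chrom and start < region.end and region.start < end


def compute_degrees(
    tf_regions: Mapping[str, Sequence[GenomicInterval]],
    se_assignments: Mapping[GenomicInterval, Sequence[str]],
    hits: pd.DataFrame,
    group: str = "",
) -> list[CRCNode]:
    """IN/OUT/total degrees for every TF in the node list.

    ``tf_regions`` maps each TF to its proximal SE and promoter regions;
    ``se_assignments`` maps each TF-associated SE region to its TF list.
    Hits naming TFs outside ``tf_regions`` are ignored with a warning;
    duplicate hits have no effect (set semantics). Self-loops count toward
    both IN and OUT.
    """
    for tf in {tf for tfs in se_assignments.values() for tf in tfs}:
        if tf not in tf_regions:
            raise ValueError(f"SE-assigned TF {tf!r} missing from tf_regions")
    hit_sets = _hits_by_tf(hits)
    unknown = set(hit_sets) - set(tf_regions)
    if unknown:
        warnings.warn(
            f"ignoring motif hits for unknown TFs: {sorted(unknown)}", stacklevel=2
        )
        for tf in unknown:
            del hit_sets[tf]

    nodes = []
    se_regions = list(se_assignments)
    for tfi in sorted(tf_regions):
        regions_i = tf_regions[tfi]
        in_deg = sum(
            1
            for tfj, hset in hit_sets.items()
            if any(_overlaps(r, h) for r in regions_i for h in hset)
        )
        my_hits = hit_sets.get(tfi, set())
        out_deg = sum(
            1 for se in se_regions if any(_overlaps(se, h) for h in my_hits)
        )
        nodes.append(CRCNode(tf_id=tfi, in_degree=in_deg, out_degree=out_deg, group=group))
    return nodes


def rank_delta(
    nodes_tumor: Sequence[CRCNode], nodes_native: Sequence[CRCNode]
) -> pd.DataFrame:
    """Total-degree delta (tumor - native) per TF, sorted descending.

    TFs present in only one group contribute degree 0 in the other; equal
    deltas are ordered by tf_id.
    """
    tot_t = {n.tf_id: n.total_degree for n in nodes_tumor}
    tot_n = {n.tf_id: n.total_degree for n in nodes_native}
    rows = [
        {
            "tf_id": tf,
            "total_tumor": tot_t.get(tf, 0),
            "total_native": tot_n.get(tf, 0),
            "delta": tot_t.get(tf, 0) - tot_n.get(tf, 0),
        }
        for tf in sorted(set(tot_t) | set(tot_n))
    ]
    df = pd.DataFrame(rows, columns=["tf_id", "total_tumor", "total_native", "delta"])
    return df.sort_values(["delta", "tf_id"], ascending=[False, True], kind="stable").reset_index(
        drop=True
    )


def edge_list(
    tf_regions: Mapping[str, Sequence[GenomicInterval]],
    hits: pd.DataFrame,
) -> pd.DataFrame:
    """Directed TF->TF edges: source has a motif hit in a region of target."""
    hit_sets = _hits_by_tf(hits)
    rows = []
    for target, regions in tf_regions.items():
        for source, hset in hit_sets.items():
            if source not in tf_regions:
                continue
            if any(_overlaps(r, h) for r in regions for h in hset):
                rows.append({"tf_source": source, "tf_target": target})
    return pd.DataFrame(rows, columns=["tf_source", "tf_target"]).sort_values(
        ["tf_source", "tf_target"]
    ).reset_index(drop=True)


_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def scan_pwm(
    sequence: str,
    pwm: np.ndarray,
    threshold_fraction: float = 0.8,
) -> list[MotifHit]:
    """Scan both strands of a sequence with a position probability matrix.

    ``pwm`` has shape (width, 4) with columns A, C, G, T, each row summing
    to 1. The score at an offset is the summed log2-odds against a uniform
    background; N positions contribute 0. Offsets scoring at least
    ``threshold_fraction`` x the maximum achievable score (on either strand)
    are reported; reverse-strand offsets refer to the forward sequence.
    """
    pwm = np.asarray(pwm, dtype=float)
    if pwm.ndim != 2 or pwm.shape[1] != 4:
        raise ValueError("pwm must have shape (width, 4)")
    if not np.allclose(pwm.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("pwm rows must each sum to 1")
    seq = sequence.upper()
    if any(b not in "ACGTN" for b in seq):
        raise ValueError("sequence must be over A, C, G, T, N")
    width = pwm.shape[0]
    if len(seq) < width:
        return []
    with np.errstate(divide="ignore"):
        logodds = np.log2(pwm / 0.25)  # -inf where probability is 0
    max_score = float(np.max(logodds, axis=1).sum())
    threshold = threshold_fraction * max_score

    def score_at(s: str, offset: int) -> float:
        total = 0.0
        for k in range(width):
            base = s[offset + k]
            if base == "N":
                continue
            total += logodds[k, _BASE_INDEX[base]]
        return total

    rc = seq.translate(_COMPLEMENT)[::-1]
    hits: list[MotifHit] = []
    for offset in range(len(seq) - width + 1):
        fwd = score_at(seq, offset)
        if fwd >= threshold:
            hits.append(MotifHit(offset, "+", fwd))
        rev_offset = len(seq) - width - offset
        rev = score_at(rc, rev_offset)
        if rev >= threshold:
            hits.append(MotifHit(offset, "-", rev))
    return hits
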