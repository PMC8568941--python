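import numpy as np
import pytest

from velpipe import (
    Fragment,
    FragmentSet,
    GenomicInterval,
    Mark,
    SampleTrack,
    SimConfig,
    Tissue,
    TSSRecord,
    simulate_cohort,
)


def iv(chrom, start, end, strand=".") -> GenomicInterval:
    return GenomicInterval(chrom, start, end, strand)


def make_track(
    fragments,
    library_size=1_000_000,
    sample_id="s1",
    patient_id="p1",
    tissue=Tissue.TUMOR,
    mark=Mark.H3K27AC,
    peaks=(),
):
    """Build a SampleTrack from (chrom, start, end[, strand]) fragment tuples."""
    frs = [
        Fragment(GenomicInterval(*f) if len(f) > 3 else GenomicInterval(*f, "+"))
        for f in fragments
    ]
    return SampleTrack(
        sample_id=sample_id,
        patient_id=patient_id,
        tissue=tissue,
        mark=mark,
        peaks=list(peaks),
        fragments=FragmentSet.from_fragments(frs, sample_id=sample_id),
        library_size=library_size,
    )


def tss(gene, chrom, pos, strand="+") -> TSSRecord:
    return TSSRecord(gene, GenomicInterval(chrom, pos, pos + 1), strand)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully structured cohort: 12 pairs, 400 enhancers."""
    cfg = SimConfig(
        seed=11,
        n_patients=12,
        n_enhancers=400,
        n_tss=100,
        planted_gain=40,
        planted_lost=15,
        n_planted_ses=4,
        n_se_gain=2,
        genome=[("chr1", 15_000_000)],
        library_size=60_000,
    )
    tracks, truth = simulate_cohort(cfg)
    return cfg, tracks, truth
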