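"""Exon-event counting, PSI computation and TPM normalization.

PSI for a bin is the normalized ratio of inclusion evidence to total
evidence: nIR = (inclusion_body + inclusion_junction) / NI with
NI = exon_length + read_length - 1 positions that can produce inclusion
evidence, nER = exclusion_junction / NE with NE = read_length - 1 positions
that can produce an exclusion junction, and psi = nIR / (nIR + nER).
A raw-ratio mode (NI = NE = 1) is available via ``normalize=False``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from splicebins.intervals import CountingBin, GenomicInterval

logger = logging.getLogger(__name__)

DEFAULT_MIN_TOTAL = 10


@dataclass
class SplicedRead:
    """A (possibly spliced) read as ordered aligned blocks; gaps are junctions."""

    read_id: str
    chrom: str
    blocks: list[GenomicInterval]

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError(f"read {self.read_id} has no blocks")
        self.blocks = sorted(self.blocks, key=lambda b: b.start)
        for a, b in zip(self.blocks, self.blocks[1:]):
            if a.end > b.start:
                raise ValueError(f"read {self.read_id} has overlapping blocks")

    @property
    def junctions(self) -> list[tuple[int, int]]:
        """Gap intervals (donor, acceptor) between consecutive blocks."""
        return [(a.end, b.start) for a, b in zip(self.blocks, self.blocks[1:])]


@dataclass
class ExonEventRecord:
    """Inclusion/exclusion evidence for one counting bin in one sample."""

    bin_id: str
    sample_id: str
    inclusion_body: int
    inclusion_junction: int
    exclusion_junction: int
    read_length: int
    exon_length: int
    ambiguous: int = 0
    unassigned: int = 0

    def __post_init__(self) -> None:
        for name in ("inclusion_body", "inclusion_junction", "exclusion_junction"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.read_length <= 0 or self.exon_length <= 0:
            raise ValueError("read_length and exon_length must be > 0")


@dataclass
class PsiValue:
    """PSI for one bin in one sample; ``psi`` is None when evidence is too thin."""

    bin_id: str
    sample_id: str
    psi: float | None
    total_events: int


def count_exon_events(
    reads: list[SplicedRead],
    bin: CountingBin,
    upstream_exon: GenomicInterval,
    downstream_exon: GenomicInterval,
    read_length: int,
    min_overlap: int = 1,
) -> ExonEventRecord:
    """Classify reads as inclusion-body, inclusion-junction or exclusion evidence.

    Junction matching requires exact boundary coincidence.  Each read counts in
    at most one category; reads matching both inclusion and exclusion patterns
    are ambiguous and excluded; off-chrom or non-overlapping reads are
    unassigned.
    """
    if upstream_exon.end > bin.interval.start or bin.interval.end > downstream_exon.start:
        raise ValueError("flanking exons must bracket the bin")

    b = bin.interval
    incl_body = incl_junc = excl_junc = ambiguous = unassigned = 0

    for read in reads:
        if read.chrom != b.chrom:
            logger.warning("read %s on %s, expected %s; skipped", read.read_id, read.chrom, b.chrom)
            unassigned += 1
            continue

        junctions = read.junctions
        skips_bin = any(donor <= b.start and b.end <= acceptor for donor, acceptor in junctions)
        is_exclusion = any(
            donor == upstream_exon.end and acceptor == downstream_exon.start
            for donor, acceptor in junctions
        )

        is_incl_junc = False
        for (donor, acceptor), left, right in zip(junctions, read.blocks, read.blocks[1:]):
            if acceptor == b.start and left.overlaps(upstream_exon):
                is_incl_junc = True
            if donor == b.end and right.overlaps(downstream_exon):
                is_incl_junc = True

        overlap = sum(
            max(0, min(blk.end, b.end) - max(blk.start, b.start)) for blk in read.blocks
        )
        is_incl_body = overlap >= min_overlap and not skips_bin

        is_inclusion = is_incl_junc or is_incl_body
        if is_exclusion and is_inclusion:
            logger.warning("read %s matches inclusion and exclusion; ambiguous", read.read_id)
            ambiguous += 1
        elif is_exclusion:
            excl_junc += 1
        elif is_incl_junc:
            incl_junc += 1
        elif is_incl_body:
            incl_body += 1
        else:
            unassigned += 1

    return ExonEventRecord(
        bin_id=bin.bin_id,
        sample_id="",
        inclusion_body=incl_body,
        inclusion_junction=incl_junc,
        exclusion_junction=excl_junc,
        read_length=read_length,
        exon_length=len(b),
        ambiguous=ambiguous,
        unassigned=unassigned,
    )


def compute_psi(
    rec: ExonEventRecord,
    min_total: int = DEFAULT_MIN_TOTAL,
    normalize: bool = True,
) -> PsiValue:
    """PSI from an event record; missing when total evidence < ``min_total``."""
    if rec.read_length < 2:
        raise ValueError("read_length must be >= 2 (exclusion normalization undefined)")
    total = rec.inclusion_body + rec.inclusion_junction + rec.exclusion_junction
    if normalize:
        ni = rec.exon_length + rec.read_length - 1
        ne = rec.read_length - 1
    else:
        ni = ne = 1
    nir = (rec.inclusion_body + rec.inclusion_junction) / ni
    ner = rec.exclusion_junction / ne
    if total < min_total or (nir == 0 and ner == 0):
        psi = None
    else:
        psi = nir / (nir + ner)
    return PsiValue(bin_id=rec.bin_id, sample_id=rec.sample_id, psi=psi, total_events=total)


def compute_tpm(
    counts: pd.DataFrame,
    lengths: pd.Series,
    pseudocount_for_log: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalize a genes x samples count matrix to TPM and log2(TPM + pc).

    TPM_gs = 1e6 * (c_gs / L_g) / sum_g'(c_g's / L_g'); every column sums to
    1e6.  Raises if a sample has all-zero counts or a gene lacks a length.
    """
    missing = counts.index.difference(lengths.index)
    if len(missing):
        raise ValueError(f"no length for genes: {sorted(missing)[:5]}")
    lengths = lengths.loc[counts.index].astype(float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be > 0")
    if (counts.values < 0).any():
        raise ValueError("counts must be >= 0")
    zero_samples = counts.columns[(counts.sum(axis=0) == 0)]
    if len(zero_samples):
        raise ValueError(f"sample(s) with all-zero counts: {list(zero_samples)}")
    rate = counts.div(lengths, axis=0)
    tpm = rate.div(rate.sum(axis=0), axis=1) * 1e6
    log2tpm = np.log2(tpm + pseudocount_for_log)
    return tpm, log2tpm


def psi_from_band_intensities(lf_intensity: float, sf_intensity: float) -> PsiValue:
    """PSI from gel-band intensities of the long (inclusion) vs short isoform."""
    if lf_intensity < 0 or sf_intensity < 0:
        raise ValueError("intensities must be >= 0")
    total = lf_intensity + sf_intensity
    if total == 0:
        logger.warning("both band intensities zero; PSI missing")
        return PsiValue(bin_id="", sample_id="", psi=None, total_events=0)
    return PsiValue(bin_id="", sample_id="", psi=lf_intensity / total, total_events=0)


def events_to_psi_matrix(
    events: pd.DataFrame,
    exon_lengths: pd.Series,
    read_length: int,
    min_total: int = DEFAULT_MIN_TOTAL,
    normalize: bool = True,
) -> pd.DataFrame:
    """PSI matrix (bins x samples) from an event-count table.

    ``events`` columns: bin_id, sample_id, incl_body, incl_junc, excl_junc.
    ``exon_lengths`` maps bin_id -> exon length in nt.
    """
    rows = {}
    for t in events.itertuples():
        rec = ExonEventRecord(
            bin_id=t.bin_id,
            sample_id=t.sample_id,
            inclusion_body=int(t.incl_body),
            inclusion_junction=int(t.incl_junc),
            exclusion_junction=int(t.excl_junc),
            read_length=read_length,
            exon_length=int(exon_lengths.loc[t.bin_id]),
        )
        pv = compute_psi(rec, min_total=min_total, normalize=normalize)
        rows[(t.bin_id, t.sample_id)] = np.nan if pv.psi is None else pv.psi
    ser = pd.Series(rows)
    mat = ser.unstack()
    mat.index.name = "bin_id"
    mat.columns.name = "sample_id"
    return mat


def read_spliced_reads_tsv(path) -> list[SplicedRead]:
    """Read a TSV of spliced reads: read_id, chrom, strand, comma-separated
    ``start-end`` block pairs (0-based half-open)."""
    reads = []
    df = pd.read_csv(path, sep="\t", dtype=str)
    for t in df.itertuples():
        blocks = []
        for pair in t.blocks.split(","):
            s, e = pair.split("-")
            blocks.append(GenomicInterval(t.chrom, int(s), int(e), t.strand))
        reads.append(SplicedRead(read_id=t.read_id, chrom=t.chrom, blocks=blocks))
    return reads
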