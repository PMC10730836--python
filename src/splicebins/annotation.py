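"""GTF parsing and flattening of overlapping exons into counting bins."""

from __future__ import annotations

import logging
import re
from collections import defaultdict
from pathlib import Path

import pandas as pd

from splicebins.intervals import CountingBin, GeneModel, GenomicInterval, TranscriptModel

logger = logging.getLogger(__name__)

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


class GtfParseError(ValueError):
    """Raised on a malformed GTF line; the message names the line number."""


def _parse_attributes(field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(field))


def parse_gtf(path: str | Path) -> list[GeneModel]:
    """Parse exon features of a GTF file into gene models.

    GTF coordinates (1-based inclusive) are converted to 0-based half-open.
    Non-exon features and comment lines are ignored.  Raises
    :class:`GtfParseError` on malformed lines or exon features lacking
    ``gene_id``/``transcript_id``, and ``ValueError`` if a transcript spans
    multiple chroms or strands.
    """
    path = Path(path)
    exons_by_transcript: dict[tuple[str, str], list[GenomicInterval]] = defaultdict(list)
    gene_order: list[str] = []
    seen_genes: set[str] = set()

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs_s = fields
            if feature != "exon":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise GtfParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if strand not in ("+", "-"):
                raise GtfParseError(f"{path}:{lineno}: invalid strand {strand!r}")
            attrs = _parse_attributes(attrs_s)
            if "gene_id" not in attrs:
                raise GtfParseError(f"{path}:{lineno}: exon feature lacks gene_id")
            if "transcript_id" not in attrs:
                raise GtfParseError(f"{path}:{lineno}: exon feature lacks transcript_id")
            gene_id, transcript_id = attrs["gene_id"], attrs["transcript_id"]
            interval = GenomicInterval(chrom, start1 - 1, end1, strand)
            exons_by_transcript[(gene_id, transcript_id)].append(interval)
            if gene_id not in seen_genes:
                seen_genes.add(gene_id)
                gene_order.append(gene_id)

    transcripts_by_gene: dict[str, list[TranscriptModel]] = defaultdict(list)
    for (gene_id, transcript_id), exons in exons_by_transcript.items():
        transcripts_by_gene[gene_id].append(
            TranscriptModel(transcript_id=transcript_id, gene_id=gene_id, exons=exons)
        )

    genes = []
    for gene_id in gene_order:
        transcripts = sorted(transcripts_by_gene[gene_id], key=lambda t: t.transcript_id)
        chrom, strand = transcripts[0].chrom, transcripts[0].strand
        genes.append(
            GeneModel(gene_id=gene_id, chrom=chrom, strand=strand, transcripts=transcripts)
        )
    return genes


def flatten_gene_model(gene: GeneModel) -> list[CountingBin]:
    """Flatten a gene's overlapping exons into disjoint counting bins.

    Bin boundaries occur only at exon starts/ends of some transcript; each bin
    carries the exact set of transcripts whose exons cover it; adjacent bins
    with identical support are merged, giving the canonical minimal bin set.
    Bins are numbered ``gene_id:NNN`` in genomic order.
    """
    boundaries: set[int] = set()
    for t in gene.transcripts:
        for e in t.exons:
            boundaries.add(e.start)
            boundaries.add(e.end)
    cuts = sorted(boundaries)

    # support for each atomic segment between consecutive boundaries
    segments: list[tuple[int, int, frozenset[str]]] = []
    for lo, hi in zip(cuts, cuts[1:]):
        support = frozenset(
            t.transcript_id
            for t in gene.transcripts
            if any(e.start <= lo and hi <= e.end for e in t.exons)
        )
        if support:
            segments.append((lo, hi, support))

    # merge contiguous runs of identical support
    merged: list[tuple[int, int, frozenset[str]]] = []
    for lo, hi, support in segments:
        if merged and merged[-1][1] == lo and merged[-1][2] == support:
            merged[-1] = (merged[-1][0], hi, support)
        else:
            merged.append((lo, hi, support))

    return [
        CountingBin(
            gene_id=gene.gene_id,
            bin_id=f"{gene.gene_id}:{i:03d}",
            interval=GenomicInterval(gene.chrom, lo, hi, gene.strand),
            supporting_transcripts=support,
        )
        for i, (lo, hi, support) in enumerate(merged, start=1)
    ]


def flatten_genes(genes: list[GeneModel]) -> list[CountingBin]:
    """Flatten every gene independently; warn on same-strand gene overlap."""
    spans: dict[tuple[str, str], list[tuple[int, int, str]]] = defaultdict(list)
    bins: list[CountingBin] = []
    for gene in genes:
        gbins = flatten_gene_model(gene)
        if gbins:
            lo = min(b.interval.start for b in gbins)
            hi = max(b.interval.end for b in gbins)
            for olo, ohi, ogene in spans[(gene.chrom, gene.strand)]:
                if lo < ohi and olo < hi:
                    logger.warning(
                        "genes %s and %s overlap on %s%s; flattened independently",
                        gene.gene_id, ogene, gene.chrom, gene.strand,
                    )
            spans[(gene.chrom, gene.strand)].append((lo, hi, gene.gene_id))
        bins.extend(gbins)
    return bins


def write_flattened_gtf(bins: list[CountingBin], path: str | Path) -> None:
    """Write bins as GTF ``exonic_part`` features (1-based inclusive)."""
    with open(path, "w") as fh:
        for b in bins:
            num = b.bin_id.rsplit(":", 1)[1]
            attrs = (
                f'gene_id "{b.gene_id}"; exonic_part_number "{num}"; '
                f'transcripts "{"+".join(sorted(b.supporting_transcripts))}";'
            )
            fh.write(
                "\t".join(
                    [
                        b.interval.chrom,
                        "splicebins",
                        "exonic_part",
                        str(b.interval.start + 1),
                        str(b.interval.end),
                        ".",
                        b.interval.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def parse_flattened_gtf(path: str | Path) -> list[CountingBin]:
    """Read back a flattened annotation written by :func:`write_flattened_gtf`."""
    bins: list[CountingBin] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9 or fields[2] != "exonic_part":
                raise GtfParseError(f"{path}:{lineno}: not an exonic_part record")
            attrs = _parse_attributes(fields[8])
            bins.append(
                CountingBin(
                    gene_id=attrs["gene_id"],
                    bin_id=f'{attrs["gene_id"]}:{attrs["exonic_part_number"]}',
                    interval=GenomicInterval(
                        fields[0], int(fields[3]) - 1, int(fields[4]), fields[6]
                    ),
                    supporting_transcripts=frozenset(attrs["transcripts"].split("+")),
                )
            )
    return bins


def bins_to_table(bins: list[CountingBin]) -> pd.DataFrame:
    """Tabulate bins as a TSV-ready frame (0-based half-open coordinates)."""
    return pd.DataFrame(
        {
            "bin_id": [b.bin_id for b in bins],
            "gene_id": [b.gene_id for b in bins],
            "chrom": [b.interval.chrom for b in bins],
            "start0": [b.interval.start for b in bins],
            "end0": [b.interval.end for b in bins],
            "strand": [b.interval.strand for b in bins],
            "transcripts": ["+".join(sorted(b.supporting_transcripts)) for b in bins],
        }
    )


def table_to_bins(df: pd.DataFrame) -> list[CountingBin]:
    return [
        CountingBin(
            gene_id=row.gene_id,
            bin_id=row.bin_id,
            interval=GenomicInterval(row.chrom, int(row.start0), int(row.end0), row.strand),
            supporting_transcripts=frozenset(row.transcripts.split("+")),
        )
        for row in df.itertuples()
    ]
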