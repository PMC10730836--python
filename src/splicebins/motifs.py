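"""Flanking-sequence extraction and position-dependent motif target calling.

The RBFOX recognition element (UGCAUG; TGCATG on the DNA sense strand) is
scanned in the intronic windows flanking an alternative exon, in transcript
orientation.  Downstream placement means the regulator promotes inclusion, so
its depletion decreases PSI; upstream placement means it promotes skipping,
so depletion increases PSI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from splicebins.intervals import CountingBin, GenomicInterval

DEFAULT_MOTIF = "TGCATG"
DEFAULT_WINDOW = 500

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifSpec:
    """A short nucleotide pattern; U and T are interchangeable."""

    dna_sense_pattern: str = DEFAULT_MOTIF

    def __post_init__(self) -> None:
        pat = self.dna_sense_pattern.upper().replace("U", "T")
        if len(pat) < 4:
            raise ValueError("motif must be at least 4 nt")
        if set(pat) - set("ACGT"):
            raise ValueError(f"invalid motif characters in {self.dna_sense_pattern!r}")
        object.__setattr__(self, "dna_sense_pattern", pat)

    def __len__(self) -> int:
        return len(self.dna_sense_pattern)


@dataclass
class FlankingSequence:
    """Intronic sequence flanking one bin, in transcript orientation."""

    bin_id: str
    upstream_seq: str
    downstream_seq: str
    window: int = DEFAULT_WINDOW

    def __post_init__(self) -> None:
        for name in ("upstream_seq", "downstream_seq"):
            seq = getattr(self, name).upper()
            if set(seq) - set("ACGTN"):
                raise ValueError(f"{name} contains non-ACGTN characters")
            if len(seq) > self.window:
                raise ValueError(f"{name} longer than window {self.window}")
            setattr(self, name, seq)


@dataclass
class TargetCall:
    """Motif-placement classification of one exon with predicted depletion effect."""

    bin_id: str
    upstream_hits: list[int] = field(default_factory=list)
    downstream_hits: list[int] = field(default_factory=list)
    is_direct_target: bool = False
    predicted_depletion_effect: str = "none"  # decrease_psi | increase_psi | ambiguous | none


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """Slice a chromosome from a dict of strings or a pyfaidx-like mapping."""
    if chrom not in genome:
        raise KeyError(f"chromosome {chrom!r} absent from genome")
    seq = genome[chrom]
    start = max(0, start)
    end = min(end, len(seq))
    if start >= end:
        return ""
    return str(seq[start:end]).upper()


def extract_flanks(
    genome,
    bin: CountingBin,
    neighbor_bins: list[GenomicInterval] | None = None,
    window: int = DEFAULT_WINDOW,
) -> FlankingSequence:
    """Extract up to ``window`` nt of intronic sequence on each side of a bin.

    Windows truncate at chromosome ends and at the nearest neighboring exonic
    interval.  For minus-strand bins the genomic left/right windows are swapped
    and reverse-complemented so both flanks read in transcript orientation.
    """
    iv = bin.interval
    left_lo, right_hi = iv.start - window, iv.end + window
    for nb in neighbor_bins or []:
        if nb.chrom != iv.chrom:
            continue
        if nb.end <= iv.start:
            left_lo = max(left_lo, nb.end)
        if nb.start >= iv.end:
            right_hi = min(right_hi, nb.start)
    left = _fetch(genome, iv.chrom, left_lo, iv.start)
    right = _fetch(genome, iv.chrom, iv.end, right_hi)
    if iv.strand == "+":
        up, down = left, right
    else:
        up, down = reverse_complement(right), reverse_complement(left)
    return FlankingSequence(bin_id=bin.bin_id, upstream_seq=up, downstream_seq=down, window=window)


def scan_motif(seq: str, motif: MotifSpec) -> list[int]:
    """0-based start positions of all (possibly overlapping) motif matches.

    Case-insensitive; U maps to T; N never matches.
    """
    pattern = motif.dna_sense_pattern
    if not pattern:
        raise ValueError("empty motif")
    seq = seq.upper().replace("U", "T")
    hits = []
    start = seq.find(pattern)
    while start != -1:
        hits.append(start)
        start = seq.find(pattern, start + 1)
    return hits


def classify_target(flanks: FlankingSequence, motif: MotifSpec | None = None) -> TargetCall:
    """Classify an exon's predicted PSI response to regulator depletion.

    Downstream-only hits -> ``decrease_psi`` (the regulator promotes inclusion;
    its loss skips the exon); upstream-only -> ``increase_psi``; hits on both
    sides -> the side with strictly more hits wins, ties are ``ambiguous``;
    no hits -> ``none``.
    """
    motif = motif or MotifSpec()
    up = scan_motif(flanks.upstream_seq, motif)
    down = scan_motif(flanks.downstream_seq, motif)
    # report upstream positions as distance (nt) before the exon start
    up_positions = [len(flanks.upstream_seq) - p for p in up]
    if not up and not down:
        effect = "none"
    elif down and not up:
        effect = "decrease_psi"
    elif up and not down:
        effect = "increase_psi"
    elif len(down) > len(up):
        effect = "decrease_psi"
    elif len(up) > len(down):
        effect = "increase_psi"
    else:
        effect = "ambiguous"
    return TargetCall(
        bin_id=flanks.bin_id,
        upstream_hits=up_positions,
        downstream_hits=down,
        is_direct_target=bool(up or down),
        predicted_depletion_effect=effect,
    )
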