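"""Synthetic dataset generator with machine-readable ground truth.

Each simulated gene is a cassette-exon locus: two constitutive flanking exons
and one alternative middle exon, encoded as two transcripts (inclusion and
skipping isoforms).  Target exons carry a planted motif on one intronic side;
all spurious motif occurrences elsewhere are destroyed so motif scans are
exact by construction.  Event counts are binomial draws at a normalized
inclusion probability chosen so the PSI estimator is unbiased for the true
value.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from splicebins.annotation import bins_to_table, flatten_gene_model, write_flattened_gtf
from splicebins.intervals import GeneModel, GenomicInterval, TranscriptModel
from splicebins.motifs import DEFAULT_MOTIF, reverse_complement

_SPACER = 300


@dataclass
class SimulationConfig:
    seed: int = 0
    n_genes: int = 60
    n_target_exons: int = 40
    exon_len_range: tuple[int, int] = (80, 200)
    intron_len_range: tuple[int, int] = (700, 900)
    flank_window: int = 500
    groups: tuple[str, str] = ("control", "depleted")
    n_samples_per_group: int = 10
    psi_beta: tuple[float, float] = (2.0, 2.0)
    delta_psi: float = 0.2
    events_per_exon: float = 100.0
    read_length: int = 50
    rho: float = 0.5
    coupling_logit_sd: float = 0.35
    n_signature_genes: int = 28
    subtype_effect_size: float = 2.0
    motif: str = DEFAULT_MOTIF
    motif_offset: int | None = None  # fixed offset into the flank; None = random

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_samples_per_group <= 0:
            raise ValueError("n_genes and n_samples_per_group must be > 0")
        if self.n_target_exons > self.n_genes:
            raise ValueError("n_target_exons cannot exceed n_genes")
        if not (0 <= self.delta_psi < 0.49):
            raise ValueError("delta_psi must keep PSI within [0.01, 0.99]")
        if not (-1 < self.rho < 1):
            raise ValueError("rho must be in (-1, 1)")
        if self.events_per_exon <= 0:
            raise ValueError("events_per_exon must be > 0")
        if self.motif_offset is not None and self.motif_offset + len(self.motif) > self.flank_window:
            raise ValueError("motif offset places the motif outside the flank window")
        if self.n_signature_genes % 2:
            raise ValueError("n_signature_genes must be even")


@dataclass
class GeneLayout:
    gene_id: str
    strand: str
    exons: list[tuple[int, int]]  # three genomic intervals, ascending
    is_target: bool
    side: str | None  # upstream | downstream, transcript orientation
    motif_genome_pos: int | None  # genomic start of the planted motif
    motif_offset: int | None  # nt from the exon boundary, transcript orientation

    @property
    def cassette(self) -> tuple[int, int]:
        return self.exons[1]


@dataclass
class GroundTruth:
    """Everything the simulator knows: the answer key for the pipeline."""

    samples: list[str]
    groups: dict[str, str]  # sample -> group
    true_psi: pd.DataFrame  # bins x samples
    targets: dict[str, dict]  # bin_id -> {side, expected_effect}
    regulator_log_expr: pd.Series  # per sample, log2 scale
    subtype_labels: dict[str, str]  # sample -> subtypeA/subtypeB
    motif_positions: dict[str, dict]  # bin_id -> {side, genome_pos, offset}
    exon_lengths: dict[str, int]  # bin_id -> cassette exon length

    def to_dict(self) -> dict:
        return {
            "samples": self.samples,
            "groups": self.groups,
            "true_psi": {b: self.true_psi.loc[b].to_dict() for b in self.true_psi.index},
            "targets": self.targets,
            "regulator_log_expr": self.regulator_log_expr.to_dict(),
            "subtype_labels": self.subtype_labels,
            "motif_positions": self.motif_positions,
            "exon_lengths": self.exon_lengths,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        psi = pd.DataFrame(d["true_psi"]).T.loc[:, d["samples"]]
        psi.index.name = "bin_id"
        return cls(
            samples=list(d["samples"]),
            groups=dict(d["groups"]),
            true_psi=psi,
            targets={k: dict(v) for k, v in d["targets"].items()},
            regulator_log_expr=pd.Series(d["regulator_log_expr"]).loc[d["samples"]],
            subtype_labels=dict(d["subtype_labels"]),
            motif_positions={k: dict(v) for k, v in d["motif_positions"].items()},
            exon_lengths={k: int(v) for k, v in d["exon_lengths"].items()},
        )

    def equals(self, other: "GroundTruth") -> bool:
        return (
            self.samples == other.samples
            and self.groups == other.groups
            and np.allclose(self.true_psi.values, other.true_psi.loc[self.true_psi.index, self.samples].values)
            and self.targets == other.targets
            and np.allclose(self.regulator_log_expr.values, other.regulator_log_expr.loc[self.samples].values)
            and self.subtype_labels == other.subtype_labels
            and self.motif_positions == other.motif_positions
            and self.exon_lengths == other.exon_lengths
        )


# ---------------------------------------------------------------------------
# deterministic layout shared by the genome and truth generators

def _plan(config: SimulationConfig) -> list[GeneLayout]:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    layouts: list[GeneLayout] = []
    pos = _SPACER
    target_flags = np.zeros(config.n_genes, dtype=bool)
    target_flags[: config.n_target_exons] = True
    rng.shuffle(target_flags)
    mlen = len(config.motif)
    for i in range(config.n_genes):
        gene_id = f"G{i + 1:03d}"
        strand = "+" if i % 2 == 0 else "-"
        e_lo, e_hi = config.exon_len_range
        i_lo, i_hi = config.intron_len_range
        lens = rng.integers(e_lo, e_hi + 1, size=3)
        introns = rng.integers(i_lo, i_hi + 1, size=2)
        exons = []
        p = pos
        for j in range(3):
            exons.append((p, p + int(lens[j])))
            p += int(lens[j])
            if j < 2:
                p += int(introns[j])
        pos = p + _SPACER

        is_target = bool(target_flags[i])
        side = motif_pos = offset = None
        if is_target:
            side = "downstream" if rng.random() < 0.5 else "upstream"
            cstart, cend = exons[1]
            # transcript-orientation side -> genomic side depends on strand
            genomic_right = (side == "downstream") == (strand == "+")
            intron_len = int(introns[1] if genomic_right else introns[0])
            if config.motif_offset is not None:
                offset = int(config.motif_offset)
            else:
                # keep the motif >= window away from the adjacent constitutive
                # exon so it is visible only in the cassette exon's own flank
                hi = min(config.flank_window, intron_len - config.flank_window) - mlen
                if hi <= 10:
                    raise ValueError(
                        "introns too short to plant a leak-free motif; "
                        "increase intron_len_range or reduce flank_window"
                    )
                offset = int(rng.integers(10, hi))
            if genomic_right:
                motif_pos = cend + offset
            else:
                motif_pos = cstart - offset - mlen
        layouts.append(
            GeneLayout(gene_id, strand, exons, is_target, side, motif_pos, offset)
        )
    return layouts


def _layout_to_gene_model(lay: GeneLayout, chrom: str = "chr1") -> GeneModel:
    ivs = [GenomicInterval(chrom, s, e, lay.strand) for s, e in lay.exons]
    t_inc = TranscriptModel(f"{lay.gene_id}.inc", lay.gene_id, list(ivs))
    t_skip = TranscriptModel(f"{lay.gene_id}.skip", lay.gene_id, [ivs[0], ivs[2]])
    return GeneModel(lay.gene_id, chrom, lay.strand, [t_inc, t_skip])


def simulate_genome_with_motifs(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[GeneModel], dict[str, dict]]:
    """Random genome with cassette-exon genes and planted, registered motifs.

    Returns (genome, gene models, registry).  The registry maps cassette bin
    ids to the planted side, genomic position and flank offset.  Every
    occurrence of the motif (either strand) not in the registry is destroyed
    by a single-base substitution, so scans of non-target flanks are clean.
    """
    layouts = _plan(config)
    total_len = max(e for lay in layouts for _, e in lay.exons) + _SPACER + config.flank_window
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 102]))
    seq = rng.choice(list("ACGT"), size=total_len)

    motif = config.motif
    planted_spans: list[tuple[int, int]] = []
    registry: dict[str, dict] = {}
    for lay in layouts:
        if not lay.is_target:
            continue
        pattern = motif if lay.strand == "+" else reverse_complement(motif)
        p = lay.motif_genome_pos
        seq[p : p + len(motif)] = list(pattern)
        planted_spans.append((p, p + len(motif)))
        registry[f"{lay.gene_id}:002"] = {
            "side": lay.side,
            "genome_pos": int(p),
            "offset": int(lay.motif_offset),
        }

    genome_str = _destroy_spurious(seq, motif, planted_spans)
    genome = {"chr1": genome_str}
    genes = [_layout_to_gene_model(lay) for lay in layouts]
    return genome, genes, registry


def _destroy_spurious(seq: np.ndarray, motif: str, planted_spans: list[tuple[int, int]]) -> str:
    """Mutate away every non-registered occurrence of motif/revcomp(motif)."""
    patterns = {motif, reverse_complement(motif)}
    planted = set()
    for a, b in planted_spans:
        planted.update(range(a, b))
    s = "".join(seq)
    for _ in range(200):
        dirty = []
        for pat in patterns:
            start = s.find(pat)
            while start != -1:
                span = (start, start + len(pat))
                if span not in planted_spans:
                    dirty.append(span)
                start = s.find(pat, start + 1)
        if not dirty:
            return s
        chars = list(s)
        for a, b in dirty:
            for p in range(a, b):
                if p not in planted:
                    # pick a replacement breaking both patterns at this offset
                    bad = {chars[p]}
                    for pat in patterns:
                        bad.add(pat[p - a])
                    chars[p] = next(c for c in "ACGT" if c not in bad)
                    break
            else:
                raise RuntimeError("spurious motif occurrence fully inside a planted span")
        s = "".join(chars)
    raise RuntimeError("could not clean spurious motif occurrences")


# ---------------------------------------------------------------------------

def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1 - p))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1 / (1 + np.exp(-x))


def simulate_truth(config: SimulationConfig) -> GroundTruth:
    """True PSI matrix, regulator coupling, subtype labels and the answer key.

    Baseline PSI per exon is Beta-distributed, resampled until the group
    shift stays inside [0.01, 0.99].  In the depleted group, downstream-motif
    targets lose PSI and upstream-motif targets gain it.  Target-exon PSI is
    coupled to the regulator's within-group standardized log-expression on the
    logit scale, with slope and noise chosen so the logit-scale correlation is
    ``rho`` (sign follows the planted side).
    """
    layouts = _plan(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 103]))

    n_per = config.n_samples_per_group
    samples, groups = [], {}
    for gi, gname in enumerate(config.groups):
        for j in range(n_per):
            sid = f"S{gi * n_per + j + 1:03d}"
            samples.append(sid)
            groups[sid] = gname
    n = len(samples)
    group_arr = np.array([groups[s] for s in samples])
    depleted = group_arr == config.groups[1]

    # regulator log2 expression: depleted group down-shifted
    reg = rng.normal(8.0, 1.0, size=n)
    reg[depleted] -= 2.0
    reg_resid = reg.copy()
    for gname in config.groups:
        m = group_arr == gname
        reg_resid[m] = (reg[m] - reg[m].mean()) / (reg[m].std(ddof=0) or 1.0)

    a, b = config.psi_beta
    delta = config.delta_psi
    rows = {}
    targets = {}
    motif_positions = {}
    exon_lengths = {}
    for lay in layouts:
        bin_id = f"{lay.gene_id}:002"
        exon_lengths[bin_id] = lay.exons[1][1] - lay.exons[1][0]
        for _ in range(1000):
            base = rng.beta(a, b)
            if 0.01 + delta <= base <= 0.99 - delta:
                break
        else:
            raise RuntimeError("could not draw a feasible baseline PSI")

        mean_psi = np.full(n, base)
        if lay.is_target:
            sign = -1.0 if lay.side == "downstream" else 1.0
            mean_psi = np.where(depleted, base + sign * delta, base)
            expected = "decrease_psi" if lay.side == "downstream" else "increase_psi"
            targets[bin_id] = {"side": lay.side, "expected_effect": expected}
            motif_positions[bin_id] = {
                "side": lay.side,
                "genome_pos": int(lay.motif_genome_pos),
                "offset": int(lay.motif_offset),
            }
            s_tot = config.coupling_logit_sd
            slope = config.rho * s_tot * (-sign)  # downstream: +corr with regulator
            noise = math.sqrt(max(1 - config.rho**2, 0.0)) * s_tot
            logit_psi = (
                _logit(np.clip(mean_psi, 0.005, 0.995))
                + slope * reg_resid
                + rng.normal(0, noise, size=n)
            )
            psi = _expit(logit_psi)
        else:
            # uncoupled, but with per-sample noise of the same magnitude so
            # target and non-target exons are exchangeable under the null
            logit_psi = _logit(np.clip(mean_psi, 0.005, 0.995)) + rng.normal(
                0, config.coupling_logit_sd, size=n
            )
            psi = _expit(logit_psi)
        rows[bin_id] = np.clip(psi, 0.001, 0.999)

    true_psi = pd.DataFrame(rows, index=samples).T
    true_psi.index.name = "bin_id"

    subtype_labels = {
        s: ("subtypeA" if i % 2 == 0 else "subtypeB") for i, s in enumerate(samples)
    }
    return GroundTruth(
        samples=samples,
        groups=groups,
        true_psi=true_psi,
        targets=targets,
        regulator_log_expr=pd.Series(reg, index=samples),
        subtype_labels=subtype_labels,
        motif_positions=motif_positions,
        exon_lengths=exon_lengths,
    )


def normalized_inclusion_probability(psi: np.ndarray, exon_length, read_length: int):
    """Re-express PSI on the raw-count scale so the normalized estimator is
    unbiased: psi' = psi*NI / (psi*NI + (1-psi)*NE)."""
    ni = np.asarray(exon_length) + read_length - 1
    ne = read_length - 1
    psi = np.asarray(psi, dtype=float)
    return psi * ni / (psi * ni + (1 - psi) * ne)


def simulate_counts(truth: GroundTruth, config: SimulationConfig) -> pd.DataFrame:
    """Exon-event count table: Poisson total events, binomial inclusion split.

    Columns: bin_id, sample_id, incl_body, incl_junc, excl_junc.
    """
    if config.events_per_exon <= 0:
        raise ValueError("events_per_exon must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 104]))
    recs = []
    for bin_id in truth.true_psi.index:
        exon_len = truth.exon_lengths[bin_id]
        for sample in truth.samples:
            psi = truth.true_psi.loc[bin_id, sample]
            n_events = rng.poisson(config.events_per_exon)
            psi_prime = float(
                normalized_inclusion_probability(psi, exon_len, config.read_length)
            )
            incl = rng.binomial(n_events, psi_prime) if n_events else 0
            excl = n_events - incl
            body = rng.binomial(incl, 0.5) if incl else 0
            recs.append((bin_id, sample, int(body), int(incl - body), int(excl)))
    return pd.DataFrame(
        recs, columns=["bin_id", "sample_id", "incl_body", "incl_junc", "excl_junc"]
    )


def simulate_reads(
    events: pd.DataFrame,
    layouts_by_bin: dict[str, GeneLayout],
    read_length: int,
    seed: int = 0,
    chrom: str = "chr1",
) -> pd.DataFrame:
    """Concrete spliced-read block table realizing an event-count table.

    Columns: read_id, chrom, strand, sample_id, bin_id, blocks
    (comma-separated ``start-end`` pairs, 0-based half-open).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 105]))
    rows = []
    rid = 0
    for t in events.itertuples():
        lay = layouts_by_bin[t.bin_id]
        (u0, u1), (c0, c1), (d0, d1) = lay.exons
        for _ in range(int(t.incl_body)):
            start = int(rng.integers(c0, max(c0 + 1, c1 - read_length + 1)))
            end = min(start + read_length, c1)
            rows.append((f"r{rid}", chrom, lay.strand, t.sample_id, t.bin_id, f"{start}-{end}"))
            rid += 1
        for _ in range(int(t.incl_junc)):
            x = int(rng.integers(1, read_length))
            x = min(x, u1 - u0, read_length - 1)
            blocks = f"{u1 - x}-{u1},{c0}-{min(c0 + read_length - x, c1)}"
            rows.append((f"r{rid}", chrom, lay.strand, t.sample_id, t.bin_id, blocks))
            rid += 1
        for _ in range(int(t.excl_junc)):
            x = int(rng.integers(1, read_length))
            x = min(x, u1 - u0, read_length - 1)
            blocks = f"{u1 - x}-{u1},{d0}-{min(d0 + read_length - x, d1)}"
            rows.append((f"r{rid}", chrom, lay.strand, t.sample_id, t.bin_id, blocks))
            rid += 1
    return pd.DataFrame(
        rows, columns=["read_id", "chrom", "strand", "sample_id", "bin_id", "blocks"]
    )


# ---------------------------------------------------------------------------

def simulate_subtype_expression(
    n_samples: int = 60,
    n_signature_genes: int = 28,
    effect_size: float = 2.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Two-subtype expression on a signature gene set (log2 scale).

    Half of the genes are basal markers (up in subtype A), half classical
    (up in subtype B); the between-group shift is ``effect_size`` SDs.
    Returns (genes x samples matrix, true labels).
    """
    rng = np.random.default_rng(seed)
    half_g = n_signature_genes // 2
    genes = [f"SIGB{i + 1:02d}" for i in range(half_g)] + [
        f"SIGC{i + 1:02d}" for i in range(n_signature_genes - half_g)
    ]
    samples = [f"S{i + 1:03d}" for i in range(n_samples)]
    labels = pd.Series(
        ["subtypeA" if i < n_samples // 2 else "subtypeB" for i in range(n_samples)],
        index=samples,
    )
    is_a = (labels == "subtypeA").values
    x = rng.normal(0, 1, size=(n_signature_genes, n_samples))
    d = effect_size / 2
    x[:half_g, is_a] += d
    x[:half_g, ~is_a] -= d
    x[half_g:, is_a] -= d
    x[half_g:, ~is_a] += d
    return pd.DataFrame(x + 8.0, index=genes, columns=samples), labels


def _simulate_expression_counts(
    truth: GroundTruth, layouts: list[GeneLayout], config: SimulationConfig, rng
) -> tuple[pd.DataFrame, pd.Series]:
    """Gene count matrix with the regulator, signature genes and gene-body
    decoys; returns (counts, gene lengths)."""
    samples = truth.samples
    gene_ids = [lay.gene_id for lay in layouts]
    lengths = {lay.gene_id: sum(e - s for s, e in lay.exons) for lay in layouts}
    lengths["REGULATOR"] = 2000

    log2 = {}
    for gid in gene_ids:
        log2[gid] = rng.normal(7.0, 1.0, size=len(samples))
    log2["REGULATOR"] = truth.regulator_log_expr.values

    sig, sig_labels = simulate_subtype_expression(
        n_samples=len(samples),
        n_signature_genes=config.n_signature_genes,
        effect_size=config.subtype_effect_size,
        seed=config.seed + 7,
    )
    # align signature columns to the truth's subtype labels
    a_pool = [c for c, l in sig_labels.items() if l == "subtypeA"]
    b_pool = [c for c, l in sig_labels.items() if l == "subtypeB"]
    chosen = []
    for s in samples:
        pool = a_pool if truth.subtype_labels[s] == "subtypeA" else b_pool
        if not pool:
            pool = a_pool or b_pool
        chosen.append(pool.pop())
    sig = sig[chosen]
    sig.columns = samples
    for g in sig.index:
        log2[g] = sig.loc[g].values
        lengths[g] = 1000

    counts = pd.DataFrame(
        {s: [np.round(2 ** log2[g][i]) for g in log2] for i, s in enumerate(samples)},
        index=list(log2.keys()),
    ).astype(int)
    return counts, pd.Series(lengths).loc[counts.index]


def make_dataset(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Write a complete synthetic bundle; returns the file manifest.

    Files: genome.fa, annotation.gtf, events.tsv, expression.tsv, design.tsv,
    signature.yaml, truth.json, sim_config.json (plus flattened.gtf for
    convenience).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    genome, genes, registry = simulate_genome_with_motifs(config)
    truth = simulate_truth(config)
    events = simulate_counts(truth, config)
    layouts = _plan(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 106]))
    counts, lengths = _simulate_expression_counts(truth, layouts, config, rng)

    manifest: dict[str, Path] = {}

    fa = outdir / "genome.fa"
    with open(fa, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    manifest["genome"] = fa

    gtf = outdir / "annotation.gtf"
    with open(gtf, "w") as fh:
        for gene in genes:
            for t in gene.transcripts:
                for e in t.exons:
                    attrs = f'gene_id "{gene.gene_id}"; transcript_id "{t.transcript_id}";'
                    fh.write(
                        "\t".join(
                            [e.chrom, "sim", "exon", str(e.start + 1), str(e.end),
                             ".", e.strand, ".", attrs]
                        )
                        + "\n"
                    )
    manifest["gtf"] = gtf

    bins = []
    for gene in genes:
        bins.extend(flatten_gene_model(gene))
    write_flattened_gtf(bins, outdir / "flattened.gtf")
    bins_to_table(bins).to_csv(outdir / "bins.tsv", sep="\t", index=False)

    events.to_csv(outdir / "events.tsv", sep="\t", index=False)
    manifest["events"] = outdir / "events.tsv"

    expr = counts.copy()
    expr.insert(0, "length", lengths.astype(int))
    expr.index.name = "gene_id"
    expr.to_csv(outdir / "expression.tsv", sep="\t")
    manifest["expression"] = outdir / "expression.tsv"

    design = pd.DataFrame(
        {
            "sample_id": truth.samples,
            "group": [truth.groups[s] for s in truth.samples],
            "subtype_true": [truth.subtype_labels[s] for s in truth.samples],
        }
    )
    design.to_csv(outdir / "design.tsv", sep="\t", index=False)
    manifest["design"] = outdir / "design.tsv"

    half_g = config.n_signature_genes // 2
    signature = {
        "basal": [f"SIGB{i + 1:02d}" for i in range(half_g)],
        "classical": [f"SIGC{i + 1:02d}" for i in range(config.n_signature_genes - half_g)],
    }
    with open(outdir / "signature.yaml", "w") as fh:
        yaml.safe_dump(signature, fh)
    manifest["signature"] = outdir / "signature.yaml"

    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1)
    manifest["truth"] = outdir / "truth.json"

    cfg = asdict(config)
    with open(outdir / "sim_config.json", "w") as fh:
        json.dump(cfg, fh, indent=1, default=list)
    manifest["config"] = outdir / "sim_config.json"

    return manifest
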