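import numpy as np
import pytest

from splicebins.intervals import GeneModel, GenomicInterval, TranscriptModel
from splicebins.simulate import SimulationConfig, make_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_gene_model(rng, gene_id="G1", max_transcripts=5, max_exons=8):
    """A random small gene model for flattening property tests."""
    strand = "+" if rng.random() < 0.5 else "-"
    n_t = int(rng.integers(1, max_transcripts + 1))
    transcripts = []
    for ti in range(n_t):
        n_e = int(rng.integers(1, max_exons + 1))
        pos = int(rng.integers(0, 50))
        exons = []
        for _ in range(n_e):
            start = pos + int(rng.integers(0, 30))
            end = start + int(rng.integers(1, 40))
            exons.append(GenomicInterval("chr1", start, end, strand))
            pos = end + int(rng.integers(0, 20))
        transcripts.append(TranscriptModel(f"T{ti}", gene_id, exons))
    return GeneModel(gene_id, "chr1", strand, transcripts)


def sweep_oracle(gene):
    """Brute-force per-base flattening: label each exonic base with its
    transcript set and merge runs of identical labels."""
    lo = min(e.start for t in gene.transcripts for e in t.exons)
    hi = max(e.end for t in gene.transcripts for e in t.exons)
    labels = []
    for pos in range(lo, hi):
        support = frozenset(
            t.transcript_id
            for t in gene.transcripts
            if any(e.start <= pos < e.end for e in t.exons)
        )
        labels.append((pos, support))
    runs = []
    for pos, support in labels:
        if not support:
            continue
        if runs and runs[-1][1] == pos and runs[-1][2] == support:
            runs[-1] = (runs[-1][0], pos + 1, support)
        else:
            runs.append((pos, pos + 1, support))
    return runs


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A small but complete simulated dataset bundle."""
    outdir = tmp_path_factory.mktemp("bundle")
    cfg = SimulationConfig(
        seed=11, n_genes=20, n_target_exons=10, n_samples_per_group=8,
        events_per_exon=100.0,
    )
    manifest = make_dataset(cfg, outdir)
    return cfg, outdir, manifest
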