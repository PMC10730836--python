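import json

import numpy as np
import pandas as pd
import pytest

from splicebins.annotation import flatten_gene_model, parse_gtf
from splicebins.intervals import GenomicInterval
from splicebins.motifs import MotifSpec, classify_target, extract_flanks, scan_motif
from splicebins.quantify import count_exon_events, read_spliced_reads_tsv
from splicebins.simulate import (
    GroundTruth,
    SimulationConfig,
    _plan,
    make_dataset,
    simulate_counts,
    simulate_genome_with_motifs,
    simulate_reads,
    simulate_truth,
)

CFG = SimulationConfig(seed=21, n_genes=16, n_target_exons=8, n_samples_per_group=6)


class TestConfig:
    def test_invalid_offset_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(flank_window=500, motif_offset=600)

    def test_bad_counts_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_genes=0)
        with pytest.raises(ValueError):
            SimulationConfig(events_per_exon=0)
        with pytest.raises(ValueError):
            SimulationConfig(rho=1.5)


class TestGenome:
    def test_seed_determinism(self):
        g1, genes1, r1 = simulate_genome_with_motifs(CFG)
        g2, genes2, r2 = simulate_genome_with_motifs(CFG)
        assert g1 == g2 and r1 == r2
        assert [g.gene_id for g in genes1] == [g.gene_id for g in genes2]

    def test_planted_side_matches_registry(self):
        genome, genes, registry = simulate_genome_with_motifs(CFG)
        spec = MotifSpec(CFG.motif)
        for gene in genes:
            bins = flatten_gene_model(gene)
            cassette = bins[1]
            neighbors = [b.interval for b in bins if b.bin_id != cassette.bin_id]
            fl = extract_flanks(genome, cassette, neighbors, CFG.flank_window)
            up = scan_motif(fl.upstream_seq, spec)
            down = scan_motif(fl.downstream_seq, spec)
            if cassette.bin_id in registry:
                side = registry[cassette.bin_id]["side"]
                if side == "downstream":
                    assert len(down) == 1 and not up
                else:
                    assert len(up) == 1 and not down
            else:
                assert not up and not down

    def test_no_motif_leakage_anywhere(self):
        """All non-target flanks across the genome scan clean."""
        genome, genes, registry = simulate_genome_with_motifs(CFG)
        spec = MotifSpec(CFG.motif)
        for gene in genes:
            bins = flatten_gene_model(gene)
            for b in bins:
                if b.bin_id in registry:
                    continue
                neighbors = [o.interval for o in bins if o.bin_id != b.bin_id]
                fl = extract_flanks(genome, b, neighbors, CFG.flank_window)
                call = classify_target(fl, spec)
                assert not call.is_direct_target, b.bin_id


class TestTruth:
    def test_seed_determinism(self):
        t1, t2 = simulate_truth(CFG), simulate_truth(CFG)
        assert t1.equals(t2)

    def test_truth_effect_signs_follow_side(self):
        truth = simulate_truth(CFG)
        groups = pd.Series(truth.groups)
        ctrl = groups[groups == CFG.groups[0]].index
        depl = groups[groups == CFG.groups[1]].index
        for bin_id, info in truth.targets.items():
            d = truth.true_psi.loc[bin_id, depl].mean() - truth.true_psi.loc[bin_id, ctrl].mean()
            if info["side"] == "downstream":
                assert info["expected_effect"] == "decrease_psi" and d < 0
            else:
                assert info["expected_effect"] == "increase_psi" and d > 0

    def test_psi_bounded(self):
        truth = simulate_truth(CFG)
        assert (truth.true_psi.values > 0).all() and (truth.true_psi.values < 1).all()

    def test_regulator_coupling_close_to_rho(self):
        """Single-group config: realized PSI-regulator correlation near rho."""
        cfg = SimulationConfig(
            seed=4, n_genes=12, n_target_exons=12, n_samples_per_group=100,
            groups=("control", "control2"), delta_psi=0.0, rho=0.5,
        )
        truth = simulate_truth(cfg)
        reg = truth.regulator_log_expr
        groups = pd.Series(truth.groups)
        corrs = []
        for bin_id, info in truth.targets.items():
            sign = 1.0 if info["side"] == "downstream" else -1.0
            for g in cfg.groups:
                cols = groups[groups == g].index
                r = np.corrcoef(truth.true_psi.loc[bin_id, cols], reg.loc[cols])[0, 1]
                corrs.append(sign * r)
        assert abs(np.mean(corrs) - cfg.rho) < 0.15


class TestCounts:
    def test_seed_determinism(self):
        truth = simulate_truth(CFG)
        e1, e2 = simulate_counts(truth, CFG), simulate_counts(truth, CFG)
        pd.testing.assert_frame_equal(e1, e2)

    def test_counts_nonnegative_and_complete(self):
        truth = simulate_truth(CFG)
        events = simulate_counts(truth, CFG)
        assert (events[["incl_body", "incl_junc", "excl_junc"]].values >= 0).all()
        assert len(events) == truth.true_psi.size

    def test_monte_carlo_psi_expectation(self, rng):
        """compute_psi averaged over many simulated samples recovers psi."""
        from splicebins.quantify import ExonEventRecord, compute_psi
        from splicebins.simulate import normalized_inclusion_probability

        psi_true, n_events = 0.3, 100
        p = float(normalized_inclusion_probability(psi_true, 150, 50))
        vals = []
        for _ in range(1000):
            n = rng.poisson(n_events)
            incl = rng.binomial(n, p) if n else 0
            rec = ExonEventRecord("b", "s", incl, 0, n - incl, 50, 150)
            v = compute_psi(rec)
            if v.psi is not None:
                vals.append(v.psi)
        assert 0.29 <= np.mean(vals) <= 0.31


class TestReads:
    def test_reads_reproduce_event_counts(self):
        cfg = SimulationConfig(seed=9, n_genes=4, n_target_exons=2, n_samples_per_group=2,
                               events_per_exon=40.0)
        truth = simulate_truth(cfg)
        events = simulate_counts(truth, cfg)
        layouts = {f"{lay.gene_id}:002": lay for lay in _plan(cfg)}
        reads_df = simulate_reads(events, layouts, cfg.read_length, seed=1)
        from splicebins.annotation import flatten_gene_model
        from splicebins.simulate import _layout_to_gene_model
        from splicebins.intervals import GenomicInterval as GI
        from splicebins.quantify import SplicedRead

        for t in events.itertuples():
            lay = layouts[t.bin_id]
            gene = _layout_to_gene_model(lay)
            bins = flatten_gene_model(gene)
            cassette = bins[1]
            sub = reads_df[(reads_df.bin_id == t.bin_id) & (reads_df.sample_id == t.sample_id)]
            reads = []
            for row in sub.itertuples():
                blocks = [
                    GI("chr1", int(p.split("-")[0]), int(p.split("-")[1]), lay.strand)
                    for p in row.blocks.split(",")
                ]
                reads.append(SplicedRead(row.read_id, "chr1", blocks))
            up = GI("chr1", *lay.exons[0], lay.strand)
            down = GI("chr1", *lay.exons[2], lay.strand)
            rec = count_exon_events(reads, cassette, up, down, cfg.read_length)
            assert rec.inclusion_body + rec.inclusion_junction == t.incl_body + t.incl_junc
            assert rec.exclusion_junction == t.excl_junc


class TestMakeDataset:
    def test_bundle_files_exist_and_parse(self, small_bundle):
        cfg, outdir, manifest = small_bundle
        for key in ("genome", "gtf", "events", "expression", "design", "signature", "truth", "config"):
            assert manifest[key].exists(), key
        genes = parse_gtf(manifest["gtf"])
        assert len(genes) == cfg.n_genes
        events = pd.read_csv(manifest["events"], sep="\t")
        assert set(events.columns) == {"bin_id", "sample_id", "incl_body", "incl_junc", "excl_junc"}

    def test_truth_round_trip(self, small_bundle):
        cfg, outdir, manifest = small_bundle
        truth = simulate_truth(cfg)
        with open(manifest["truth"]) as fh:
            loaded = GroundTruth.from_dict(json.load(fh))
        assert truth.equals(loaded)

    def test_zero_samples_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            SimulationConfig(n_samples_per_group=0)
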