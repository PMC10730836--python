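"""Pipeline configuration and stage orchestration."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from splicebins import annotation, motifs, quantify, stats, subtypes

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    # input paths
    genome: str | None = None
    gtf: str | None = None
    events: str | None = None
    expression: str | None = None
    design: str | None = None
    signature: str | None = None
    outdir: str = "splicebins_out"
    # parameters
    window: int = 500
    motif: str = "TGCATG"
    min_total: int = 10
    read_length: int = 50
    normalize_psi: bool = True
    trim: bool = True
    trim_k: float = 2.0
    n_perm: int = 10000
    seed: int = 0
    fdr_q: float = 0.05
    regulator_gene: str = "REGULATOR"
    n_resamples: int = 1000
    subsample_frac: float = 0.8
    log2_pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be > 0")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.min_total < 0:
            raise ValueError("min_total must be >= 0")
        if not (0 < self.subsample_frac <= 1):
            raise ValueError("subsample_frac must be in (0, 1]")
        if not (0 < self.fdr_q < 1):
            raise ValueError("fdr_q must be in (0, 1)")


@dataclass
class RunReport:
    stages: dict = field(default_factory=dict)  # name -> {records, seconds}
    warnings: int = 0
    manifest: list = field(default_factory=list)
    config_hash: str = ""

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def validate_config(path: str | Path) -> PipelineConfig:
    """Load a JSON/YAML config, reject unknown keys, fill defaults."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    cfg = PipelineConfig(**raw)
    base = path.parent
    for name in ("genome", "gtf", "events", "expression", "design", "signature", "outdir"):
        val = getattr(cfg, name)
        if val is not None:
            setattr(cfg, name, str((base / val).resolve()) if not os.path.isabs(val) else val)
    return cfg


def _read_fasta(path: str | Path) -> dict[str, str]:
    genome: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                name = line[1:].split()[0]
                genome[name] = []
            elif name is not None:
                genome[name].append(line)
    return {k: "".join(v) for k, v in genome.items()}


def _atomic_write(df: pd.DataFrame, path: Path, **kwargs) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    df.to_csv(tmp, sep="\t", **kwargs)
    os.replace(tmp, path)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute flatten -> PSI -> TPM -> motifs -> group stats -> correlation +
    permutation -> subtyping, writing schema-stable TSV/JSON outputs."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport()
    cfg_json = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    report.config_hash = hashlib.sha256(cfg_json.encode()).hexdigest()[:16]

    def stage(name):
        t0 = time.perf_counter()

        def done(records):
            report.stages[name] = {
                "records": int(records),
                "seconds": round(time.perf_counter() - t0, 3),
            }

        return done

    # --- flatten -----------------------------------------------------------
    done = stage("flatten")
    if config.gtf is None or not Path(config.gtf).exists():
        raise FileNotFoundError(f"flatten stage input missing: gtf={config.gtf}")
    genes = annotation.parse_gtf(config.gtf)
    bins = annotation.flatten_genes(genes)
    bins_by_id = {b.bin_id: b for b in bins}
    bin_table = annotation.bins_to_table(bins)
    _atomic_write(bin_table, outdir / "bins.tsv", index=False)
    annotation.write_flattened_gtf(bins, outdir / "flattened.gtf")
    report.manifest += ["bins.tsv", "flattened.gtf"]
    done(len(bins))

    # --- PSI ---------------------------------------------------------------
    done = stage("psi")
    if config.events is None or not Path(config.events).exists():
        raise FileNotFoundError(f"quantify stage input missing: events={config.events}")
    events = pd.read_csv(config.events, sep="\t")
    exon_lengths = pd.Series(
        {b.bin_id: len(b.interval) for b in bins}, name="exon_length"
    )
    psi_matrix = quantify.events_to_psi_matrix(
        events,
        exon_lengths,
        read_length=config.read_length,
        min_total=config.min_total,
        normalize=config.normalize_psi,
    )
    _atomic_write(psi_matrix, outdir / "psi_matrix.tsv")
    report.manifest.append("psi_matrix.tsv")
    done(psi_matrix.size)

    # --- TPM ---------------------------------------------------------------
    tpm = log2tpm = None
    if config.expression is not None:
        done = stage("tpm")
        expr = pd.read_csv(config.expression, sep="\t", index_col=0)
        lengths = expr["length"]
        counts = expr.drop(columns=["length"])
        tpm, log2tpm = quantify.compute_tpm(counts, lengths, config.log2_pseudocount)
        _atomic_write(tpm, outdir / "tpm.tsv")
        _atomic_write(log2tpm, outdir / "log2tpm.tsv")
        report.manifest += ["tpm.tsv", "log2tpm.tsv"]
        done(tpm.size)

    # --- motif target calls ------------------------------------------------
    calls: dict[str, motifs.TargetCall] = {}
    if config.genome is not None:
        done = stage("motifs")
        if not Path(config.genome).exists():
            raise FileNotFoundError(f"motif stage input missing: genome={config.genome}")
        genome = _read_fasta(config.genome)
        spec = motifs.MotifSpec(config.motif)
        by_gene: dict[str, list] = {}
        for b in bins:
            by_gene.setdefault(b.gene_id, []).append(b)
        rows = []
        for gene_bins in by_gene.values():
            for b in gene_bins:
                neighbors = [o.interval for o in gene_bins if o.bin_id != b.bin_id]
                fl = motifs.extract_flanks(genome, b, neighbors, window=config.window)
                call = motifs.classify_target(fl, spec)
                calls[b.bin_id] = call
                rows.append(
                    {
                        "bin_id": b.bin_id,
                        "n_up": len(call.upstream_hits),
                        "n_down": len(call.downstream_hits),
                        "up_positions": ",".join(map(str, call.upstream_hits)),
                        "down_positions": ",".join(map(str, call.downstream_hits)),
                        "is_direct_target": call.is_direct_target,
                        "predicted_depletion_effect": call.predicted_depletion_effect,
                    }
                )
        _atomic_write(pd.DataFrame(rows), outdir / "target_calls.tsv", index=False)
        report.manifest.append("target_calls.tsv")
        done(len(rows))

    # --- group comparison --------------------------------------------------
    design = None
    if config.design is not None:
        design = pd.read_csv(config.design, sep="\t").set_index("sample_id")
        done = stage("diffsplice")
        groups = design["group"]
        rows = []
        for bin_id, row in psi_matrix.iterrows():
            try:
                res = stats.compare_psi_groups(
                    row, groups, trim=config.trim, k_sd=config.trim_k
                )
            except ValueError:
                continue
            rows.append(
                {
                    "bin_id": bin_id,
                    "delta_psi": res.effect,
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "method": res.method,
                }
            )
        diff = pd.DataFrame(rows)
        if len(diff):
            diff["q_value"] = stats.bh_adjust(diff["p_value"].values)
        _atomic_write(diff, outdir / "diff_splicing.tsv", index=False)
        report.manifest.append("diff_splicing.tsv")
        done(len(diff))

    # --- correlation + permutation ----------------------------------------
    if log2tpm is not None and config.regulator_gene in log2tpm.index:
        done = stage("correlation")
        reg = log2tpm.loc[config.regulator_gene, psi_matrix.columns]
        rows = []
        for bin_id, row in psi_matrix.iterrows():
            for method in ("pearson", "spearman"):
                try:
                    res = stats.correlate_psi_expression(row.values, reg.values, method)
                except ValueError:
                    continue
                rows.append(
                    {"bin_id": bin_id, "method": method, "r": res.effect, "p_value": res.p_value}
                )
        _atomic_write(pd.DataFrame(rows), outdir / "correlations.tsv", index=False)
        report.manifest.append("correlations.tsv")
        done(len(rows))

        done = stage("permutation")
        target_ids = [
            b for b, c in calls.items() if c.is_direct_target and b in psi_matrix.index
        ]
        # random exon collections are drawn from the full quantified exon set
        background_ids = list(psi_matrix.index)
        if target_ids and len(background_ids) >= len(target_ids):
            perm = stats.permutation_correlation_test(
                psi_matrix,
                reg.values,
                target_ids,
                background_ids,
                n_perm=config.n_perm,
                seed=config.seed,
            )
            payload = dataclasses.asdict(perm)
            tmp = outdir / "permutation.json.tmp"
            with open(tmp, "w") as fh:
                json.dump(payload, fh, indent=1)
            os.replace(tmp, outdir / "permutation.json")
            report.manifest.append("permutation.json")
            done(perm.n_perm)
        else:
            logger.warning("permutation skipped: no usable target set")
            report.warnings += 1
            done(0)

    # --- subtyping ---------------------------------------------------------
    if config.signature is not None and log2tpm is not None:
        done = stage("subtype")
        with open(config.signature) as fh:
            sig_raw = yaml.safe_load(fh)
        signature = subtypes.SignatureGeneSet(
            basal_markers=list(sig_raw["basal"]), classical_markers=list(sig_raw["classical"])
        )
        sub_expr = log2tpm.loc[signature.all_genes]
        cons = subtypes.consensus_cluster(
            sub_expr,
            k=2,
            n_resamples=config.n_resamples,
            subsample_frac=config.subsample_frac,
            seed=config.seed,
        )
        assignment = subtypes.assign_subtype_labels(cons, log2tpm, signature)
        out = pd.DataFrame(
            {
                "sample_id": cons.final_labels.index,
                "cluster": cons.final_labels.values,
                "subtype": assignment.labels.values,
            }
        )
        _atomic_write(out, outdir / "subtypes.tsv", index=False)
        _atomic_write(cons.consensus_matrix, outdir / "consensus_matrix.tsv")
        report.manifest += ["subtypes.tsv", "consensus_matrix.tsv"]
        done(len(out))

    with open(outdir / "run_report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=1)
    return report
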