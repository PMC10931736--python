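"""End-to-end orchestration of the marker pipeline from a single config.

Stages communicate through files with documented schemas (FASTQ, TSV, CSV,
GMT, PNG, JSON) so each stage is independently runnable and resumable. A
run manifest records the package version, the global seed, every stage's
parameters, and a SHA-256 checksum of every file written — reruns with the
same seed produce identical checksums.

Config is a YAML mapping: a global ``seed``, an ``outdir``, a ``stages``
list selecting which stages run, and optional per-stage parameter blocks
(defaults follow the source study: FDR < 0.01, |log2FC| > 1, FPKM >= 0.1,
cor > 0.6, enrichment p <= 0.05, top-2 hubs).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coexpression import build_network, edge_table, hub_genes, node_table
from .expression import de_screen, expressed_filter, fpkm
from .geneset import (
    DEFAULT_LIPID_KEYWORDS,
    filter_terms_by_keyword,
    hypergeom_enrich,
    merge_dedup,
    read_gmt,
    select_multiterm_genes,
    write_gmt,
)
from .image_quant import ImagePair, overlap_r, pearson_rr
from .popgen import genotype_counts_from_csv, load_table1_fixture, table_report
from .protein import physchem_report, translate
from .qpcr import ddct, group_compare
from .read_qc import filter_reads, write_fastq
from .synthetic_data import (
    ADAPTER_13MER,
    SimConfig,
    simulate_cds,
    simulate_counts,
    simulate_ct_table,
    simulate_fastq,
    simulate_gene_sets,
    simulate_image_pair,
)

log = logging.getLogger("imf.pipeline")

ALL_STAGES = ("simulate", "qc", "de", "enrich", "network", "qpcr", "coloc", "popgen", "protchem")

DEFAULTS = {
    "fdr_cut": 0.01,
    "lfc_cut": 1.0,
    "min_fpkm": 0.1,
    "cor_threshold": 0.6,
    "enrich_alpha": 0.05,
    "min_terms": 5,
    "top_hubs": 2,
    "control_group": "STH",
}


@dataclass
class PipelineConfig:
    """Validated run configuration."""

    seed: int = 0
    outdir: Path = Path("imf_run")
    stages: tuple[str, ...] = ALL_STAGES
    params: dict = field(default_factory=dict)
    sim: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        merged = dict(DEFAULTS)
        merged.update(self.params)
        self.params = merged
        if not 0 < self.params["fdr_cut"] <= 1:
            raise ValueError("fdr_cut must be in (0, 1]")
        if self.params["cor_threshold"] >= 1 or self.params["cor_threshold"] < 0:
            raise ValueError("cor_threshold must be in [0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            seed=int(raw.get("seed", 0)),
            outdir=Path(raw.get("outdir", "imf_run")),
            stages=tuple(raw.get("stages", ALL_STAGES)),
            params=dict(raw.get("params", {})),
            sim=dict(raw.get("sim", {})),
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the enabled stages in order and return the manifest dict.

    The ``simulate`` stage writes every synthetic input the later stages
    consume; a later stage whose input file is missing fails naming the
    stage that should have produced it.
    """
    out = cfg.outdir
    out.mkdir(parents=True, exist_ok=True)
    sim_cfg = SimConfig(seed=cfg.seed, **cfg.sim)
    p = cfg.params
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "parameters": dict(p),
        "stages": [],
        "files": {},
    }

    def record(stage: str, *paths: Path) -> None:
        manifest["stages"].append(stage)
        for path in paths:
            manifest["files"][str(path.relative_to(out))] = _sha256(path)

    def require(stage: str, path: Path) -> Path:
        if not path.exists():
            raise FileNotFoundError(
                f"stage {stage!r} needs {path.name}, produced by an earlier stage that did not run"
            )
        return path

    if "simulate" in cfg.stages:
        log.info("simulate: generating synthetic inputs (seed=%d)", cfg.seed)
        reads, read_truth = simulate_fastq(sim_cfg)
        write_fastq(reads, out / "reads.fastq")
        read_truth.to_csv(out / "read_truth.csv", index=False)
        matrix, deg_truth = simulate_counts(sim_cfg)
        matrix.to_tsv(out / "counts.tsv")
        matrix.lengths.rename_axis("gene").to_csv(out / "gene_lengths.tsv", sep="\t")
        matrix.groups.rename_axis("sample").rename("group").to_csv(out / "sample_groups.tsv", sep="\t")
        deg_truth.to_csv(out / "deg_truth.csv", index=False)
        write_gmt(simulate_gene_sets(sim_cfg, deg_truth), out / "annotation.gmt")
        simulate_ct_table(sim_cfg).to_csv(out / "ct.csv", index=False)
        ch1, ch2, mask = simulate_image_pair(sim_cfg)
        import imageio.v3 as iio

        iio.imwrite(out / "channel1.png", ch1)
        iio.imwrite(out / "channel2.png", ch2)
        iio.imwrite(out / "mask.png", mask.astype(np.uint8) * 255)
        with open(out / "cds.fasta", "w") as fh:
            fh.write(">synthetic_cds\n" + simulate_cds(sim_cfg) + "\n")
        record(
            "simulate",
            out / "reads.fastq", out / "read_truth.csv", out / "counts.tsv",
            out / "gene_lengths.tsv", out / "sample_groups.tsv", out / "deg_truth.csv",
            out / "annotation.gmt", out / "ct.csv", out / "channel1.png",
            out / "channel2.png", out / "mask.png", out / "cds.fasta",
        )

    if "qc" in cfg.stages:
        from .read_qc import read_fastq

        reads = list(read_fastq(require("qc", out / "reads.fastq")))
        kept, report = filter_reads(reads, p.get("adapter", ADAPTER_13MER))
        write_fastq(kept, out / "clean.fastq")
        (out / "qc_report.json").write_text(report.to_json())
        log.info("qc: %s", report)
        record("qc", out / "clean.fastq", out / "qc_report.json")

    deg_table = None
    fpkm_matrix = None
    if "de" in cfg.stages:
        from .expression import ExpressionMatrix

        groups = pd.read_csv(require("de", out / "sample_groups.tsv"), sep="\t", index_col=0)["group"]
        lengths = pd.read_csv(require("de", out / "gene_lengths.tsv"), sep="\t", index_col=0)["length"]
        counts = ExpressionMatrix.from_tsv(out / "counts.tsv", groups=groups, lengths=lengths)
        fpkm_matrix = expressed_filter(fpkm(counts), p["min_fpkm"])
        fpkm_matrix.to_tsv(out / "fpkm.tsv")
        deg_table = de_screen(
            fpkm_matrix, p["control_group"], fdr_cut=p["fdr_cut"], lfc_cut=p["lfc_cut"]
        )
        deg_table.to_csv(out / "deg_table.tsv", sep="\t", index=False)
        log.info("de: %d/%d genes pass FDR<%g, |log2FC|>%g",
                 int(deg_table["is_deg"].sum()), len(deg_table), p["fdr_cut"], p["lfc_cut"])
        record("de", out / "fpkm.tsv", out / "deg_table.tsv")

    candidates = None
    if "enrich" in cfg.stages:
        if deg_table is None:
            deg_table = pd.read_csv(require("enrich", out / "deg_table.tsv"), sep="\t")
        annotation = read_gmt(require("enrich", out / "annotation.gmt"), ontology="BP")
        lipid_terms = filter_terms_by_keyword(annotation, p.get("keywords", DEFAULT_LIPID_KEYWORDS))
        universe = deg_table["gene"].tolist()
        degs = deg_table.loc[deg_table["is_deg"], "gene"].tolist()
        enrichment = hypergeom_enrich(degs, lipid_terms, universe, alpha=p["enrich_alpha"])
        enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        selected = select_multiterm_genes(enrichment, lipid_terms, degs, min_terms=p["min_terms"])
        candidates = merge_dedup([selected])
        (out / "candidates.txt").write_text("\n".join(candidates) + "\n")
        log.info("enrich: %d significant terms, %d candidate genes",
                 int(enrichment["significant"].sum()) if len(enrichment) else 0, len(candidates))
        record("enrich", out / "enrichment.tsv", out / "candidates.txt")

    if "network" in cfg.stages:
        if fpkm_matrix is None:
            from .expression import ExpressionMatrix

            groups = pd.read_csv(require("network", out / "sample_groups.tsv"), sep="\t", index_col=0)["group"]
            fpkm_matrix = ExpressionMatrix.from_tsv(
                require("network", out / "fpkm.tsv"), groups=groups, units="fpkm"
            )
        if candidates is None:
            candidates = require("network", out / "candidates.txt").read_text().split()
        net = build_network(fpkm_matrix.values, candidates, threshold=p["cor_threshold"])
        edge_table(net).to_csv(out / "network_edges.tsv", sep="\t", index=False)
        node_table(net).to_csv(out / "network_nodes.tsv", sep="\t", index=False)
        hubs = hub_genes(net, p["top_hubs"]) if net.number_of_nodes() else []
        (out / "hub_genes.txt").write_text("\n".join(hubs) + "\n")
        log.info("network: %d nodes, %d edges, hubs=%s", net.number_of_nodes(), net.number_of_edges(), hubs)
        record("network", out / "network_edges.tsv", out / "network_nodes.tsv", out / "hub_genes.txt")

    if "qpcr" in cfg.stages:
        ct = pd.read_csv(require("qpcr", out / "ct.csv"))
        target = p.get("qpcr_target", "PIK3R1")
        folds = ddct(ct, target=target, reference=p.get("qpcr_reference", "GAPDH"),
                     calibrator_group=p["control_group"])
        folds.to_csv(out / "qpcr_folds.tsv", sep="\t", index=False)
        comparison = group_compare(folds)
        comparison.to_csv(out / "qpcr_groups.tsv", sep="\t", index=False)
        log.info("qpcr: %s", comparison.to_dict("records"))
        record("qpcr", out / "qpcr_folds.tsv", out / "qpcr_groups.tsv")

    if "coloc" in cfg.stages:
        import imageio.v3 as iio

        ch1 = iio.imread(require("coloc", out / "channel1.png"))
        ch2 = iio.imread(require("coloc", out / "channel2.png"))
        mask = iio.imread(require("coloc", out / "mask.png")) > 0
        pair = ImagePair(ch1, ch2, mask)
        result = {"pearson_rr": pearson_rr(pair), "overlap_r": overlap_r(pair)}
        (out / "colocalization.json").write_text(json.dumps(result, indent=2))
        log.info("coloc: Rr=%.3f R=%.3f", result["pearson_rr"], result["overlap_r"])
        record("coloc", out / "colocalization.json")

    if "popgen" in cfg.stages:
        counts_csv = p.get("genotype_csv")
        pops = genotype_counts_from_csv(counts_csv) if counts_csv else load_table1_fixture()
        report = table_report(pops, convention=p.get("convention", "paper_rounded"),
                              df=int(p.get("hwe_df", 2)))
        report.to_csv(out / "diversity_table.tsv", sep="\t", index=False)
        log.info("popgen: %d populations (+pooled) reported", len(pops))
        record("popgen", out / "diversity_table.tsv")

    if "protchem" in cfg.stages:
        from Bio import SeqIO

        cds = str(next(SeqIO.parse(str(require("protchem", out / "cds.fasta")), "fasta")).seq)
        protein = translate(cds)
        e_pos = protein.index("E") + 1
        mutant = protein[: e_pos - 1] + "U" + protein[e_pos:]
        result = {
            "wild_type": physchem_report(protein).as_dict(),
            "mutant_E%dU" % e_pos: physchem_report(mutant).as_dict(),
        }
        (out / "physchem.json").write_text(json.dumps(result, indent=2))
        record("protchem", out / "physchem.json")

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
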