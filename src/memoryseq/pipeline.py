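"""End-to-end orchestration of the analysis stages.

Stages run in order: (simulate?) -> differential expression -> profile /
memory classification -> DMR calling -> methylation-expression linkage ->
term enrichment.  A single config object (YAML-serializable) carries every
threshold exactly once; the effective config and a machine-readable summary
are written into the run directory, and a rerun with the same config and
seed reproduces the summary byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .enrichment import hypergeometric_enrichment
from .expression import default_contrasts, run_contrasts
from .linkage import associate_dmr_gene, correlate_linkage
from .methylation import dmr_analysis
from .profiles import classify_genes, profile_catalog
from .simulate import (LinkageSimConfig, MethylomeSimConfig, SimulationConfig,
                       simulate_expression, simulate_linkage, simulate_methylome)

log = logging.getLogger("memoryseq")


@dataclass
class PipelineConfig:
    """All pipeline inputs, outputs and thresholds in one place."""

    outdir: str = "memoryseq_run"
    seed: int = 0
    simulate: bool = False
    conditions: tuple[str, ...] = ("R0", "S1", "R3", "S4")
    # inputs (ignored with simulate=True)
    expression: str | None = None
    samples: str | None = None
    cytosines_a: str | None = None
    cytosines_b: str | None = None
    gene_models: str | None = None
    annotation: str | None = None
    meth_levels: str | None = None
    # differential expression
    fc_threshold: float = 1.0
    fdr_threshold: float = 0.05
    # memory / profiles
    memory_rule: str = "any"
    max_unit_change: int = 1
    # DMR calling
    window: int = 200
    step: int = 50
    p_cut: float = 0.05
    q_cut: float = 0.05
    min_coverage: int = 5
    # linkage
    pos_thr: float = 0.04
    neg_thr: float = -0.04
    promoter_bp: int = 2000
    # simulation sub-configs (plain dicts so the YAML round-trips)
    sim_expression: dict = field(default_factory=dict)
    sim_methylome: dict = field(default_factory=dict)
    sim_linkage: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "conditions" in data:
            data["conditions"] = tuple(data["conditions"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["conditions"] = list(self.conditions)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _require(path: str | None, what: str) -> Path:
    if path is None:
        raise FileNotFoundError(f"missing input: {what} (no path configured)")
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"missing input: {what} at {p}")
    return p


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every applicable stage; returns the summary dict (also written to
    <outdir>/summary.json)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    summary: dict = {"seed": config.seed, "conditions": list(config.conditions)}
    try:
        config.to_yaml(outdir / "effective_config.yaml")
        t0 = time.time()

        # ---- stage: inputs (simulate or load) ----------------------------
        links_truth = None
        levels = None
        gene_models = None
        annotation = None
        if config.simulate:
            inputs = outdir / "inputs"
            inputs.mkdir(exist_ok=True)
            ecfg = SimulationConfig(**{"seed": config.seed,
                                       "conditions": tuple(config.conditions),
                                       **config.sim_expression})
            table, expr_truth = simulate_expression(ecfg)
            mcfg = MethylomeSimConfig(**{"seed": config.seed + 1,
                                         **config.sim_methylome})
            cyt_a, cyt_b, dmr_truth = simulate_methylome(mcfg)
            lcfg = LinkageSimConfig(**{"seed": config.seed + 2,
                                       **config.sim_linkage})
            levels, gene_models, links_truth = simulate_linkage(
                table, expr_truth, dmr_truth, lcfg)
            annotation = _synthetic_annotation(expr_truth, config.seed + 3)
            mio.write_expression(table, inputs / "expression.tsv",
                                 inputs / "samples.tsv")
            mio.write_cytosine_report(cyt_a, inputs / "cytosines_a.tsv")
            mio.write_cytosine_report(cyt_b, inputs / "cytosines_b.tsv")
            mio.write_gene_models_bed(gene_models, inputs / "genes.bed")
            mio.write_levels(levels, inputs / "meth_levels.tsv")
            expr_truth.to_csv(inputs / "truth_expression.tsv", sep="\t")
            dmr_truth.to_csv(inputs / "truth_dmrs.tsv", sep="\t", index=False)
            links_truth.to_csv(inputs / "truth_links.tsv", sep="\t", index=False)
            annotation.to_csv(inputs / "annotation.tsv", sep="\t", index=False)
            summary["simulated"] = True
        else:
            table = mio.read_expression(
                _require(config.expression, "expression matrix"),
                _require(config.samples, "sample sheet"))
            cyt_a = cyt_b = None
            if config.cytosines_a and config.cytosines_b:
                cyt_a = mio.read_cytosine_report(_require(config.cytosines_a,
                                                          "cytosine report A"))
                cyt_b = mio.read_cytosine_report(_require(config.cytosines_b,
                                                          "cytosine report B"))
            if config.gene_models:
                gene_models = mio.read_gene_models(_require(config.gene_models,
                                                            "gene models"))
            if config.annotation:
                annotation = mio.read_annotation(_require(config.annotation,
                                                          "annotation map"))
            if config.meth_levels:
                levels = mio.read_levels(_require(config.meth_levels,
                                                  "methylation level matrix"))
            summary["simulated"] = False
        summary["n_genes"] = int(table.counts.shape[0])
        summary["n_samples"] = int(table.counts.shape[1])
        log.info("inputs ready: %d genes x %d samples (%.1fs)",
                 summary["n_genes"], summary["n_samples"], time.time() - t0)

        # ---- stage: differential expression ------------------------------
        t0 = time.time()
        de_dir = outdir / "de"
        de_dir.mkdir(exist_ok=True)
        contrasts = default_contrasts(config.conditions)
        de = run_contrasts(table, contrasts, fc_threshold=config.fc_threshold,
                           fdr_threshold=config.fdr_threshold)
        summary["de"] = {}
        for name, res in de.items():
            res.to_csv(de_dir / f"{name}.tsv", sep="\t", index_label="gene_id")
            summary["de"][name] = {
                "up": int((res["status"] == "up").sum()),
                "down": int((res["status"] == "down").sum()),
            }
        log.info("differential expression: %d contrasts (%.1fs)",
                 len(de), time.time() - t0)

        # ---- stage: profiles / memory ------------------------------------
        t0 = time.time()
        prof_dir = outdir / "profiles"
        prof_dir.mkdir(exist_ok=True)
        catalog = profile_catalog(len(config.conditions), config.max_unit_change)
        catalog.to_csv(prof_dir / "catalog.tsv", sep="\t")
        classified = classify_genes(table, de, rule=config.memory_rule,
                                    max_unit_change=config.max_unit_change)
        classified.to_csv(prof_dir / "gene_classification.tsv", sep="\t",
                          index_label="gene_id")
        summary["profiles"] = {"n_profiles": int(len(catalog))}
        summary["memory"] = {
            "n_memory": int(classified["is_memory"].sum()),
            "by_category": {k: int(v) for k, v in
                            classified.loc[classified["is_memory"], "category"]
                            .value_counts().sort_index().items()},
        }
        log.info("profiles/memory: %d memory genes (%.1fs)",
                 summary["memory"]["n_memory"], time.time() - t0)

        # ---- stage: DMR calling ------------------------------------------
        dmrs = None
        if cyt_a is not None and cyt_b is not None:
            t0 = time.time()
            dmr_dir = outdir / "dmr"
            dmr_dir.mkdir(exist_ok=True)
            stats, dmrs = dmr_analysis(cyt_a, cyt_b, window=config.window,
                                       step=config.step,
                                       min_coverage=config.min_coverage,
                                       p_cut=config.p_cut, q_cut=config.q_cut)
            stats.to_csv(dmr_dir / "window_stats.tsv", sep="\t", index=False)
            mio.write_dmrs_bed(dmrs, dmr_dir / "dmrs.bed")
            summary["dmr"] = {
                "n_windows_tested": int(stats["testable"].sum()),
                "n_dmrs": int(len(dmrs)),
                "by_context": {k: int(v) for k, v in
                               dmrs["context"].value_counts().sort_index().items()},
            }
            log.info("dmr: %d DMRs from %d tested windows (%.1fs)",
                     len(dmrs), summary["dmr"]["n_windows_tested"], time.time() - t0)

        # ---- stage: linkage ----------------------------------------------
        if dmrs is not None and gene_models is not None and levels is not None \
                and len(dmrs):
            t0 = time.time()
            link_dir = outdir / "linkage"
            link_dir.mkdir(exist_ok=True)
            pairs = associate_dmr_gene(dmrs, gene_models,
                                       promoter_bp=config.promoter_bp)
            linkage = correlate_linkage(levels, table.fpkm(), pairs,
                                        pos_thr=config.pos_thr,
                                        neg_thr=config.neg_thr)
            linkage.to_csv(link_dir / "linkage.tsv", sep="\t", index=False)
            summary["linkage"] = {
                "n_pairs": int(len(linkage)),
                "n_linked": int(linkage["linked"].sum()) if len(linkage) else 0,
            }
            log.info("linkage: %d/%d pairs linked (%.1fs)",
                     summary["linkage"]["n_linked"],
                     summary["linkage"]["n_pairs"], time.time() - t0)

        # ---- stage: enrichment -------------------------------------------
        if annotation is not None:
            t0 = time.time()
            enr_dir = outdir / "enrichment"
            enr_dir.mkdir(exist_ok=True)
            memory_genes = classified.index[classified["is_memory"]]
            enr = hypergeometric_enrichment(memory_genes, annotation,
                                            universe=table.counts.index)
            enr.to_csv(enr_dir / "enrichment.tsv", sep="\t", index=False)
            summary["enrichment"] = {
                "n_terms": int(len(enr)),
                "n_significant": int((enr["qvalue"] < 0.05).sum()),
            }
            log.info("enrichment: %d terms (%.1fs)", len(enr), time.time() - t0)

        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return summary
    finally:
        log.removeHandler(handler)
        handler.close()


def _synthetic_annotation(expr_truth: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Toy gene->term map for simulated runs: one term enriched among planted
    memory genes plus background terms assigned at random."""
    rng = np.random.default_rng(seed)
    genes = expr_truth.index.to_numpy()
    is_mem = expr_truth["is_memory"].to_numpy()
    rows = []
    keep = rng.random(len(genes)) < np.where(is_mem, 0.5, 0.05)
    for g in genes[keep]:
        rows.append({"gene": g, "term": "TERM:memory"})
    for t in range(5):
        keep = rng.random(len(genes)) < 0.1
        for g in genes[keep]:
            rows.append({"gene": g, "term": f"TERM:bg{t}"})
    return pd.DataFrame(rows, columns=["gene", "term"])
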