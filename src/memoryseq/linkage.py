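"""DMR-to-gene association and methylation-expression correlation.

A DMR is associated with a gene when it overlaps the gene body or the
strand-aware promoter window (2,000 bp upstream of the transcription start
by default).  For each associated pair, the Pearson correlation between the
DMR's per-sample methylation level and the gene's per-sample expression
(log2(FPKM+1) by default) is computed across the shared sample axis; the
pair is called linked when r exceeds the positive threshold or falls below
the negative one (the permissive defaults +0.04 / -0.04 follow the source
study; 0.4 is a common stricter choice).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

ZONES = ("body", "promoter", "downstream")


def associate_dmr_gene(dmrs: pd.DataFrame, gene_models: pd.DataFrame,
                       promoter_bp: int = 2000,
                       downstream_bp: int = 0) -> pd.DataFrame:
    """Candidate DMR-gene pairs with their association zone.

    dmrs        : DataFrame with dmr_id, chrom, start, end (0-based half-open).
    gene_models : DataFrame with gene_id, chrom, start, end, strand.

    Zone priority when a DMR overlaps several zones of one gene:
    body > promoter > downstream.  DMRs on chromosomes absent from the gene
    models are skipped with a warning.
    """
    if promoter_bp < 0 or downstream_bp < 0:
        raise ValueError("flank sizes must be non-negative")
    gene_chroms = set(gene_models["chrom"])
    rows = []
    for chrom, dsub in dmrs.groupby("chrom"):
        if chrom not in gene_chroms:
            warnings.warn(f"DMRs on {chrom!r} skipped: no gene model on that chromosome")
            continue
        gsub = gene_models[gene_models["chrom"] == chrom]
        gs = gsub["start"].to_numpy()
        ge = gsub["end"].to_numpy()
        plus = (gsub["strand"] == "+").to_numpy()
        # strand-aware flanks
        prom_s = np.where(plus, gs - promoter_bp, ge)
        prom_e = np.where(plus, gs, ge + promoter_bp)
        down_s = np.where(plus, ge, gs - downstream_bp)
        down_e = np.where(plus, ge + downstream_bp, gs)
        for rec in dsub.itertuples(index=False):
            in_body = (rec.start < ge) & (rec.end > gs)
            in_prom = (rec.start < prom_e) & (rec.end > prom_s)
            in_down = (rec.start < down_e) & (rec.end > down_s)
            zone = np.select([in_body, in_prom, in_down],
                             ["body", "promoter", "downstream"], default="")
            for g, z in zip(gsub["gene_id"], zone):
                if z:
                    rows.append({"dmr_id": rec.dmr_id, "gene_id": g, "zone": z})
    return pd.DataFrame(rows, columns=["dmr_id", "gene_id", "zone"])


def pearson_r(x, y) -> float:
    """Centered product-moment correlation; nan when either vector is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired samples")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("values must be finite")
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.linalg.norm(xc)
    ny = np.linalg.norm(yc)
    if nx == 0 or ny == 0:
        return float("nan")
    return float(np.clip(xc @ yc / (nx * ny), -1.0, 1.0))


def correlate_linkage(meth_levels: pd.DataFrame, expression: pd.DataFrame,
                      pairs: pd.DataFrame, pos_thr: float = 0.04,
                      neg_thr: float = -0.04, log2_expression: bool = True,
                      pseudocount: float = 1.0) -> pd.DataFrame:
    """Score each DMR-gene pair's across-sample correlation and link verdict.

    meth_levels : DataFrame indexed by dmr_id, one column per sample
                  (methylation level in [0, 1]).
    expression  : DataFrame indexed by gene_id with the same sample columns
                  (FPKM; log2(x + pseudocount) applied when
                  ``log2_expression``).
    pairs       : DataFrame with dmr_id, gene_id (zone column carried along).

    linked <=> r > pos_thr or r < neg_thr; undefined r (constant vector) is
    never linked.
    """
    if neg_thr > pos_thr:
        raise ValueError("neg_thr must not exceed pos_thr")
    shared = [c for c in meth_levels.columns if c in expression.columns]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples")
    expr = expression[shared]
    if log2_expression:
        expr = np.log2(expr + pseudocount)
    rows = []
    for rec in pairs.itertuples(index=False):
        if rec.dmr_id not in meth_levels.index or rec.gene_id not in expr.index:
            continue
        r = pearson_r(meth_levels.loc[rec.dmr_id, shared], expr.loc[rec.gene_id])
        linked = bool(np.isfinite(r) and (r > pos_thr or r < neg_thr))
        sign = 0 if not linked else (1 if r > 0 else -1)
        row = {"dmr_id": rec.dmr_id, "gene_id": rec.gene_id,
               "correlation": r, "linked": linked, "link_sign": sign}
        if hasattr(rec, "zone"):
            row["zone"] = rec.zone
        rows.append(row)
    return pd.DataFrame(rows)
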