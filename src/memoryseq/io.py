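"""Readers and writers for the plain-text interchange formats.

Expression matrix TSV (gene_id, length, one column per sample), sample sheet
TSV (sample, condition, replicate), Bismark-style cytosine report TSV
(chrom, 1-based pos, strand, count_methylated, count_unmethylated, context),
gene models as BED6 or GFF3, gene->term annotation TSV, and DMRs as BED6+.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionTable
from .methylation import CYTOSINE_COLUMNS, validate_cytosines


def write_expression(table: ExpressionTable, expr_path, samples_path) -> None:
    out = table.counts.copy()
    out.insert(0, "length", table.lengths)
    out.to_csv(expr_path, sep="\t", index_label="gene_id")
    table.samples.to_csv(samples_path, sep="\t", index_label="sample")


def read_expression(expr_path, samples_path, is_fpkm: bool = False) -> ExpressionTable:
    df = pd.read_csv(expr_path, sep="\t", index_col="gene_id")
    if "length" not in df.columns:
        raise ValueError(f"{expr_path}: expected a 'length' column")
    lengths = df["length"]
    counts = df.drop(columns="length")
    samples = pd.read_csv(samples_path, sep="\t", index_col="sample")
    return ExpressionTable(counts=counts, lengths=lengths, samples=samples,
                           is_fpkm=is_fpkm)


def write_cytosine_report(cytosines: pd.DataFrame, path) -> None:
    validate_cytosines(cytosines)
    cytosines[CYTOSINE_COLUMNS].to_csv(path, sep="\t", index=False, header=False)


def read_cytosine_report(path) -> pd.DataFrame:
    """Cytosine report dialect: chrom, 1-based position, strand,
    count_methylated, count_unmethylated, context (CG/CHG/CHH); headerless."""
    df = pd.read_csv(path, sep="\t", header=None, names=CYTOSINE_COLUMNS,
                     dtype={"chrom": str, "pos": np.int64, "strand": str,
                            "meth": np.int64, "unmeth": np.int64, "context": str})
    return validate_cytosines(df)


def write_gene_models_bed(gene_models: pd.DataFrame, path) -> None:
    bed = pd.DataFrame({
        "chrom": gene_models["chrom"],
        "start": gene_models["start"].astype(int),
        "end": gene_models["end"].astype(int),
        "name": gene_models["gene_id"],
        "score": 0,
        "strand": gene_models["strand"],
    })
    bed.to_csv(path, sep="\t", index=False, header=False)


def read_gene_models(path) -> pd.DataFrame:
    """Gene models from BED6 (0-based half-open) or GFF3 (gene features;
    1-based inclusive, converted)."""
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        return _read_gene_models_gff3(path)
    bed = pd.read_csv(path, sep="\t", header=None, comment="#",
                      names=["chrom", "start", "end", "name", "score", "strand"],
                      dtype={"chrom": str, "name": str, "strand": str})
    return pd.DataFrame({"gene_id": bed["name"], "chrom": bed["chrom"],
                         "start": bed["start"].astype(int),
                         "end": bed["end"].astype(int),
                         "strand": bed["strand"]})


def _read_gene_models_gff3(path) -> pd.DataFrame:
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    rows = []
    for feat in db.features_of_type("gene"):
        rows.append({"gene_id": feat.id, "chrom": feat.seqid,
                     "start": feat.start - 1, "end": feat.end,
                     "strand": feat.strand})
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


def write_dmrs_bed(dmrs: pd.DataFrame, path) -> None:
    """DMRs as BED6+ : chrom, start, end, name, -log10(min q), direction,
    context, n_windows, mean level difference."""
    q = dmrs["min_q"].to_numpy(dtype=float)
    neglog = np.where(q > 0, -np.log10(np.maximum(q, 1e-300)), 300.0)
    bed = pd.DataFrame({
        "chrom": dmrs["chrom"],
        "start": dmrs["start"].astype(int),
        "end": dmrs["end"].astype(int),
        "name": [f"dmr{int(i)}" for i in dmrs["dmr_id"]],
        "score": np.round(neglog, 4),
        "strand": dmrs["direction"].map({"hyper": "+", "hypo": "-"}),
        "context": dmrs["context"],
        "n_windows": dmrs["n_windows"].astype(int),
        "mean_diff": np.round(dmrs["mean_diff"], 6),
    })
    bed.to_csv(path, sep="\t", index=False, header=False)


def read_annotation(path) -> pd.DataFrame:
    """gene->term map: two-column TSV (gene, term), header optional."""
    df = pd.read_csv(path, sep="\t")
    cols = [c.lower() for c in df.columns]
    if "gene" in cols and "term" in cols:
        df.columns = cols
        return df[["gene", "term"]]
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "term"])
    return df


def write_levels(levels: pd.DataFrame, path) -> None:
    levels.to_csv(path, sep="\t", index_label="dmr_id")


def read_levels(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="dmr_id")
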