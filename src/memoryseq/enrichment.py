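"""Hypergeometric term enrichment for gene sets.

A generic over-representation test: for each term, the upper-tail
hypergeometric probability of drawing at least the observed number of
term-annotated genes in the query set from the annotated universe,
Benjamini-Hochberg corrected across terms.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import benjamini_hochberg


def hypergeometric_enrichment(gene_set, annotation: pd.DataFrame,
                              universe=None) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``gene_set`` per term.

    annotation : DataFrame with columns ``gene`` and ``term``.
    universe   : iterable of background genes (defaults to all annotated
                 genes).  ``gene_set`` must be a subset of the universe.

    Returns one row per term: k (set genes with term), n (set size),
    K (universe genes with term), N (universe size), pvalue, qvalue.
    """
    if not {"gene", "term"} <= set(annotation.columns):
        raise ValueError("annotation needs 'gene' and 'term' columns")
    if universe is None:
        universe = annotation["gene"].unique()
    universe = pd.Index(pd.unique(pd.Series(list(universe))))
    if len(universe) == 0:
        raise ValueError("empty universe")
    gene_set = pd.Index(pd.unique(pd.Series(list(gene_set))))
    if not gene_set.isin(universe).all():
        raise ValueError("gene_set must be a subset of the universe")
    ann = annotation[annotation["gene"].isin(universe)]
    N = len(universe)
    n = len(gene_set)
    in_set = ann["gene"].isin(gene_set)
    K_by_term = ann.groupby("term")["gene"].nunique()
    k_by_term = ann[in_set].groupby("term")["gene"].nunique()
    terms = K_by_term.index
    K = K_by_term.to_numpy()
    k = k_by_term.reindex(terms, fill_value=0).to_numpy()
    # P(X >= k) for X ~ Hypergeometric(N, K, n)
    p = sps.hypergeom.sf(k - 1, N, K, n)
    p = np.minimum(p, 1.0)
    out = pd.DataFrame({"term": terms, "k": k, "n": n, "K": K, "N": N,
                        "pvalue": p}).reset_index(drop=True)
    out["qvalue"] = benjamini_hochberg(out["pvalue"].to_numpy())
    return out.sort_values("pvalue").reset_index(drop=True)
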