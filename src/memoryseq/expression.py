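"""Expression normalization and differential-expression screening.

The screen follows the common RNA-seq recipe for a two-group comparison with
few replicates: median-ratio library-size normalization, pooling of scaled
replicate counts, and an exact conditional count test per gene.  With
dispersion 0 the test conditions on the pooled gene total and reduces to a
two-sided exact binomial test; with dispersion alpha > 0 the conditional
distribution of the group-A total given the pooled total is computed from
negative-binomial point probabilities (variance mu + alpha*mu^2), and the
two-sided p sums all outcomes no more probable than the observed one.
Genes pass the screen when |log2 fold change| exceeds the fold-change cut
and the Benjamini-Hochberg q-value is below the FDR cut.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import REL_TIE, benjamini_hochberg

UNCHANGED, UP, DOWN = "unchanged", "up", "down"


@dataclass
class ExpressionTable:
    """Gene-by-sample abundance matrix with sample metadata.

    counts   : DataFrame indexed by gene id, one column per sample.
    lengths  : Series of gene lengths in bp (same index as counts).
    samples  : DataFrame indexed by sample name with columns
               ``condition`` and ``replicate``.
    """

    counts: pd.DataFrame
    lengths: pd.Series
    samples: pd.DataFrame
    is_fpkm: bool = field(default=False)

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("abundances must be non-negative")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        if not self.lengths.index.equals(self.counts.index):
            self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            raise ValueError("every gene needs a length")
        if (self.lengths <= 0).any():
            raise ValueError("gene lengths must be positive")

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for s in self.counts.columns:
            c = self.samples.loc[s, "condition"]
            if c not in seen:
                seen.append(c)
        return seen

    def samples_for(self, condition: str) -> list[str]:
        sel = self.samples["condition"] == condition
        return [s for s in self.counts.columns if sel.get(s, False)]

    def fpkm(self, library_sizes=None, robust: bool = False) -> pd.DataFrame:
        """FPKM normalization.

        With ``robust=True`` the library sizes are median-of-ratios effective
        sizes (scaled to the geometric mean of the raw totals) instead of raw
        column sums, which keeps cross-condition ratios unbiased when a
        sizeable fraction of genes changes in one direction.
        """
        if self.is_fpkm:
            return self.counts
        if robust and library_sizes is None:
            totals = self.counts.sum(axis=0).astype(float)
            sf = median_ratio_size_factors(self.counts)
            library_sizes = sf * float(np.exp(np.mean(np.log(totals))))
        return compute_fpkm(self.counts, self.lengths, library_sizes)

    def condition_means(self, values: pd.DataFrame | None = None) -> pd.DataFrame:
        """Replicate-averaged abundance per condition (columns in first-seen order)."""
        v = self.counts if values is None else values
        out = {c: v[self.samples_for(c)].mean(axis=1) for c in self.conditions}
        return pd.DataFrame(out)


def compute_fpkm(counts: pd.DataFrame, gene_lengths: pd.Series,
                 library_sizes=None) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped fragments.

    fpkm = count / (length/1e3) / (library_size/1e6).  Library sizes default
    to column sums of the count matrix.
    """
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        raise ValueError("missing gene length")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    library_sizes = pd.Series(library_sizes, index=counts.columns, dtype=float)
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    kb = lengths.to_numpy(dtype=float)[:, None] / 1e3
    per_million = library_sizes.to_numpy(dtype=float)[None, :] / 1e6
    return pd.DataFrame(counts.to_numpy(dtype=float) / kb / per_million,
                        index=counts.index, columns=counts.columns)


def median_ratio_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (reference = geometric mean gene profile).

    Falls back to total-count scaling when no gene is expressed everywhere.
    """
    x = counts.to_numpy(dtype=float)
    positive = (x > 0).all(axis=1)
    if positive.sum() >= 10:
        logx = np.log(x[positive])
        ref = logx.mean(axis=1, keepdims=True)
        sf = np.exp(np.median(logx - ref, axis=0))
    else:
        totals = x.sum(axis=0)
        sf = totals / np.exp(np.mean(np.log(totals)))
    return pd.Series(sf, index=counts.columns)


def estimate_dispersion(counts: pd.DataFrame, groups: pd.Series,
                        size_factors: pd.Series | None = None) -> float:
    """Common NB dispersion by a ratio-of-sums moment estimator.

    For scaled counts y with group mean m and variance s^2 (per gene, per
    group with >=2 replicates), E[s^2 - m] = alpha * mu^2 and
    E[m^2 - s^2/n] = mu^2, so alpha is estimated as
    sum(s^2 - m) / sum(m^2 - s^2/n), clipped at 0.
    """
    if size_factors is None:
        size_factors = median_ratio_size_factors(counts)
    y = counts / size_factors
    num = 0.0
    den = 0.0
    for _, cols in groups.groupby(groups).groups.items():
        cols = [c for c in cols if c in y.columns]
        if len(cols) < 2:
            continue
        sub = y[cols].to_numpy(dtype=float)
        m = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        num += float(np.sum(s2 - m))
        den += float(np.sum(m * m - s2 / len(cols)))
    if den <= 0:
        return 0.0
    return max(0.0, num / den)


def exact_count_test(counts_group_a, counts_group_b, dispersion: float = 0.0,
                     size_factors_a=None, size_factors_b=None,
                     pseudocount: float = 1.0):
    """Exact conditional two-group count test for a single gene.

    Returns ``(p, log2fc, testable)`` where log2fc = log2 of the (pseudo-
    counted) normalized mean of group B over group A, so swapping the groups
    negates it.  Replicates are scaled by their size factors and pooled;
    the pooled totals are compared conditionally on their sum.
    """
    a = np.asarray(counts_group_a, dtype=float)
    b = np.asarray(counts_group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("each group needs at least one replicate")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    sfa = np.ones(a.size) if size_factors_a is None else np.asarray(size_factors_a, float)
    sfb = np.ones(b.size) if size_factors_b is None else np.asarray(size_factors_b, float)
    ya = float(np.sum(a / sfa))
    yb = float(np.sum(b / sfb))
    mean_a = ya / a.size
    mean_b = yb / b.size
    log2fc = float(np.log2((mean_b + pseudocount) / (mean_a + pseudocount)))
    ka, kb = int(round(ya)), int(round(yb))
    n = ka + kb
    if n == 0:
        return 1.0, 0.0, False
    p = _conditional_two_sided_p(ka, n, a.size, b.size, dispersion)
    return p, log2fc, True


def _conditional_two_sided_p(ka: int, n: int, na: int, nb: int,
                             dispersion: float) -> float:
    """Two-sided p for group-A total ka given pooled total n.

    dispersion == 0: A | A+B=n ~ Binomial(n, na/(na+nb)); otherwise the
    conditional pmf is proportional to NB(k; na/alpha, q) NB(n-k; nb/alpha, q)
    with a common success parameter q (equal per-replicate null mean).
    """
    k = np.arange(n + 1)
    if dispersion == 0:
        logpmf = sps.binom.logpmf(k, n, na / (na + nb))
    else:
        r_a = na / dispersion
        r_b = nb / dispersion
        mu = n / (na + nb)  # per-replicate null mean
        q = (1.0 / dispersion) / (1.0 / dispersion + mu)
        logpmf = sps.nbinom.logpmf(k, r_a, q) + sps.nbinom.logpmf(n - k, r_b, q)
    pmf = np.exp(logpmf - logpmf.max())
    pmf /= pmf.sum()
    obs = pmf[ka]
    return float(min(1.0, pmf[pmf <= obs * REL_TIE].sum()))


def screen_deg(results: pd.DataFrame, fc_threshold: float = 1.0,
               fdr_threshold: float = 0.05) -> pd.Series:
    """Assign up/down/unchanged from log2fc and q columns."""
    lfc = results["log2fc"]
    q = results["qvalue"]
    status = pd.Series(UNCHANGED, index=results.index, dtype=object)
    status[(lfc > fc_threshold) & (q < fdr_threshold)] = UP
    status[(lfc < -fc_threshold) & (q < fdr_threshold)] = DOWN
    return status


def parse_contrast(contrast) -> tuple[str, str]:
    """'S1:R0' or ('S1','R0') -> (target, reference), i.e. S1 vs R0."""
    if isinstance(contrast, str):
        if ":" in contrast:
            tgt, ref = contrast.split(":", 1)
        elif "_vs_" in contrast:
            tgt, ref = contrast.split("_vs_", 1)
        else:
            raise ValueError(f"cannot parse contrast {contrast!r}")
        return tgt, ref
    tgt, ref = contrast
    return tgt, ref


def test_contrast(table: ExpressionTable, contrast, dispersion: float | None = None,
                  fc_threshold: float = 1.0, fdr_threshold: float = 0.05,
                  pseudocount: float = 1.0) -> pd.DataFrame:
    """Run the exact count screen for one condition pair (target vs reference).

    Returns a per-gene DataFrame with log2fc, pvalue, qvalue (BH within this
    contrast), status and a ``testable`` flag (all-zero genes are untestable
    and reported with p=1, log2fc=0).
    """
    target, reference = parse_contrast(contrast)
    cols_ref = table.samples_for(reference)
    cols_tgt = table.samples_for(target)
    if not cols_ref or not cols_tgt:
        raise ValueError(f"contrast {target} vs {reference}: condition missing samples")
    sub = table.counts[cols_ref + cols_tgt]
    sf = median_ratio_size_factors(sub)
    if dispersion is None:
        groups = table.samples.loc[sub.columns, "condition"]
        dispersion = estimate_dispersion(sub, groups, sf)
    sfa = sf[cols_ref].to_numpy()
    sfb = sf[cols_tgt].to_numpy()
    genes = sub.index
    p = np.empty(len(genes))
    lfc = np.empty(len(genes))
    testable = np.empty(len(genes), dtype=bool)
    ref_counts = sub[cols_ref].to_numpy(dtype=float)
    tgt_counts = sub[cols_tgt].to_numpy(dtype=float)
    for i in range(len(genes)):
        p[i], lfc[i], testable[i] = exact_count_test(
            ref_counts[i], tgt_counts[i], dispersion,
            size_factors_a=sfa, size_factors_b=sfb, pseudocount=pseudocount)
    q = benjamini_hochberg(p)
    out = pd.DataFrame({
        "log2fc": lfc, "pvalue": p, "qvalue": q, "testable": testable,
    }, index=genes)
    out["status"] = screen_deg(out, fc_threshold, fdr_threshold)
    out.loc[~out["testable"], "status"] = UNCHANGED
    out.attrs["contrast"] = f"{target}_vs_{reference}"
    out.attrs["dispersion"] = float(dispersion)
    return out


def run_contrasts(table: ExpressionTable, contrasts,
                  dispersion: float | None = None,
                  fc_threshold: float = 1.0,
                  fdr_threshold: float = 0.05) -> dict[str, pd.DataFrame]:
    """Screen several contrasts; keys are normalized '<target>_vs_<ref>' names."""
    out: dict[str, pd.DataFrame] = {}
    for c in contrasts:
        tgt, ref = parse_contrast(c)
        out[f"{tgt}_vs_{ref}"] = test_contrast(
            table, (tgt, ref), dispersion=dispersion,
            fc_threshold=fc_threshold, fdr_threshold=fdr_threshold)
    return out


def default_contrasts(conditions) -> list[tuple[str, str]]:
    """Responsiveness contrasts (each later condition vs baseline) plus the
    memory contrasts (each post-first-stress condition vs first stress)."""
    conditions = list(conditions)
    if len(conditions) < 3:
        raise ValueError("need at least baseline, first stress, one later condition")
    baseline, first = conditions[0], conditions[1]
    out = [(c, baseline) for c in conditions[1:]]
    out += [(c, first) for c in conditions[2:]]
    return out
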