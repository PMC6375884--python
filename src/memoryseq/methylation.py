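"""Sliding-window differential-methylation (DMR) calling.

Per-cytosine methylated/unmethylated counts from two conditions are pooled
(both strands) into 200 bp windows sliding every 50 bp, separately per
sequence context (CG, CHG, CHH).  Each covered window is tested with a
two-sided Fisher exact test on the pooled 2x2 count table, p-values are
Benjamini-Hochberg corrected within context, and significant windows
(p <= 0.05 and q <= 0.05 by default) of the same context and direction are
merged (overlapping or bookended) into DMRs.

Coordinates are 0-based half-open internally; cytosine reports use 1-based
positions and are converted on read.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import benjamini_hochberg, fisher_exact_two_sided

CONTEXTS = ("CG", "CHG", "CHH")
CYTOSINE_COLUMNS = ["chrom", "pos", "strand", "meth", "unmeth", "context"]


def validate_cytosines(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(CYTOSINE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cytosine table missing columns: {sorted(missing)}")
    if (df["meth"] < 0).any() or (df["unmeth"] < 0).any():
        raise ValueError("counts must be non-negative")
    bad = set(df["context"].unique()) - set(CONTEXTS)
    if bad:
        raise ValueError(f"unknown contexts: {sorted(bad)}")
    return df


def make_windows(chrom_length: int, window: int = 200, step: int = 50) -> np.ndarray:
    """Sliding-window intervals [k*step, k*step+window) with start < length;
    the final window is truncated at the chromosome end.

    Returns an (n, 2) integer array of 0-based half-open intervals.
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    if window < step:
        raise ValueError("window must be >= step")
    if chrom_length <= 0:
        raise ValueError("chromosome length must be positive")
    starts = np.arange(0, chrom_length, step)
    ends = np.minimum(starts + window, chrom_length)
    return np.column_stack([starts, ends])


def pool_window(cytosines: pd.DataFrame, interval, context: str) -> tuple[int, int, bool]:
    """Pooled (meth, unmeth) counts of matching-context cytosines in one
    0-based half-open interval; both strands pooled.  ``covered`` is False
    when the window holds no cytosine of that context."""
    start, end = interval
    sub = cytosines[(cytosines["context"] == context)
                    & (cytosines["pos"] > start) & (cytosines["pos"] <= end)]
    if len(sub) == 0:
        return 0, 0, False
    return int(sub["meth"].sum()), int(sub["unmeth"].sum()), True


def _window_sums(pos: np.ndarray, values: np.ndarray, windows: np.ndarray) -> np.ndarray:
    """Sum of ``values`` at sorted 1-based positions p with start < p <= end
    for every window, via cumulative sums."""
    csum = np.concatenate([[0], np.cumsum(values)])
    lo = np.searchsorted(pos, windows[:, 0] + 1, side="left")
    hi = np.searchsorted(pos, windows[:, 1], side="right")
    return csum[hi] - csum[lo]


def pool_windows(cytosines_a: pd.DataFrame, cytosines_b: pd.DataFrame,
                 window: int = 200, step: int = 50,
                 chrom_lengths: dict[str, int] | None = None) -> pd.DataFrame:
    """Window-level pooled counts for two conditions, per chromosome and
    context.  Chromosome lengths default to the maximum observed position."""
    validate_cytosines(cytosines_a)
    validate_cytosines(cytosines_b)
    chroms = sorted(set(cytosines_a["chrom"]) | set(cytosines_b["chrom"]))
    rows = []
    for chrom in chroms:
        sub_a = cytosines_a[cytosines_a["chrom"] == chrom]
        sub_b = cytosines_b[cytosines_b["chrom"] == chrom]
        if chrom_lengths and chrom in chrom_lengths:
            length = chrom_lengths[chrom]
        else:
            length = int(max(sub_a["pos"].max() if len(sub_a) else 0,
                             sub_b["pos"].max() if len(sub_b) else 0))
        if length <= 0:
            continue
        wins = make_windows(length, window, step)
        for context in CONTEXTS:
            ca = sub_a[sub_a["context"] == context].sort_values("pos")
            cb = sub_b[sub_b["context"] == context].sort_values("pos")
            if len(ca) == 0 and len(cb) == 0:
                continue
            pos_a = ca["pos"].to_numpy()
            pos_b = cb["pos"].to_numpy()
            meth_a = _window_sums(pos_a, ca["meth"].to_numpy(float), wins)
            unmeth_a = _window_sums(pos_a, ca["unmeth"].to_numpy(float), wins)
            meth_b = _window_sums(pos_b, cb["meth"].to_numpy(float), wins)
            unmeth_b = _window_sums(pos_b, cb["unmeth"].to_numpy(float), wins)
            n_cyt = (_window_sums(pos_a, np.ones(len(ca)), wins)
                     + _window_sums(pos_b, np.ones(len(cb)), wins))
            df = pd.DataFrame({
                "chrom": chrom,
                "start": wins[:, 0], "end": wins[:, 1],
                "context": context,
                "meth_a": meth_a.astype(int), "unmeth_a": unmeth_a.astype(int),
                "meth_b": meth_b.astype(int), "unmeth_b": unmeth_b.astype(int),
                "covered": n_cyt > 0,
            })
            rows.append(df)
    if not rows:
        return pd.DataFrame(columns=["chrom", "start", "end", "context",
                                     "meth_a", "unmeth_a", "meth_b", "unmeth_b",
                                     "covered"])
    out = pd.concat(rows, ignore_index=True)
    cov_a = out["meth_a"] + out["unmeth_a"]
    cov_b = out["meth_b"] + out["unmeth_b"]
    with np.errstate(invalid="ignore", divide="ignore"):
        out["level_a"] = np.where(cov_a > 0, out["meth_a"] / cov_a, np.nan)
        out["level_b"] = np.where(cov_b > 0, out["meth_b"] / cov_b, np.nan)
    return out


def test_windows(pooled: pd.DataFrame, min_coverage: int = 5) -> pd.DataFrame:
    """Fisher-test covered windows and BH-correct within each context.

    Windows with total coverage below ``min_coverage`` in either condition
    are flagged untestable and excluded from the correction.
    """
    out = pooled.copy()
    cov_a = out["meth_a"] + out["unmeth_a"]
    cov_b = out["meth_b"] + out["unmeth_b"]
    out["testable"] = out["covered"] & (cov_a >= min_coverage) & (cov_b >= min_coverage)
    p = np.full(len(out), np.nan)
    idx = np.flatnonzero(out["testable"].to_numpy())
    ma = out["meth_a"].to_numpy()
    ua = out["unmeth_a"].to_numpy()
    mb = out["meth_b"].to_numpy()
    ub = out["unmeth_b"].to_numpy()
    for i in idx:
        p[i] = fisher_exact_two_sided(((ma[i], ua[i]), (mb[i], ub[i])))
    out["pvalue"] = p
    out["qvalue"] = np.nan
    for context in out["context"].unique():
        mask = (out["context"] == context) & out["testable"]
        if mask.any():
            out.loc[mask, "qvalue"] = benjamini_hochberg(out.loc[mask, "pvalue"].to_numpy())
    diff = out["level_b"] - out["level_a"]
    out["direction"] = np.where(diff > 0, "hyper", "hypo")
    out.loc[~out["testable"], "direction"] = "none"
    return out


def _refine_cluster(starts, ends, full_stack: int) -> tuple[int, int]:
    """Median-stack boundary estimate for one cluster of significant windows.

    A sliding design covers every interior base with window/step overlapping
    windows, so a merged cluster overhangs the underlying differential region
    by up to window-step on each side.  The refined extent keeps the bases
    supported by at least d = min(window/step, ceil((k+1)/2)) of the k
    significant windows, which for equal-width windows is simply
    [d-th smallest start, d-th largest end).  Falls back to the plain union
    when the stack never reaches depth d (scattered, barely-chained windows).
    """
    k = len(starts)
    d = min(full_stack, (k + 2) // 2)  # ceil((k+1)/2)
    d = max(1, d)
    s = sorted(starts)
    e = sorted(ends)
    lo, hi = s[d - 1], e[k - d]
    if lo >= hi:
        return s[0], e[-1]
    return lo, hi


def merge_windows(sig: pd.DataFrame, boundary: str = "stack",
                  full_stack: int = 4) -> pd.DataFrame:
    """Merge overlapping/bookended significant windows of the same chromosome,
    context and direction into DMRs.

    boundary="union" reports the plain union of the merged windows;
    boundary="stack" (default) trims each cluster to the median-stack extent
    (see ``_refine_cluster``), correcting the systematic overhang of
    overlapping significant windows.  ``full_stack`` is window/step.
    """
    if boundary not in ("stack", "union"):
        raise ValueError("boundary must be 'stack' or 'union'")
    cols = ["chrom", "start", "end", "context", "direction",
            "n_windows", "min_q", "mean_diff"]
    if len(sig) == 0:
        out = pd.DataFrame(columns=["dmr_id", *cols])
        return out
    sig = sig.sort_values(["chrom", "context", "direction", "start", "end"])
    clusters = []
    cur = None
    for rec in sig.itertuples(index=False):
        if (cur is not None and rec.chrom == cur["chrom"]
                and rec.context == cur["context"]
                and rec.direction == cur["direction"]
                and rec.start <= max(cur["ends"])):
            cur["starts"].append(int(rec.start))
            cur["ends"].append(int(rec.end))
            cur["qs"].append(rec.qvalue)
            cur["diffs"].append(rec.level_b - rec.level_a)
        else:
            if cur is not None:
                clusters.append(cur)
            cur = {"chrom": rec.chrom, "context": rec.context,
                   "direction": rec.direction, "starts": [int(rec.start)],
                   "ends": [int(rec.end)], "qs": [rec.qvalue],
                   "diffs": [rec.level_b - rec.level_a]}
    clusters.append(cur)
    rows = []
    for c in clusters:
        if boundary == "stack":
            start, end = _refine_cluster(c["starts"], c["ends"], full_stack)
        else:
            start, end = min(c["starts"]), max(c["ends"])
        rows.append({"chrom": c["chrom"], "start": start, "end": end,
                     "context": c["context"], "direction": c["direction"],
                     "n_windows": len(c["starts"]), "min_q": min(c["qs"]),
                     "mean_diff": float(np.mean(c["diffs"]))})
    out = pd.DataFrame(rows, columns=cols)
    out = out.sort_values(["chrom", "start", "end", "context"]).reset_index(drop=True)
    out.index.name = "dmr_id"
    return out.reset_index()


def call_dmrs(window_stats: pd.DataFrame, p_cut: float = 0.05,
              q_cut: float = 0.05, merge: bool = True,
              boundary: str = "stack", min_windows: int = 2,
              window: int = 200, step: int = 50) -> pd.DataFrame:
    """Significant windows -> merged DMRs.

    A window is significant when testable, p <= p_cut and q <= q_cut; with
    ``merge=False`` each significant window becomes its own DMR, otherwise
    overlapping/bookended same-context same-direction windows are merged and
    their extent refined per ``boundary`` (see ``merge_windows``).  DMRs must
    be supported by at least ``min_windows`` significant windows (window-level
    FDR control does not control the region-level false-discovery rate;
    isolated single-window clusters are dominated by such false discoveries).
    """
    sig = window_stats[window_stats["testable"]
                       & (window_stats["pvalue"] <= p_cut)
                       & (window_stats["qvalue"] <= q_cut)].copy()
    if not merge:
        out = sig[["chrom", "start", "end", "context", "direction"]].copy()
        out["n_windows"] = 1
        out["min_q"] = sig["qvalue"].to_numpy()
        out["mean_diff"] = (sig["level_b"] - sig["level_a"]).to_numpy()
        out = out.sort_values(["chrom", "start", "end", "context"]).reset_index(drop=True)
        out.index.name = "dmr_id"
        return out.reset_index()
    merged = merge_windows(sig, boundary=boundary,
                           full_stack=max(1, window // step))
    merged = merged[merged["n_windows"] >= min_windows].reset_index(drop=True)
    merged["dmr_id"] = np.arange(len(merged))
    return merged


def dmr_analysis(cytosines_a: pd.DataFrame, cytosines_b: pd.DataFrame,
                 window: int = 200, step: int = 50, min_coverage: int = 5,
                 p_cut: float = 0.05, q_cut: float = 0.05,
                 chrom_lengths: dict[str, int] | None = None):
    """Convenience wrapper: pooled windows -> tests -> DMRs.

    Returns ``(window_stats, dmrs)``.
    """
    pooled = pool_windows(cytosines_a, cytosines_b, window, step, chrom_lengths)
    stats = test_windows(pooled, min_coverage=min_coverage)
    dmrs = call_dmrs(stats, p_cut=p_cut, q_cut=q_cut, window=window, step=step)
    return stats, dmrs
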