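"""Synthetic expression and methylome data with planted ground truth.

The expression simulator emulates the repeated drought / re-watering design:
four conditions (baseline R0, first stress S1, late re-watering R3, late
stress S4) with three biological replicates each.  Each gene follows one of
the enumerated unit-change trajectory profiles (or stays flat); its mean
count in condition t is baseline_mean * 2^(effect_size * value_t), and
replicate counts are negative-binomial with variance mu + alpha*mu^2
(alpha = 0 degenerates to Poisson).  Dosage-class genes have value 0 at the
first stress, so their R0 and S1 count distributions are identical by
construction.

The methylome simulator draws per-cytosine methylated/unmethylated counts in
CG/CHG/CHH contexts at Poisson read depth around context-specific baseline
levels, and plants disjoint differentially methylated windows in which the
second condition's level is shifted by a configured delta.

The linkage simulator couples planted DMRs to planted genes: a linked DMR's
per-sample methylation level is an affine function of the gene's per-sample
log2(FPKM+1) with a configured sign, plus optional noise; unlinked DMRs get
independent level noise.  All randomness flows from one seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionTable
from .profiles import categorize_values, enumerate_profiles

FLAT_SHAPE = -1

DEFAULT_CONDITIONS = ("R0", "S1", "R3", "S4")

#: Default planted mixture: 60% flat background plus an even spread over
#: representative memory shapes (lineage 25, accumulated 22, stable 21/24,
#: initial 18/7, dosage 13/15) under canonical numbering.
DEFAULT_MIXTURE = {
    FLAT_SHAPE: 0.60,
    25: 0.05, 22: 0.05, 21: 0.05, 24: 0.05,
    18: 0.05, 7: 0.05, 13: 0.05, 15: 0.05,
}


@dataclass
class SimulationConfig:
    """Expression-simulation parameters (defaults mirror the study design)."""

    n_genes: int = 2000
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    n_replicates: int = 3
    profile_mixture: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_MIXTURE))
    effect_size: float = 2.0        # log2 units per unit profile step
    baseline_mean: float = 100.0    # mean count of an unchanged gene
    nb_dispersion: float = 0.05     # alpha in var = mu + alpha*mu^2; 0 => Poisson
    length_range: tuple[float, float] = (500.0, 5000.0)  # log-uniform gene lengths, bp
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_replicates <= 0:
            raise ValueError("n_genes and n_replicates must be positive")
        if len(self.conditions) < 2:
            raise ValueError("need at least two conditions")
        if self.baseline_mean < 0 or self.nb_dispersion < 0:
            raise ValueError("baseline_mean and nb_dispersion must be >= 0")
        total = sum(self.profile_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"profile_mixture must sum to 1 (got {total})")
        if any(f < 0 for f in self.profile_mixture.values()):
            raise ValueError("mixture fractions must be non-negative")
        n_profiles = (2 * 1 + 1) ** (len(self.conditions) - 1) - 1
        for sid in self.profile_mixture:
            if sid != FLAT_SHAPE and not (0 <= sid < n_profiles):
                raise ValueError(f"unknown shape id {sid}")


def _mixture_counts(mixture: dict[int, float], n: int) -> dict[int, int]:
    """Deterministic largest-remainder apportionment of n genes to shapes."""
    ids = sorted(mixture)
    exact = np.array([mixture[i] * n for i in ids])
    base = np.floor(exact).astype(int)
    rem = exact - base
    short = n - base.sum()
    for i in np.argsort(-rem, kind="mergesort")[:short]:
        base[i] += 1
    return {i: int(c) for i, c in zip(ids, base)}


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mu, alpha) with var = mu + alpha*mu^2; alpha = 0 => Poisson."""
    if alpha == 0:
        return rng.poisson(mean)
    r = 1.0 / alpha
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_expression(config: SimulationConfig) -> tuple[ExpressionTable, pd.DataFrame]:
    """Simulate a count matrix plus its per-gene ground truth.

    Ground-truth columns: shape_id (-1 for flat), value_<cond> (planted unit
    values), mean_<cond> (planted condition means), is_memory, category.
    Memory truth: a non-flat gene whose value at any post-first-stress
    condition differs from its value at the first stress.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    T = len(config.conditions)
    profiles = {p.id: p for p in enumerate_profiles(T)}
    counts_by_shape = _mixture_counts(config.profile_mixture, config.n_genes)

    shape_ids = np.concatenate([
        np.full(c, sid, dtype=int) for sid, c in counts_by_shape.items()
    ])
    rng.shuffle(shape_ids)
    gene_ids = [f"gene{g:05d}" for g in range(config.n_genes)]

    values = np.zeros((config.n_genes, T), dtype=int)
    for i, sid in enumerate(shape_ids):
        if sid != FLAT_SHAPE:
            values[i] = profiles[sid].values
    means = config.baseline_mean * np.power(2.0, config.effect_size * values)

    lo, hi = config.length_range
    lengths = np.exp(rng.uniform(np.log(lo), np.log(hi), size=config.n_genes))
    lengths = np.round(lengths).astype(int)

    sample_names = [f"{c}_{r}" for c in config.conditions
                    for r in range(1, config.n_replicates + 1)]
    counts = np.empty((config.n_genes, len(sample_names)), dtype=np.int64)
    col = 0
    for t in range(T):
        for _ in range(config.n_replicates):
            counts[:, col] = _nb_draw(rng, means[:, t], config.nb_dispersion)
            col += 1

    samples = pd.DataFrame({
        "condition": [s.rsplit("_", 1)[0] for s in sample_names],
        "replicate": [int(s.rsplit("_", 1)[1]) for s in sample_names],
    }, index=pd.Index(sample_names, name="sample"))
    table = ExpressionTable(
        counts=pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                            columns=sample_names),
        lengths=pd.Series(lengths, index=gene_ids, name="length"),
        samples=samples,
    )

    truth = pd.DataFrame({"shape_id": shape_ids},
                         index=pd.Index(gene_ids, name="gene_id"))
    for t, cond in enumerate(config.conditions):
        truth[f"value_{cond}"] = values[:, t]
        truth[f"mean_{cond}"] = means[:, t]
    nonflat = shape_ids != FLAT_SHAPE
    differs_later = (values[:, 2:] != values[:, [1]]).any(axis=1) if T > 2 \
        else np.zeros(config.n_genes, dtype=bool)
    truth["is_memory"] = nonflat & differs_later
    truth["category"] = [
        "non-memory" if not mem else categorize_values(v)
        for mem, v in zip(truth["is_memory"], values)
    ]
    return table, truth


@dataclass
class MethylomeSimConfig:
    """Methylome-simulation parameters for a two-condition comparison."""

    genome_length: int = 200_000
    chrom: str = "chr1"
    # densities follow the rice genome's base composition (~43% GC):
    # roughly 1 CG per 11 bp, 1 CHG per 14 bp, 1 CHH per 4 bp (both strands)
    n_cytosines_per_context: dict[str, int] = field(
        default_factory=lambda: {"CG": 18_000, "CHG": 14_000, "CHH": 50_000})
    depth_mean: float = 30.0
    baseline_level: dict[str, float] = field(
        default_factory=lambda: {"CG": 0.6, "CHG": 0.3, "CHH": 0.1})
    n_dmrs: int = 40
    dmr_delta: float = 0.3
    dmr_width: int = 200
    grid: int = 50                  # planted boundaries align to this grid
    seed: int = 0

    def validate(self) -> None:
        if self.genome_length <= 0 or self.depth_mean < 0:
            raise ValueError("genome_length must be positive, depth_mean >= 0")
        if self.dmr_width > self.genome_length:
            raise ValueError("dmr_width exceeds genome_length")
        if self.dmr_width <= 0 or self.grid <= 0:
            raise ValueError("dmr_width and grid must be positive")
        if self.n_dmrs < 0 or self.dmr_delta < 0:
            raise ValueError("n_dmrs and dmr_delta must be >= 0")
        for ctx, level in self.baseline_level.items():
            if not 0 <= level <= 1:
                raise ValueError(f"baseline level for {ctx} outside [0, 1]")
            feasible = (level + self.dmr_delta <= 1) or (level - self.dmr_delta >= 0)
            if self.n_dmrs and self.dmr_delta > 0 and not feasible:
                raise ValueError(f"dmr_delta {self.dmr_delta} infeasible for "
                                 f"{ctx} baseline {level}")
        if self.n_dmrs:
            seg = self.genome_length // self.n_dmrs
            if seg < self.dmr_width + 4 * self.grid:
                raise ValueError("genome too short for that many disjoint DMRs")


def _place_dmrs(cfg: MethylomeSimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Disjoint grid-aligned planted windows, one per genome segment,
    with context cycling over CG/CHG/CHH and a feasible direction."""
    contexts = [c for c in ("CG", "CHG", "CHH") if cfg.n_cytosines_per_context.get(c, 0) > 0]
    rows = []
    seg = cfg.genome_length // cfg.n_dmrs if cfg.n_dmrs else 0
    for i in range(cfg.n_dmrs):
        lo_slot = (i * seg) // cfg.grid + 1
        hi_slot = ((i + 1) * seg - cfg.dmr_width) // cfg.grid - 1
        start = int(rng.integers(lo_slot, hi_slot + 1)) * cfg.grid
        ctx = contexts[i % len(contexts)]
        base = cfg.baseline_level[ctx]
        can_hyper = base + cfg.dmr_delta <= 1
        can_hypo = base - cfg.dmr_delta >= 0
        if can_hyper and can_hypo:
            direction = "hyper" if rng.random() < 0.5 else "hypo"
        else:
            direction = "hyper" if can_hyper else "hypo"
        rows.append({"dmr_id": i, "chrom": cfg.chrom, "start": start,
                     "end": start + cfg.dmr_width, "context": ctx,
                     "direction": direction,
                     "delta": cfg.dmr_delta if direction == "hyper" else -cfg.dmr_delta})
    return pd.DataFrame(rows, columns=["dmr_id", "chrom", "start", "end",
                                       "context", "direction", "delta"])


def simulate_methylome(config: MethylomeSimConfig):
    """Per-cytosine counts for two conditions plus planted-DMR ground truth.

    Returns ``(cytosines_a, cytosines_b, dmr_truth)``; cytosine tables have
    1-based positions, alternating strands, and binomial methylated counts at
    Poisson depth.  Condition B's level is shifted by +/- dmr_delta inside
    planted windows of the matching context.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = _place_dmrs(config, rng)

    frames_a, frames_b = [], []
    for ctx in ("CG", "CHG", "CHH"):
        n = config.n_cytosines_per_context.get(ctx, 0)
        if n == 0:
            continue
        if n > config.genome_length:
            raise ValueError(f"more {ctx} cytosines than genome positions")
        pos = np.sort(rng.choice(config.genome_length, size=n, replace=False)) + 1
        strand = np.where(np.arange(n) % 2 == 0, "+", "-")
        level_a = np.full(n, config.baseline_level[ctx])
        level_b = level_a.copy()
        for rec in truth[truth["context"] == ctx].itertuples(index=False):
            inside = (pos > rec.start) & (pos <= rec.end)
            level_b[inside] = np.clip(level_a[inside] + rec.delta, 0.0, 1.0)
        for levels, frames in ((level_a, frames_a), (level_b, frames_b)):
            depth = rng.poisson(config.depth_mean, size=n)
            meth = rng.binomial(depth, levels)
            frames.append(pd.DataFrame({
                "chrom": config.chrom, "pos": pos, "strand": strand,
                "meth": meth, "unmeth": depth - meth, "context": ctx,
            }))
    empty = pd.DataFrame(columns=["chrom", "pos", "strand", "meth", "unmeth", "context"])
    cyt_a = pd.concat(frames_a, ignore_index=True) if frames_a else empty
    cyt_b = pd.concat(frames_b, ignore_index=True) if frames_b else empty.copy()
    cyt_a = cyt_a.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    cyt_b = cyt_b.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return cyt_a, cyt_b, truth


@dataclass
class LinkageSimConfig:
    """Coupling between planted DMRs and planted genes."""

    linked_fraction: float = 0.8
    link_sign: int = -1             # -1: methylation represses expression
    noise_sd: float = 0.0           # level noise for linked DMRs
    unlinked_sd: float = 0.05       # iid level noise for unlinked DMRs
    baseline: float = 0.5
    amplitude: float = 0.25         # max |level shift| driven by expression
    gene_chrom: str = "chr2"        # where unlinked genes are placed
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.linked_fraction <= 1:
            raise ValueError("linked_fraction must be in [0, 1]")
        if self.link_sign not in (-1, 1):
            raise ValueError("link_sign must be +1 or -1")
        if self.noise_sd < 0 or self.unlinked_sd < 0:
            raise ValueError("noise sds must be >= 0")
        if not 0 < self.baseline < 1 or self.amplitude < 0:
            raise ValueError("baseline in (0,1), amplitude >= 0 required")
        if self.baseline - self.amplitude < 0 or self.baseline + self.amplitude > 1:
            raise ValueError("baseline +/- amplitude must stay inside [0, 1]")


def simulate_linkage(table: ExpressionTable, expr_truth: pd.DataFrame,
                     dmr_truth: pd.DataFrame,
                     config: LinkageSimConfig | None = None):
    """Couple planted DMRs to planted memory genes across the sample axis.

    For each linked pair the DMR's per-sample methylation level is
    baseline + amplitude * link_sign * z(log2(FPKM+1)) + noise, where z is
    the max-normalized centered log-expression, so with noise_sd = 0 the
    across-sample Pearson correlation is exactly link_sign.  Unlinked DMRs
    receive independent Gaussian level noise.

    Returns ``(levels, gene_models, links)``:
    levels      : DataFrame dmr_id x sample of methylation levels.
    gene_models : BED-like DataFrame (gene_id, chrom, start, end, strand);
                  linked genes sit just downstream of their DMR so the DMR
                  falls in the promoter zone.
    links       : DataFrame dmr_id, gene_id (empty for unlinked), true_sign.
    """
    cfg = config or LinkageSimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    samples = list(table.counts.columns)
    fpkm = table.fpkm()
    logx = np.log2(fpkm + 1.0)

    memory_genes = expr_truth.index[expr_truth["is_memory"]].tolist()
    pool = memory_genes if memory_genes else list(table.counts.index)
    n_dmrs = len(dmr_truth)
    n_linked = int(round(cfg.linked_fraction * n_dmrs))
    n_linked = min(n_linked, len(pool))
    linked_dmrs = dmr_truth["dmr_id"].to_numpy()[:n_linked]
    chosen = rng.choice(np.array(pool, dtype=object), size=n_linked, replace=False)

    levels = np.empty((n_dmrs, len(samples)))
    link_rows = []
    gene_rows = []
    gene_by_dmr = dict(zip(linked_dmrs, chosen))
    for i, rec in enumerate(dmr_truth.itertuples(index=False)):
        if rec.dmr_id in gene_by_dmr:
            g = gene_by_dmr[rec.dmr_id]
            x = logx.loc[g, samples].to_numpy(dtype=float)
            xc = x - x.mean()
            scale = np.abs(xc).max()
            z = xc / scale if scale > 0 else np.zeros_like(xc)
            lv = (cfg.baseline + cfg.amplitude * cfg.link_sign * z
                  + rng.normal(0.0, cfg.noise_sd, size=len(samples)))
            link_rows.append({"dmr_id": rec.dmr_id, "gene_id": g,
                              "true_sign": cfg.link_sign})
            gene_rows.append({"gene_id": g, "chrom": rec.chrom,
                              "start": int(rec.end) + 100,
                              "end": int(rec.end) + 100 + int(min(
                                  table.lengths[g], 2000)),
                              "strand": "+"})
        else:
            lv = cfg.baseline + rng.normal(0.0, cfg.unlinked_sd, size=len(samples))
            link_rows.append({"dmr_id": rec.dmr_id, "gene_id": "",
                              "true_sign": 0})
        levels[i] = np.clip(lv, 0.0, 1.0)

    placed = {r["gene_id"] for r in gene_rows}
    cursor = 0
    for g in table.counts.index:
        if g in placed:
            continue
        length = int(min(table.lengths[g], 2000))
        gene_rows.append({"gene_id": g, "chrom": cfg.gene_chrom,
                          "start": cursor, "end": cursor + length, "strand":
                          "+" if cursor // 1000 % 2 == 0 else "-"})
        cursor += length + 500

    levels_df = pd.DataFrame(levels, index=pd.Index(dmr_truth["dmr_id"], name="dmr_id"),
                             columns=samples)
    gene_models = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "start",
                                                   "end", "strand"])
    links = pd.DataFrame(link_rows, columns=["dmr_id", "gene_id", "true_sign"])
    return levels_df, gene_models, links
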