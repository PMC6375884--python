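# Methods

This note documents the statistical procedures implemented in `memoryseq`,
the defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions.

## Study design and vocabulary

The package targets repeated-stress ("stress memory") designs: an untreated
control (R0), a first drought (S1), and later conditions sampled after
further drought/re-watering cycles (a late re-watering R3 and a late drought
S4), each with biological replicates (three by default). A **memory gene** is
a stress-responsive gene whose transcript level at R3 or S4 differs
significantly from its level at the first stress S1 — i.e. the response to a
repeated stress is not a replay of the first response.

## Differential expression

`exact_count_test` is an exact conditional two-group count test:

- Library sizes are normalized by **median-of-ratios** size factors
  (reference = per-gene geometric mean across samples; fallback to
  total-count scaling when too few genes are expressed everywhere).
- Scaled replicate counts are **pooled** per group and the group-A total is
  tested conditionally on the pooled total. With dispersion α = 0 the
  conditional law is Binomial(n, n_a/(n_a+n_b)) — the classic exact binomial
  two-sample Poisson comparison. With α > 0 the conditional probability mass
  is proportional to NB(k; n_a/α, q)·NB(n−k; n_b/α, q) with a common success
  parameter (the negative-binomial model with variance μ + αμ²; α = 0
  degenerates to Poisson). Two-sided p-values sum all outcomes whose point
  probability does not exceed the observed one (relative tie tolerance
  1 + 1e-7).
- The common dispersion is estimated by a **ratio-of-sums moment estimator**,
  α̂ = Σ(s² − m) / Σ(m² − s²/n) over genes and groups with ≥ 2 replicates.
  Per-gene moment estimates with three replicates are extremely noisy and
  their median is biased low (the variance estimate is roughly χ²₂-scaled),
  which would make the screen anticonservative; the ratio-of-sums form is
  consistent and stable. On simulated NB data with α = 0.05 the null
  rejection rate at p < 0.05 is 0.043–0.047 (slightly conservative, as
  expected for a discrete exact test).
- log₂ fold changes are computed on normalized group means with pseudocount 1
  (finite for genes silent in one condition); swapping groups negates the
  fold change and leaves p unchanged. Genes with zero counts in both groups
  are reported untestable (p = 1, log₂FC = 0).
- **Benjamini–Hochberg** adjustment is applied within each contrast; a gene
  is up/down when |log₂FC| > 1 and q < 0.05 (both thresholds configurable).

The screen runs on counts. FPKM (count / (length/10³) / (library/10⁶)) is
provided for reporting and for trajectory shapes; `ExpressionTable.fpkm`
accepts explicit library sizes, and `robust=True` replaces raw column sums
with median-of-ratios effective sizes. The robust variant is used for
trajectory classification because raw column-sum normalization suffers
composition bias when a sizeable fraction of genes changes in one direction
— in simulations with ~40% strongly induced genes it corrupted
cross-condition ratios badly enough to scramble profile assignment.

## Trajectory profiles and memory categories

Candidate trajectories are all step vectors over {−c, …, +c}^(T−1) with the
flat vector excluded; c = 1 and T = 4 give 3³ − 1 = 26 profiles. Profiles
are numbered canonically by the lexicographic rank of the step vector
(−1 < 0 < +1) with the flat slot removed, so id 0 is (−1,−1,−1) and id 25 is
(+1,+1,+1).

Per gene, replicate-averaged robust-FPKM condition means are transformed to
log-ratios against the first condition, v_t = log₂((x_t+1)/(x_0+1)), and the
gene is assigned the profile whose cumulative value vector maximizes the
centered Pearson correlation (scale-invariant, so the unit of the planted
effect does not matter). Ties break toward the lower id; all-zero
trajectories are unassignable. No permutation-based profile significance is
computed — assignment is purely nearest-profile.

The memory flag is DE-based: responsive in at least one contrast against R0,
and different from S1 at R3 or S4 (rule `any`; `all` requires both). An
explicit 16-profile membership preset (`PAPER_MEMORY_PROFILES`,
`flag_memory_by_profiles`) is also shipped for users who want the curated
profile-list definition instead of the DE-derived one; the two agree on
clearly shaped genes but are not identical by construction.

Memory categories are shape predicates on the profile values (0, v₁, …):

| category    | predicate                                            | example |
|-------------|------------------------------------------------------|---------|
| dosage      | v₁ = 0 (no response to the first stress)             | (0,0,1,2) |
| initial     | v₁ ≠ 0 and all later values back at 0                | (0,1,0,0) |
| lineage     | strictly monotone in one direction                   | (0,1,2,3) |
| stable      | monotone in one direction, final transition flat     | (0,1,2,2) |
| accumulated | monotone with an interior hold, then a further step  | (0,1,1,2) |
| other-memory| any other shape, or memory gene without a profile    | (0,1,−1,0) |

These predicates are direction-symmetric (a falling lineage is still
lineage). They partition the 26 profiles, and genes not flagged as memory are
`non-memory` regardless of shape.

## DMR calling

Per-cytosine methylated/unmethylated counts (1-based positions, Bismark-like
cytosine-report dialect) are pooled, both strands together, into sliding
windows of 200 bp every 50 bp (0-based half-open internally; a 1-based
position p belongs to window [s, e) iff s < p ≤ e). Contexts (CG, CHG, CHH)
are kept separate throughout. Windows with pooled coverage below 5 reads in
either condition are excluded — Fisher's test on near-empty tables is
uninformative. Each remaining window's 2×2 table is tested with a two-sided
Fisher exact test (hypergeometric point-mass summation; verified against
exhaustive enumeration for all tables with margins ≤ 30), and BH correction
is applied within context. Windows with p ≤ 0.05 and q ≤ 0.05 are
significant; direction is the sign of the level difference.

**Region extent.** Overlapping or bookended significant windows of the same
chromosome, context and direction are merged into one DMR. Because a sliding
design covers every base with window/step = 4 overlapping windows, windows
that only partially overlap a truly differential region are themselves often
significant, so the plain union of a merged cluster systematically overhangs
the true region by up to window − step on each side. The default boundary
rule therefore trims each cluster to its **median-stack extent**: the bases
supported by at least d = min(window/step, ⌈(k+1)/2⌉) of the cluster's k
significant windows, which for equal-width windows is simply the d-th
smallest start to the d-th largest end. In the high-power limit (all
overlapping windows significant) this recovers the true region exactly; with
moderate power the boundary error is at most one step. `boundary="union"`
restores the plain union. DMRs must additionally be supported by at least two
significant windows (`min_windows=2`): window-level BH does not control the
region-level false-discovery rate, and isolated single-window clusters are
dominated by false discoveries.

## Methylation–expression linkage

DMRs are paired with genes whose body or strand-aware promoter (2 kb upstream
of the TSS by default) they overlap; a downstream flank can be enabled with
`downstream_bp` (0 by default, since body + promoter is the default pairing
rule). Zone priority is body > promoter > downstream. Each DMR–gene pair is
scored independently by the Pearson correlation, across the shared sample
axis, of the DMR's per-sample methylation level against the gene's per-sample
log₂(FPKM+1). A pair is **linked** when r > +0.04 or r < −0.04. These
permissive defaults follow the source study verbatim; note that with 12
samples ~90% of independent pairs exceed |r| = 0.04 by chance, so for real
analyses a conventional threshold such as |r| > 0.4 (`pos_thr`/`neg_thr`) is
recommended. Constant vectors have undefined correlation and are never
linked. Which libraries form the sample axis is a free choice of the user;
the pipeline uses all condition × replicate samples and requires a per-sample
DMR level matrix (two pooled WGBS libraries alone cannot support a
correlation, so in simulation mode the coupled generator supplies it).

Term enrichment is a generic upper-tail hypergeometric test per term with BH
across terms — a deliberate reduction of web-tool GO/KEGG pipelines to their
statistical core (no DAG propagation or pathway topology).

## Physiology

RWC = (FW−DW)/(RW−DW)·100% (requires RW > DW) and Fv/Fm = (Fm−F0)/Fm
(requires Fm > 0). Values outside [0, 100]% or [0, 1] are reported with a
warning, never clipped — measurement error should be visible. Steady-state
fluorescence Fs is carried through unused.

## Synthetic data

All randomness flows from one seeded `numpy` generator per simulation; the
same config and seed reproduce outputs bit for bit.

**Expression.** Each gene draws a trajectory shape from a configured mixture
(default: 60% flat plus 5% each of eight representative shapes — lineage 25,
accumulated 22, stable 21/24, initial 18/7, dosage 13/15). Condition means
are baseline·2^(effect·value); replicates are NB(μ, α) with variance μ + αμ².
Defaults — three replicates, baseline mean 100, effect 2 log₂-units per step,
α = 0.05 — represent a well-powered bulk RNA-seq experiment with clear
stress responses; the replicate-level dispersion is implementer-chosen (no
replicate-level estimate was available to copy) and config-exposed. Gene
lengths are log-uniform on 500–5000 bp so FPKM normalization is non-trivial.
Dosage-class genes have identical R0 and S1 distributions by construction.

**Methylome.** Cytosine positions are uniform per context with alternating
strands; densities default to the rice genome's base composition (~43% GC:
roughly one CG per 11 bp, one CHG per 14 bp, one CHH per 4 bp counting both
strands). Baseline levels default to CG 0.6, CHG 0.3, CHH 0.1 — typical
plant leaf methylomes. Read depth is Poisson (mean 30) and methylated counts
binomial. Planted DMRs are disjoint, grid-aligned 200 bp windows (one per
genome segment, contexts cycling, direction random among feasible ones) in
which condition B's level shifts by ±delta (default 0.3).

**Coupling.** A configured fraction of planted DMRs (default 0.8) is tied to
planted memory genes: the DMR's per-sample level is
baseline + amplitude·sign·z(log₂(FPKM+1)) + Gaussian noise, with amplitude
0.25 around baseline 0.5 so the noise-free case stays strictly inside [0, 1]
and the across-sample correlation is exactly ±1. Unlinked DMRs receive
independent Gaussian level noise (sd 0.05). Linked genes are placed just
downstream of their DMR (promoter zone); all other genes go to a separate
chromosome so no spurious associations arise.

**What the generator does not emulate** — and hence what passing tests do not
establish about real data: read-level sampling and mapping artefacts,
bisulfite conversion error, clustered/autocorrelated cytosine spacing and
methylation levels, gene-length or GC biases in counting, batch effects,
replicate-level methylomes, lncRNA-specific features, and any coupling
mechanism beyond a monotone affine link. Recovery rates measured on these
simulations are upper bounds for messier real data.

## Numerical conventions and problem sizes

- Ties in two-sided exact tests use a relative tolerance of 1 + 1e-7 on point
  probabilities; profile-assignment ties break toward the lower profile id.
- BH is computed by the step-up recursion on a stable mergesort order;
  q ≥ p elementwise and q is monotone in p.
- Zero-margin Fisher tables and all-zero genes are untestable (p = 1), never
  errors; empty windows are flagged uncovered and skipped.
- The shipped test suite exercises the full stack at deliberately modest
  sizes — a few hundred to 5000 genes, 200 kb genomes with ~80k cytosines,
  40 planted DMRs — chosen so the statistical assertions (null rates within
  ±0.01, recovery rates with planted effects) have adequate Monte-Carlo
  resolution while the whole suite runs in well under a minute per module.

## Known limitations

- The exact NB test uses a plug-in common dispersion; no per-gene empirical
  Bayes moderation. Strong per-gene dispersion heterogeneity will make the
  screen mildly miscalibrated.
- Profile assignment ignores within-condition variance (replicate means
  only), so low-expression genes with noisy means can be assigned confidently
  wrong shapes; the correlation column should be consulted.
- DMR boundaries are step-quantized; the median-stack refinement assumes a
  roughly symmetric significance stack and can misplace a boundary by more
  than one step when cytosines are locally very sparse.
- The linkage stage requires a per-sample methylation level matrix; it does
  not estimate per-sample levels from two pooled libraries.
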