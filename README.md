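# memoryseq

Analysis toolkit for **drought stress memory** in plant transcriptomes and
methylomes. When plants experience repeated cycles of mild drought and
re-watering, many genes respond differently to a later stress than they did to
the first one — a transcriptional "memory" of the earlier exposure. Given
expression data from a repeated-stress design (untreated control R0, first
drought S1, a later re-watering R3 and a later drought S4, with replicates)
plus whole-genome bisulfite counts, `memoryseq`:

1. screens **differentially expressed genes** between condition pairs with an
   exact conditional count test (|log₂FC| > 1 and BH FDR < 0.05 by default);
2. classifies each gene's condition trajectory into one of the **26
   unit-change profiles** (all step vectors in {−1, 0, +1}³ over the three
   transitions, flat excluded) by maximal Pearson correlation, flags **memory
   genes** (stress-responsive genes whose R3 or S4 level differs significantly
   from S1) and sorts them into **memory categories** — dosage, initial,
   stable, accumulated, lineage;
3. calls **differentially methylated regions** (DMRs) from per-cytosine
   CG/CHG/CHH counts with the sliding-window Fisher procedure (200 bp windows
   every 50 bp, BH within context, significant windows merged);
4. **links methylation to expression**: DMRs are paired with genes they overlap
   (gene body or 2 kb strand-aware promoter) and scored by the Pearson
   correlation of per-sample methylation level against log₂(FPKM+1);
5. computes the drought-physiology indices **RWC** = (FW−DW)/(RW−DW)·100% and
   **Fv/Fm** = (Fm−F0)/Fm.

A first-class synthetic-data module simulates all of these inputs with planted
ground truth (negative-binomial count trajectories following chosen profile
shapes, binomial bisulfite counts with planted DMRs, and DMR–gene couplings
with a configured sign), so every stage is testable end to end without
external data.

It is aimed at plant molecular biologists and bioinformaticians analysing
repeated-stress (priming / stress-memory) experiments in rice or similar
species.

## Worked example

Everything below runs from scratch in a few seconds — the data are simulated
with planted truth:

```python
import memoryseq as m

table, truth = m.simulate_expression(m.SimulationConfig(n_genes=1000, seed=4))
de = m.run_contrasts(table, m.default_contrasts(table.conditions))
for name, res in de.items():
    print(f"{name}: {(res['status']=='up').sum()} up, {(res['status']=='down').sum()} down")

cls = m.classify_genes(table, de)
print(f"memory genes: {int(cls['is_memory'].sum())} of {len(cls)}")
print(cls.loc[cls['is_memory'], 'category'].value_counts().sort_index().to_string())

ca, cb, dtruth = m.simulate_methylome(m.MethylomeSimConfig(seed=5))
stats, dmrs = m.dmr_analysis(ca, cb)
print(f"DMRs: {len(dmrs)} (planted {len(dtruth)})")
```

which prints:

```
S1_vs_R0: 250 up, 51 down
R3_vs_R0: 249 up, 1 down
S4_vs_R0: 299 up, 4 down
R3_vs_S1: 199 up, 52 down
S4_vs_S1: 297 up, 54 down
memory genes: 352 of 1000
category
accumulated     49
dosage          97
initial         98
lineage         51
other-memory     4
stable          53
DMRs: 43 (planted 40)
```

The five DE lines are the responsiveness contrasts (each treatment vs the R0
control) and the two memory contrasts (R3 and S4 vs the first stress S1). Of
1000 simulated genes, 400 were planted with non-flat trajectories and 352 are
recovered as memory genes; the category table splits them by trajectory shape
(e.g. *dosage* genes did not respond to the first drought but changed after
repeated cycles; *lineage* genes rise monotonically across cycles). The DMR
caller recovers the 40 planted 200 bp regions (43 calls, including a small
number of false or split regions at the 5% FDR).

The same stages are available from the shell:

```bash
memoryseq simulate --outdir sim --n-genes 1000 --seed 4
memoryseq de --expression sim/expression.tsv --samples sim/samples.tsv \
             --contrast S1:R0 --contrast S4:S1 --outdir de
memoryseq dmr --cytosines-a sim/cytosines_a.tsv --cytosines-b sim/cytosines_b.tsv
memoryseq run --simulate --seed 4 --outdir run   # full pipeline + summary.json
```

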