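# heteroseq

Transcriptome analysis of **heterosis** (hybrid vigor) in
female-parent / male-parent / F1-hybrid trios, built for diallel crossing
designs such as a 4 × 4 Chinese cabbage panel (16 hybrids, three
biological replicates per material).

Heterosis studies ask why an F1 outperforms its parents. At the
transcriptome level the standard decomposition compares each gene's
expression in the hybrid against both parents and bins differentially
expressed genes (DEGs) into twelve patterns:

* **additive** (P1–P2) — hybrid expression strictly between the parents
  (`M < H < F` or `F < H < M`, all three pairwise comparisons significant),
* **dominant** (P3–P6) — hybrid statistically indistinguishable from one
  parent and different from the other (`H = M` with `F ≠ M`, or `H = F`),
* **over-dominant** (P7–P12) — hybrid above or below *both* parents.

Here `X = Y` means the pairwise test is not significant and `X < Y` means
it is significant with group-mean FPKMs in that order. Alongside the
pattern decomposition the package computes:

* **pairwise DE** per trio (F-vs-M, F-vs-H, M-vs-H): Welch *t* on
  log2(FPKM+1) (or a negative-binomial Wald test on counts), with
  Benjamini–Hochberg FDR and the per-trio DEG ratio
  `100·|FM ∩ (FH ∪ MH)|/|FM|`,
* **mid-parent heterosis** of a trait such as plant gross weight (PGW):
  `MPV = 100·(F1 − MP)/MP` with `MP = (P♀ + P♂)/2`, grading hybrids into
  strong (MPV > 140), weak (MPV < 40) and middle groups,
* **group-common DEGs** (Venn intersections across the hybrids of a
  heterosis group) and **hypergeometric term enrichment**
  (`p = P(X ≥ k)`, `X ~ Hypergeom(N, K, n)`, BH-adjusted),
* **weighted coexpression modules**: unsigned adjacency `|cor|^β`
  (β = 11), topological overlap, average-linkage module detection
  (minimum module size 50), module eigengenes and eigengene–trait
  correlation — either on raw expression or on the per-hybrid
  mid-parent-heterosis transform of expression,
* a **seeded negative-binomial simulator** that plants patterns, trait
  heterosis and coexpression modules with full truth tables, so the whole
  pipeline is testable without external data.

## Worked example

```python
from heteroseq.simulate import SimulationConfig, simulate_trio_counts, counts_to_fpkm
from heteroseq import de, patterns, heterosis

cfg = SimulationConfig(n_genes=1000, seed=4)        # 4x4 diallel, 3 replicates
counts, samples, design, truth = simulate_trio_counts(cfg)
fpkm = counts_to_fpkm(counts)

tabs = de.trio_de(fpkm, samples, "A", "E", "AE")    # the A x E trio
table = patterns.classify_trio(tabs["fm"], tabs["fh"], tabs["mh"])
cnt, pct = patterns.summarize_patterns(table)
print(pct.round(2).to_string())
```

```
category
additive          9.01
dominant         83.85
over-dominant     7.14
```

Of the 331 DEGs of this simulated trio, 83.85% classify as dominant —
the simulator's default pattern mix mirrors a published cabbage diallel
in which dominant expression was the major mode. Trait heterosis from
the simulated plant-gross-weight table:

```python
het = heterosis.heterosis_table(truth.line_traits, design)
print(het.round(2).head(4).to_string())
```

```
          F1    MP     MPV   group
hybrid
AE      6.11  2.82  116.63  middle
AF      3.63  3.16   15.17    weak
AG      5.00  2.89   73.21  middle
AH      8.71  3.26  167.63  strong
```

`AH`'s F1 weighs 8.71 against a mid-parent mean of 3.26, an MPV of
167.63% — above the 140 cutoff, hence a strong-heterosis combination.

The same analysis is available from the shell:

```bash
heteroseq simulate --n-genes 2000 --seed 4 --out sim/
heteroseq de --expr sim/fpkm.tsv --samples sim/samples.tsv --design sim/design.tsv --out de/
heteroseq classify --de de/ --design sim/design.tsv --out patterns/
heteroseq heterosis --traits sim/traits.tsv --design sim/design.tsv --out het.tsv
heteroseq run --out full/ --seed 4        # everything end to end
```

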