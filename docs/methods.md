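# Methods

## Trio expression patterns

For each hybrid the package forms three pairwise comparisons — female
vs. male parent (FM), female vs. hybrid (FH), male vs. hybrid (MH) — and
describes each gene by a relation triple: "=" when the comparison is not
significant at the configured FDR, "<"/">" when it is significant with
the group-mean FPKMs in that order. Twelve patterns partition the
consistent triples (see the table in `heteroseq.patterns`): P1–P2
additive, P3–P6 dominant, P7–P12 over-dominant. Two conventions are
worth making explicit, because the pattern definitions as usually quoted
leave them open:

* **Classified universe.** Genes significant in *at least one* of the
  three comparisons are classified (the union of the three DEG sets).
  Restricting to parent–parent DEGs would make P7 and P10 — which
  require a *non-significant* FM — unreachable.
* **Implied third relation.** Some pattern definitions state only two of
  the three relations; the implied third (e.g. P3's `F < M` with `H = M`
  forces `F < H`) is enforced so the patterns are mutually exclusive.
  Triples matching no pattern — internally contradictory calls, and the
  ambiguous cases where the hybrid is indistinguishable from both
  parents while the parents differ — are reported as `unclassified`,
  never force-fitted.

Per-hybrid summaries report counts per pattern and category percentages
over classified genes. The cross-hybrid summary row uses the arithmetic
mean rounded half away from zero and the population standard deviation
(n divisor) over √n reported to two decimals; these conventions exactly
reproduce the published summary rows of the bundled 16-hybrid table, and
were confirmed by recomputation from its count rows.

## Differential expression

The default test is Welch's unequal-variance *t* on log2(FPKM+1) with
Benjamini–Hochberg adjustment and a DEG call at FDR ≤ 0.05. This is a
deliberate, documented choice of a simple, exactly testable test; count
models (DESeq2-style NB GLMs with dispersion shrinkage) are out of
scope, but a per-gene negative-binomial Wald test (moment estimate of
the dispersion, delta-method variance of the log-mean contrast) is
available as `method="nb"` for count input. Genes with zero variance in
both groups get p = 1 when means agree and p = 0 otherwise. The
pseudo-expression ε = 1 is used in both the log transform and the
log2 fold change `log2((mean_B+ε)/(mean_A+ε))`.

The published protocol states the DEG threshold once as FDR ≤ 0.05 and
once as adjusted p < 0.01; 0.05 is the default here and the threshold is
a single configuration knob (`--fdr`).

FPKM conversion is `counts · 10⁹ / (length_bp · library_size)`, with
library sizes defaulting to column sums when true mapped totals are
unknown. Group means are arithmetic means of FPKM across replicates.
Replicate QC reports Pearson correlations of log2(FPKM+1) for all sample
pairs plus the minimum within-material replicate correlation.

## Mid-parent heterosis

`MPV = 100 · (F1 − MP)/MP`, `MP = (P♀ + P♂)/2`, requires MP > 0 and is
invariant to rescaling the trait's unit. Grouping uses strict
inequalities — MPV > 140 strong, MPV < 40 weak, otherwise middle — so
the boundary values fall in the middle group; both cutoffs are
configurable. Replicate-level trait rows are averaged per line before
the formula. For group-common DEGs the per-hybrid set defaults to
FH ∪ MH (genes differential between the hybrid and either parent), with
`fh | mh | union | fm` selectable since the published analysis does not
pin the definition.

## Enrichment

One-sided hypergeometric over-representation against flat term/gene-set
annotations (GMT or two-column TSV), BH-adjusted, significant at
adjusted p < 0.05. The population universe defaults to all genes tested
for DE — not the genome — and is configurable. No ontology-graph
propagation and no gene-length bias correction: annotations are taken
as given.

## Coexpression modules

Unsigned weighted network: `a_ij = |cor(x_i, x_j)|^β` with β = 11,
topological overlap
`TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij)`, and
average-linkage hierarchical clustering on 1 − TOM. Instead of dynamic
tree cutting, a fixed-height cut (default 0.95) is used, followed by
merging modules whose eigengenes correlate above 0.8; this is a
documented simplification, so absolute module *counts* are not
comparable to dynamic-tree-cut results, while planted-module recovery
is (adjusted Rand ≥ 0.9 on two-module simulations at noise sd 0.3, 24
samples). Clusters below the minimum size (default 50) are left
unassigned. The module eigengene is the first principal component of
the gene-standardized module submatrix, unit-norm, sign-oriented to
correlate positively with member genes on average; module–trait
association is Pearson r with a two-sided t test (df = n − 2),
significant at p < 0.05.

Two input modes: `raw` correlates per-sample expression with the
per-sample trait; `mpv` first transforms expression to per-hybrid
mid-parent heterosis values (`100·(H − MP)/MP` on line-mean FPKMs,
genes with MP = 0 dropped) and correlates against the MPV of the trait.
Whether a real analysis feeds replicate samples or line means into the
raw mode is a user decision; both are accepted.

## Synthetic data generator

The generator emulates the diallel study design: 4 female × 4 male
inbred lines, 16 hybrids, 3 replicates, ~72 libraries. Counts are
negative binomial with variance μ + αμ²; α defaults to 0.01
(biological CV 0.1, the standard figure for genetically identical
material — appropriate for inbred lines and F1s with pooled sampling).
Library sizes are log-uniform over 5–15 million, gene lengths uniform
over 500–5000 bp, per-gene baseline counts log-normal around 300, which
puts median FPKM near 15. Planted patterns fix the (female, male,
hybrid) mean triple exactly — "=" is exact equality, "<" spans
`parent_log2fc` (default 2) between parents and `hybrid_log2fc` beyond
the parental range, additive hybrids sit at the geometric midpoint — and
the same triple applies to every trio (all female lines share the
planted female level). The default pattern mix is 70% null genes with
the signal fraction split across P1–P12 in proportion to the published
per-pattern averages. The trait generator gives parents ~N(3, 0.3) kg
and plants hybrid MPVs in strong/middle/weak bands (4/8/4 hybrids), so
grouping is recoverable by construction. A separate Gaussian
latent-factor generator plants coexpression modules
(`loading·factor + noise`) and a trait correlated with the first
module's factor.

What the simulator deliberately does **not** model: batch effects,
line-specific expression divergence between same-role lines,
GC/length-dependent biases, outlier replicates, and trio-specific
patterns (a gene shows one pattern in all 16 trios). Passing tests
therefore demonstrate the pipeline's correctness and statistical
calibration under the stated noise model, not robustness to every
artifact of real RNA-seq.

## Numerical and scale choices

* Degenerate inputs: zero-variance genes are removed (network) or
  flagged (heatmap export, p = 1 rules in DE); empty parent-vs-parent
  DEG sets make the DEG ratio an error rather than a silent 0/0.
* Determinism: every stochastic step flows from a single integer seed;
  module labels are size-ranked with deterministic tie-breaks, and
  enrichment ranking breaks ties lexicographically by term id.
* Test problem sizes (hundreds to a couple thousand genes, 3 trios for
  recovery measurements, 8–20 seeds for sampling properties) were chosen
  so the full suite exercises every stage end-to-end while remaining
  quick to run; recovery rates at these sizes are stable to ~1–2
  percentage points across seeds.
* The published per-hybrid pattern counts and mid-parent heterosis
  values ship as package data; they are inputs (the study's printed
  results), and the raw parental trait values behind the published MPVs
  are not available, so MPVs are consumed, not recomputed.

## Known limitations

The Welch default ignores count overdispersion structure that dedicated
NB frameworks model, so absolute DEG counts will differ from DESeq2-based
analyses even at the same threshold. The fixed-height tree cut trades
the adaptive resolution of dynamic tree cutting for exact
reproducibility. Enrichment assumes exchangeable genes (no length bias).
The pattern classifier is threshold-sharp: genes near the significance
boundary can flip patterns between neighboring categories under
resampling.
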