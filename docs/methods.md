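# Methods

## The screen

The pipeline consumes a differential-expression (DE) summary table — it
never fits DE models. The screen proceeds in four steps:

1. **Selection.** The downregulated pathway set is
   `{g ∈ pathway ∩ universe : p_adj(g) < alpha_select, log2FC(g) < 0}`,
   with `alpha_select = 0.1` by default and a *strict* inequality. Its size
   is D; the DE table's row count is the universe size N.
2. **Enrichment.** For each miRNA, M = |targets ∩ universe| and
   O = |targets ∩ downregulated|; targets absent from the DE table count for
   neither, because the hypergeometric model draws from the genes analyzed.
   The p-value is the upper tail P(X ≥ O) of Hypergeometric(N, D, M).
3. **Adjustment.** Across all retained miRNAs (those with at least
   `min_targets = 10` targets in the universe, the conventional retention
   filter for conserved-family exports). The method is Benjamini–Hochberg;
   it is configurable (`holm`, `bonferroni`) because the screening context —
   many weakly dependent discrete tests — is exactly where BH is the field
   default but not the only defensible choice.
4. **Network.** miRNAs with adjusted p ≤ `alpha_network = 0.05` (inclusive)
   become nodes of a bipartite graph, each connected to the downregulated
   genes inside its target set. Gene nodes carry log2FC and adjusted p.
   An empty network is a legitimate outcome, not an error; a miRNA whose
   overlap is empty never appears as an isolated node.

The asymmetry of the two thresholds (strict `< 0.1` for selection, inclusive
`≤ 0.05` for the network) is deliberate and matches the screen this package
operationalizes.

## Numerical evaluation of the tail

All binomial coefficients are computed as log-gamma differences and the tail
sum (at most `min(M, D) − O + 1` terms) via log-sum-exp, then exponentiated
and clipped to [0, 1]. Naive factorials overflow long before N = 16,000;
the log-space route keeps every intermediate bounded. Two independent
checks constrain the implementation: exhaustive subset enumeration for all
3,184 valid (N ≤ 12, M, D, O) tuples (≤ 1e-12 absolute) and
`scipy.stats.hypergeom.sf` at transcriptome scale (≤ 1e-10 relative).
O = 0 short-circuits to exactly 1.0. Invalid count configurations
(O > min(M, D), M > N, D > N) raise rather than return a value.

Ranking is fully deterministic: ascending adjusted p, then raw p, then
descending O, then miRNA id. Rerunning the CLI on identical inputs produces
byte-identical tables; results are written at %.17g so a read-back is exact
(the reader forces pandas' round-trip float parser, since its default parser
is off by one ulp).

## Duplicate and missing data policy

Duplicate gene ids in a DE table keep the row with the smallest adjusted p
(ties: smallest raw p, then first occurrence) and log a warning. A missing
p-value is an error, not a silent drop. Gene symbols are canonicalized by
strip+uppercase only; alias and ortholog mapping are version-dependent and
out of scope, so inputs must share a symbol namespace.

## Seed-site taxonomy

The seed is mature-miRNA positions 2–8. A site is any UTR occurrence of the
reverse complement of positions 2–7 (the 6mer core), classified at the
longest applicable type: 8mer (core + position-8 match + adenosine opposite
position 1), 7mer-m8 (core + position-8 match), 7mer-A1 (core + A1
adenosine), else 6mer. The A1 base is a literal A in the UTR regardless of
the miRNA's first nucleotide, per the canonical site definitions. Only the
given strand is scanned; `N` never matches; coordinates are 0-based
half-open over the full reported match (a CLI flag converts to 1-based).
Conservation scoring, context scores and 3'-supplementary pairing are out of
scope. The scanner is validated against a brute-force sliding-window matcher
on random sequences.

## Concordance

Cross-dataset agreement is the Pearson correlation of log2 fold changes over
the pathway genes shared by each pair of DE tables (Spearman available as an
option). Genes missing from either table are pairwise-deleted; a pair
sharing fewer than 3 genes is reported as missing rather than correlated.
The companion gene × dataset fold-change table feeds any heatmap tool; no
figure rendering or batch correction is attempted.

## Synthetic data: what it emulates and what it does not

`SyntheticScenario` defaults describe a liver-transcriptome-scale screen:
16,000 genes, a 50-gene pathway with 17 planted downregulated members, 353
miRNAs with target-set sizes uniform on [10, 400], one driver miRNA whose
set is forced (by size-preserving swap-in) to contain exactly 8 planted
genes. Planted genes draw log2FC from Normal(−1.5, 0.3) and background from
Normal(0, 0.3); with these values a planted gene sits about five noise
standard deviations from null, so nearly all survive BH at 0.1 in a
16,000-gene universe — emulating a strongly and coherently downregulated
pathway. Raw p-values come from the known-variance two-sided z-test, making
adjusted p-values exactly reconstructible.

What the generator deliberately does not model: count-level noise and
mean–variance coupling of real RNA-seq, correlated expression between genes,
biased target-set composition (real conserved-target sets favor long, highly
expressed 3'UTRs), and shared targets between related miRNA families.
Passing recovery and calibration tests therefore demonstrates that the
*procedure* is correct and well-calibrated under its own assumptions — not
that any particular real-data screen is free of confounding.

Replicate r of an experiment reuses the generator with seed
`base_seed + r`, so any replicate is reproducible in isolation. Recovery
experiments report the fraction of replicates ranking a driver first (and
within the top ten) and the mean false-discovery proportion among calls at
adjusted p ≤ 0.05; replicates where no gene passes selection (possible at
weak effect sizes) are excluded and counted. Under a no-driver null the raw
p-values are stochastically conservative because the hypergeometric test is
discrete; calibration tests assert exceedance ≤ α plus three Monte-Carlo
standard errors.

## Problem sizes in the test and acceptance runs

The test suite runs the full-scale recovery experiment at 200 replicates and
the null calibration at 500 replicates (about a minute total); unit tests
use a scaled scenario (800 genes, 40 miRNAs) chosen to keep per-test cost
low while preserving all structural properties. The acceptance script runs
the enumeration oracle up to N = 10, 200 recovery and 500 null replicates,
500 random UTRs, 100 Pearson pairs and 50 network round trips.

## Known limitations

- Symbol-based matching only; inputs from different annotation eras can
  silently shrink M and D.
- BH assumes positive-regression dependence; target sets of related miRNA
  families overlap, which BH tolerates in practice but no proof covers.
- The network carries no edge weights (e.g. context scores); it encodes
  membership only.
- Consensus intersection treats all prediction sources as equally reliable.
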