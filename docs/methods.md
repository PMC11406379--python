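# Methods

## Scope and model

`taxafunc` re-implements, as an offline and fully testable library, the
analytical core of a metatranscriptomic profiling workflow that starts from
per-read protein-level taxonomic classifications (Kaiju-style verbose TSV)
and produces:

1. **species abundance profiles** — strain/below-species assignments are
   rolled up to the nearest ancestor of rank `species`; reads at or above
   genus rank, unclassified reads and unknown taxids are excluded and
   tallied so that every input read is accounted for;
2. **GO functional profiles** — tied best protein matches share a read
   (1/k each), accession counts are annotated from an accession→GO store
   and closed over `is_a`/`part_of` ancestors as a *set* (no path is
   double-counted), and percentages are computed within each GO namespace;
3. **differential statistics** — TMM normalization, a two-group
   negative-binomial exact test with common dispersion, BH adjustment,
   TPM conversion and preranked GSEA;
4. **host–microbe correlation** — average-rank Spearman rho between top
   differentially expressed host genes (TPM) and differentially abundant
   microbes (percent abundance), with average-linkage clustering of the
   rho matrix for heatmap ordering.

## Species tables

Percent abundance divides each species' count by the sample's total
species-mapped reads (×100), so per-sample columns sum to 100 before
filtering. The low-abundance filter (default 0.001%) drops a species only
when it is below threshold in *every* sample, and the original percentages
are deliberately not recomputed afterwards — retained rows therefore sum to
slightly less than 100. Removed species are written to a separate table for
audit. Group tables are arithmetic means of per-sample percentages.
"Strain level" is interpreted structurally: any node strictly below a
species node rolls up, regardless of its rank string, because rank labels
in real dumps are inconsistent (`strain`, `subspecies`, `no rank`).

## Accession→GO store

Non-redundant protein databases compile identical sequences into one entry
and classifiers report only the entry's first (representative) accession.
The store therefore unions, for each representative, the GO annotations of
*all* member accessions (member → UniProt id → GO term). Rows whose GAF
qualifier contains `NOT` are excluded (they assert absence of function);
all evidence codes are accepted by default with an opt-in exclusion flag.
Representatives with no reachable annotation are absent from the store and
queries for them return the empty set; lookups are exact-string (version
suffix included), because the store is keyed by the classifier's emitted
accession. The store persists either as a single-file sqlite database or a
sorted two-column TSV; both load identically.

## GO propagation and percentages

Only `is_a` and `part_of` edges are used; other relationship types are
ignored at parse time. Alternate ids resolve to their primary term;
obsolete terms encountered at annotation time are dropped with a tally (no
`replaced_by` chasing). Because the closure is a set, a term reached by
several paths (diamonds) is counted exactly once, which makes the
aggregated count of a parent always ≥ that of any child. Protein percent
scaling uses a *global* denominator (all species-mapped reads of the
sample, the same denominator as the taxonomy table); this makes the
namespace percentages invariant to that choice, since they renormalize
within each namespace anyway. Group-level GO tables average the
proportional protein counts across a group's samples *first* and annotate
afterwards. Cross tables (GO→taxa, taxa→GO) are two views of one pair set
and report whole-species group percent abundances, not the share
contributed by the term's proteins.

## Differential statistics

Counts in sample *j* are modelled as NB with mean μ·N_j and common
dispersion φ (variance μ + φμ²; φ = 0 is Poisson). Effective library sizes
are library × TMM factor. Samples are brought to a common effective size
by linear scaling to the geometric-mean effective library; group
pseudo-sums are rounded to the nearest integer before the exact test.
(Full quantile-to-quantile NB equalization was not reproduced; with equal
libraries — the regime all enumeration oracles run in — the two coincide
exactly.) The two-sided exact p-value conditions on a feature's total and
sums the probabilities of all splits whose conditional probability does
not exceed the observed one; with φ = 0 and group sizes (n₁, n₂) this
conditional law is Binomial(total, n₁/(n₁+n₂)), which the test suite
checks exhaustively for all totals ≤ 50 to 1e-10. The common φ is
estimated by conditional maximum likelihood on the equalized counts
(per-group conditional likelihoods given the group total, maximized on a
bounded log scale; estimates below exp(−9.5) collapse to 0). Tagwise or
trended dispersion is out of scope. log2 fold changes use equalized group
means with a prior count (default 0.125) to keep them finite.

TMM follows the standard recipe: reference = sample whose upper-quartile/
library ratio is closest to the mean; per sample, gene-wise M and A values
on genes positive in both; 30% two-sided trim on M and 5% on A;
precision-weighted mean of the surviving M; factors rescaled to geometric
mean 1. The expression filter retains a feature when its raw count is ≥
`min_count` (default 1) in at least as many samples as the smallest group
— a deliberate raw-count simplification of the usual CPM-based rule,
switchable via the `min_count` argument.

Multi-group designs are handled pairwise: a feature is significant *for*
group *i* only if significant (and in the right direction) against every
other group.

Preranked GSEA uses the weighted Kolmogorov–Smirnov running sum (hit steps
|score|ᵖ / Σ|hit scores|ᵖ with p = 1 by default, miss steps −1/(N−N_h); ES
is the extreme deviation), a gene-label permutation null with a required
seed, NES = ES / mean(|null ES| of matching sign), two-sided permutation p
within sign, and BH across sets. Sets disjoint from or fully covering the
ranked list are skipped with a recorded reason.

## Correlation

Spearman rho is the Pearson correlation of average ranks (ties share their
mean rank); p-values use the t-approximation with n−2 degrees of freedom,
reported raw and BH-adjusted. At the correlation stage microbes must pass
a stricter abundance floor (default 0.01%) than the profiling filter
(0.001%), reflecting the observation that classifiers are unreliable below
0.01%; the two cutoffs are independent knobs. Constant vectors leave rho
undefined and are reported missing; for clustering distances only, missing
cells are imputed as 0 with a warning. Clustering is agglomerative with
average linkage on 1 − Pearson correlation between rows (and columns) of
the rho grid; rows are pre-sorted by feature id so leaf orders are
deterministic across reruns. Genes and microbes are correlated across all
samples pooled (matched designs); per-group correlation can be had by
subsetting the input tables.

## Synthetic data

The fixture generator emulates every input dialect with planted signal:

- a 23-node taxonomy (two superkingdoms, three phyla, five genera — one
  species-less — eight species, four below-species nodes);
- a 21-term GO DAG over all three namespaces containing a diamond (a term
  with both an `is_a` and a `part_of` path to the same ancestor), one
  obsolete term and one alternate id;
- store source tables in which every representative also has a member
  accession carrying annotation, one representative annotated *only*
  through its member, and one unannotated accession;
- per-sample classifier files: 20,000 reads per sample by default, drawn
  multinomially from species proportions (5% unclassified, 2% at genus
  level, 20% of reads from species with strains assigned at strain level,
  20% with two tied accessions); the case group multiplies planted species
  (one 8-fold up starting at 1% baseline, one 8-fold down) before a mild
  per-sample lognormal wobble (σ = 0.3) that gives the dispersion
  estimator something real to estimate;
- host counts: 300 genes, NB with dispersion 0.1 around lognormal baseline
  means, ten genes planted 4-fold up and ten 4-fold down in the case
  group, gene lengths varied (200–5000 bp) so TPM ≠ CPM; matching GMT sets
  (planted-up, planted-down, random null).

Randomness is keyed by (seed, channel, sample index), so adding samples
never reshuffles existing ones and a fixed seed yields byte-identical
files. What the generator does **not** emulate: real sequence content,
cross-taxon tied matches, compositional coupling between host and microbe
abundances, contamination, or batch effects — so passing tests demonstrate
algorithmic correctness and statistical calibration under the stated
model, not robustness to those real-data phenomena.

## Problem sizes and numerical choices

The default test suite runs scaled-down fixtures (3 samples/group, 4,000
reads) for speed; the statistical acceptance checks use the full default
conditions (5/group, 20,000 reads, 20 seeds for recovery, 6 seeds of
300-gene null tables for calibration). TSV floats are rendered with 6
significant digits so reruns are byte-identical; ties in the exact test's
"as extreme" comparison use a 1e-7 relative guard, mirroring common
practice in exact binomial tests. Thresholds default to: abundance filter
0.001%, correlation-stage filter 0.01%, FDR 0.05, expression filter
min-count 1, top 100 genes for correlation.

## Known limitations

- No merged-taxid (merged.dmp) resolution; unknown taxids are counted and
  reported rather than remapped.
- Common dispersion only; no tagwise empirical Bayes.
- The exact test's simple library equalization diverges slightly from
  quantile-based equalization when library sizes are very unequal.
- GO slim mapping, microbial-term enrichment testing and compositional
  transforms are deliberately out of scope.
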