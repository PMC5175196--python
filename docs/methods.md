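# Methods

## Model

The pipeline treats biomarker discovery as a network-position problem on a
directed bipartite graph of miRNA → mRNA regulation. Three per-miRNA
statistics are computed:

- **NOD** (novel out-degree): the number of a miRNA's targets whose
  in-degree in the scoring network is exactly 1. A gene with a single
  regulator is a non-redundant ("weak") site; a miRNA controlling many
  such sites can perturb the system on its own.
- **TFP**: the fraction of the miRNA's targets that are transcription
  factors. Dysregulating TFs propagates further than dysregulating leaf
  genes.
- **AGP** (disease gene percentage, generalized from the autism use case):
  the fraction of the miRNA's targets on a curated disease-associated gene
  list. This is the disease-specific knowledge term that turns a generic
  functional-miRNA screen into a biomarker screen.

NOD and TFP are scored on the disease-specific network — the reference
network trimmed to differentially expressed genes — because they quantify
regulatory power *in the disease state*. AGP is scored on the untrimmed
reference network by default: the disease gene list supplies the
specificity, and trimming would conflate the two filters. A config switch
(`agp_network: specific`) scores AGP on the trimmed network instead; both
denominators are defensible and the choice is exposed rather than hidden.

## Differential expression

Probes are collapsed to genes by arithmetic mean intensity. Per gene we
use the two-sided pooled-variance Student's *t*-test and the linear fold
change of group means; DE requires *p* < 0.05 and FC > 2 or FC < 0.5
(strict), i.e. |log2 FC| > 1 applied symmetrically. No multiple-testing
correction is applied at this stage — the raw-p cutoff is part of the
procedure, and correction appears only in enrichment. Intensities are
assumed linear-scale, positive and pre-normalized; a zero pooled variance
yields *p* = 1 for equal means and *p* = 0 otherwise (degenerate
convention, exercised in tests).

## Outlier test construction

The filters need a per-miRNA notion of a "significantly high" score
against the cohort of all scored miRNAs. We use a one-sample Wilcoxon
signed-rank test on the paired differences d_j = x_focal − x_j over all
other miRNAs j, one-sided "greater". **This construction is an
interpretation**: it is the simplest test consistent with per-miRNA
p-values, identical p-values for identical scores, and monotonically
smaller p for larger scores — all structural properties the method's score
tables exhibit. Conventions:

- zero differences are dropped (Wilcoxon's original treatment);
- tied absolute differences receive mid-ranks;
- the null of W+ is enumerated exactly (subset-sum dynamic programming)
  for n_eff ≤ 25 tie-free differences; otherwise a tie-corrected normal
  approximation with continuity correction is used;
- all-zero differences give p = 1.0;
- the background for each metric is *every* miRNA in that metric's scoring
  network, for all three metrics; the sequential filters shrink the
  candidate list, never the background. This keeps a given score's p-value
  constant regardless of the stage at which a miRNA is examined.

No across-miRNA multiple-testing correction is applied; each filter uses
raw p < α (default 0.05), matching the procedure's design.

## Enrichment

Over-representation uses the one-sided hypergeometric tail
P(X ≥ k | N, K, n) with the universe defaulting to all reference-network
genes. Bonferroni multiplies by the number of sets actually tested (≥ 1
universe member), not the catalog size on disk; adj. p < 0.05 flags
significance. This replaces proprietary enrichment backends with the
standard open equivalent.

## Synthetic data

The generator emulates the statistical shape of a microarray biomarker
study, not its biology:

- **Expression**: per-gene log-normal baselines (median ≈ 100, σ = 1);
  multiplicative log-normal noise with coefficient of variation `cv`
  (unit-mean, so planted fold changes hold in expectation); planted DE
  genes split half up (×fc), half down (×1/fc) so both arms of the
  symmetric FC cutoff are exercised.
- **Network**: background edges attach to genes preferentially by current
  in-degree (heavy-tailed gene in-degree, as in merged target databases);
  each planted outlier miRNA receives a fixed number of exclusive targets
  (withheld from all other attachment, so their in-degree is exactly 1)
  plus Poisson-distributed shared targets. Planted target sets are
  composition-stratified: a target set of size D contains
  round(D·min(1, boost·frac)) TF members and likewise disease members, so
  the boosted TFP/AGP fractions hold exactly per planted miRNA rather than
  only on average. At boost = 1 the composition equals the background
  expectation (null planting).
- **Association list**: all planted outliers plus 20 random background
  decoys — the reproducible stand-in for manual literature curation.

Not emulated: probe-level effects, batch structure, correlated genes,
sequence features, and database-specific biases. Passing recovery tests
therefore shows the pipeline's statistical machinery is sound under its
own assumptions, not that it would recover biomarkers from any particular
real cohort.

Preset scales: `toy` (8 miRNAs / 20 genes, fixed content, hand-checkable —
it deliberately ignores the seed so it is byte-identical everywhere);
`default` (200 miRNAs, 1000 genes, mean degree 8, 10 planted outliers with
6 exclusive targets each, TF and disease fractions 0.1, boosts 3,
expression 20/20 samples with fc 4 and cv 0.2, 300 DE genes); `stress`
(2000 miRNAs, 5000 genes). The default scale keeps a full simulate+run
cycle around one second, so multi-seed funnel and recovery checks stay
cheap; planted outliers' targets are forced into the DE set so trimming
cannot erase the planted signal (their detection still has to pass the DE
test).

## Numerical and design choices

- miRNA IDs are normalized by stripping a leading `hsa-` only; gene
  symbols are uppercased. No alias resolution beyond this rule.
- Interaction sources are unioned without weighting; validated and
  predicted pairs are treated equally.
- Genes in the DE list but absent from the reference network are ignored
  with a logged count; miRNAs orphaned by trimming are pruned (NOD/TFP
  would otherwise be undefined).
- Ranking: descending AGP, ties by descending NOD, then lexicographic ID
  (a total order, so outputs are deterministic).
- All file writes are sorted and floats are printed with 10 significant
  digits; a fixed config reproduces its outputs byte-for-byte.
- Score fractions are kept unrounded internally; rounding happens only in
  the writer.

## Known limitations

- The signed-rank outlier construction is one defensible reading of an
  under-specified test; absolute p-value magnitudes depend on cohort size
  and are not comparable across networks of different size.
- With fewer than ~6 scored miRNAs the outlier test cannot reach p < 0.05
  and every funnel stage passes nothing; the pipeline reports the empty
  stage rather than guessing.
- Bonferroni is conservative for overlapping gene sets; no FDR option is
  provided.
- The DE stage implements the plain t-test + fold-change procedure; no
  moderated (empirical-Bayes) variance estimation is offered.
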