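# poma

Network-based prioritization of miRNA biomarkers from case/control
expression data — an implementation of the improved POMA (Pipeline of
Outlier MicroRNA Analysis) model with the disease-gene-percentage
extension, plus generic gene-set over-representation analysis.

## The problem and the model

High-throughput screens for disease miRNA biomarkers are noisy: for
heterogeneous diseases there is often no consensus set of dysregulated
miRNAs across studies. POMA instead asks which miRNAs occupy *structurally
powerful and disease-relevant positions* in the miRNA–mRNA regulatory
network restricted to the disease state. Given a case/control expression
matrix and a merged miRNA→mRNA interaction table, the pipeline:

1. **Differential expression.** Probes are collapsed to genes by mean
   intensity; per gene a two-sided Student's (pooled-variance) *t*-test and
   a linear fold change FC = mean(case)/mean(control) are computed. A gene
   is DE iff *p* < 0.05 and FC > 2 or FC < 1/2.
2. **Disease-specific network.** The reference network (union of all
   interaction sources, one edge per distinct miRNA→gene pair) is trimmed
   to DE genes; miRNAs left without targets are pruned.
3. **NOD filter.** For each miRNA *m*, NOD(*m*) = #{targets *g* of *m* with
   in-degree(*g*) = 1} — the number of genes regulated *only* by *m*.
   miRNAs whose NOD is a significant outlier over the background of all
   scored miRNAs (one-sided Wilcoxon signed-rank on the paired differences
   focal − other, *p* < 0.05) pass.
4. **TFP filter.** TFP(*m*) = |targets(*m*) ∩ TF| / |targets(*m*)|, the
   transcription-factor fraction of the target set; the same outlier test
   is applied to the stage-3 survivors.
5. **Literature association (optional).** Survivors are intersected with a
   user-supplied list of disease-associated miRNAs — a declarative,
   reproducible stand-in for manual citation curation.
6. **AGP filter and ranking.** AGP(*m*) = |targets(*m*) ∩ D| /
   |targets(*m*)| for a curated disease gene set *D* (targets taken from
   the reference network by default). Significant-AGP survivors are the
   candidate biomarkers, reported in descending AGP order (ties: NOD
   descending, then ID).

Enrichment of candidate targets against any GMT catalog uses the one-sided
hypergeometric tail with Bonferroni adjustment (significant at adj. *p* <
0.05).

## Worked example

The package ships a generator for fully synthetic studies with planted
ground truth. The `toy` preset is an 8-miRNA / 20-gene study small enough
to verify every stage by hand:

```sh
poma simulate --preset toy --outdir study
poma run \
  --expression study/expression.tsv --annotation study/annotation.tsv \
  --interactions study/interactions_validated.tsv \
  --interactions study/interactions_predicted.tsv \
  --tf-genes study/tf_genes.txt --disease-genes study/disease_genes.txt \
  --associated-mirnas study/associated_mirnas.txt --outdir out
```

prints

```
{
  "agp": 2,
  "association": 2,
  "de_genes": 16,
  "network_edges": 18,
  "network_genes": 14,
  "network_mirnas": 8,
  "nod": 3,
  "tfp": 3
}
candidates (descending AGP): miR-t1, miR-t2
```

Reading: 16 of the 20 genes are differentially expressed; trimming the
24-edge reference network to them leaves 18 edges over 8 miRNAs and 14
genes. Three miRNAs (NOD 5, 4, 4) pass the NOD outlier filter, all three
pass TFP, two are on the association list, and both of those have
significantly high AGP — miR-t1 (AGP 0.5) ranks above miR-t2 (AGP 0.4).
`out/score_table.tsv` holds the full per-miRNA table (NOD/TFP/AGP, their
outlier p-values and the stage flags); `study/manifest.json` records the
planted truth and the expected result of every stage.

The library mirrors the CLI one-to-one:

```python
from poma import simulate_study, PipelineConfig, run_poma
paths = simulate_study("default", seed=1, outdir="study")  # 200 miRNAs, 1000 genes
report = run_poma(PipelineConfig(
    expression=paths["expression"], annotation=paths["annotation"],
    interactions=[paths["interactions_validated"], paths["interactions_predicted"]],
    tf_genes=paths["tf_genes"], disease_genes=paths["disease_genes"],
    associated_mirnas=paths["associated_mirnas"], outdir="out"))
report.candidates          # AGP-ranked biomarker list
report.stage_counts        # the filter funnel
```

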