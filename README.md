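# methclass

Integrative methylation-array analysis for resolving molecular classes of
tumor cohorts — built around the workflow used to separate DICER1-associated
mesenchymal tumors into a low-grade class, a sarcoma class and a primary
intracranial sarcoma class from genome-wide beta-value profiles.

The package is aimed at computational biologists working with Illumina-style
methylation arrays (450k/EPIC-like) who need, in one place:

- **probe-level preprocessing** — platform intersection, removal of
  sex-chromosome / SNP-overlapping / cross-reactive / ambiguously mapped
  probes, beta ↔ M-value transforms;
- **unsupervised class discovery** — top-variable probe selection,
  hierarchical clustering (Euclidean distance, average or Ward linkage),
  tree cutting, t-SNE embedding and bootstrap co-clustering stability;
- **copy-number inference** from array intensity — per-probe log2 ratios
  against a reference panel, recursive binary segmentation, gain/loss calls
  at ±0.1 log2, per-sample **genomic index** GI = A²/C (A = altered
  segments, C = chromosomes involved), cohort aberration frequencies and
  focal-event detection;
- **methylation quantification** — global (outside CpG islands), per
  context (islands, gene bodies, promoters) and per CNV state, plus the
  cohort statistics used for clinical tables (Pearson chi-squared,
  Games–Howell post-hoc comparisons, Pearson correlation);
- **differential methylation** — per-probe Welch t tests with
  Benjamini–Hochberg FDR, Δβ banding (hyper > 0.1, hypo < −0.1),
  probe-lasso-style DMR calling (≥ 5 significant probes per window),
  sign-matched DMR intersection between class comparisons, and
  hypergeometric gene-set enrichment;
- **survival analysis** — Kaplan–Meier product-limit estimation with
  Greenwood errors and the k-sample log-rank test;
- a **synthetic-cohort generator** with full ground truth (class labels,
  copy segments, DMR blocks, noise-free copy signal) so that every stage
  can be tested for parameter recovery without any external data.

The fit/transform-shaped stages are exposed as scikit-learn estimators
(`ProbeFilter`, `VariableProbeSelector`, `HierarchicalClassDiscovery`,
`TSNEEmbedding`, `CopyNumberSegmenter`) that compose with sklearn
pipelines; plain functions cover the same operations on probes × samples
frames, which is also the on-disk layout (TSV matrices, BED-like
annotation, CSV sample sheets, SEG/BED segment output, GMT gene sets).

## Worked example

```python
from methclass import datasets, preprocess, classify, cnv, methstats

annotation = datasets.build_genome_annotation(datasets.GenomeModel(), seed=0)
cohort = datasets.simulate_cohort(annotation, datasets.default_class_specs(), seed=0)

beta, report = preprocess.filter_probes(cohort.beta, annotation)
print(report)

probes = classify.select_variable_probes(beta, 2000)
labels = classify.assign_classes(classify.hierarchical_cluster(beta.loc[probes]), 3)

ratios = cnv.cohort_log2_ratios(
    2 ** cohort.log2_intensity, 2 ** cohort.reference_log2_intensity
).loc[beta.index]
segments = cnv.segment_cohort(ratios, annotation)
gi = cnv.cohort_genomic_index(segments)
print(gi.join(cohort.truth.classes).groupby("true_class")["genomic_index"].median())

chi = methstats.chi_squared_test([[9, 29, 15], [11, 9, 13]])
print(f"chi2 = {chi.statistic:.3f}, df = {chi.df}, p = {chi.p_rounded}")
```

prints

```
FilterReport(removed={'sex_chromosome': 1387, 'snp_overlap': 362, 'multi_hit': 358, 'non_unique': 215}, retained=17678)
true_class
LG       1.000
PIS     18.375
SARC     5.000
Name: genomic_index, dtype: float64
chi2 = 6.574, df = 2, p = 0.037
```

The filter report accounts for every removed probe by rule (probes failing
several rules are attributed to the first matching one).  Cutting the
dendrogram of the 2000 most variable probes at k = 3 recovers the three
simulated classes exactly (adjusted Rand index 1.0 against the generator's
truth).  The median genomic index is graded across classes — near-balanced
genomes in the low-grade class, increasingly complex genomes in the two
sarcoma classes — mirroring the inverse relationship between global
methylation and chromosomal instability that the hypomethylation analysis
quantifies.  The last line is the worked clinical statistic: the Pearson
chi-squared on the 2×3 sex-by-class table of an 86-patient cohort
(Female 9/29/15, Male 11/9/13) gives p = 0.037 at three decimals.

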