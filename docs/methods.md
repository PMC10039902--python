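# Methods

This note documents the models, defaults and numerical choices behind
`methclass`, and what the synthetic-cohort experiments do and do not
demonstrate about real array data.

## Data model

Beta values are methylation fractions in [0, 1], stored probes × samples.
All analyses operate on betas; the logit2 M-value transform is provided as
a convenience (offset-guarded, default offset 1e-6, exactly invertible).
Probe annotation carries chromosome, 1-based position, CGI relation
(island vs open sea — shores and shelves are folded into open sea), gene
region (promoter / body / intergenic), platform membership (A / B / both)
and three exclusion flags.  Internally all intervals are 0-based
half-open; the SEG writer converts to that format's 1-based inclusive
convention.

## Preprocessing

Platform merging takes the probe intersection of the two array designs
and concatenates their sample sets; sample ids must be disjoint.
Filtering removes, in fixed reporting order, sex-chromosome probes,
SNP-overlapping probes, cross-reactive ("multi-hit") probes and probes
that cannot be uniquely mapped.  A probe failing several rules is counted
under the first matching rule; the removal outcome is order-independent
and filtering is idempotent.  Raw-intensity normalization (background and
dye-bias correction) is upstream of this package — the pipeline ingests
normalized betas.  Missingness policy: variance ranking and per-probe t
statistics need complete rows, so probes with any missing value are
dropped by default (`drop_incomplete_probes`, configurable per-probe
missing-rate threshold).

## Class discovery

"Most variable" probes are those with the largest per-probe standard
deviation of beta across samples (ddof = 1), the common convention for
methylation classifiers; ties break lexicographically by probe id, which
makes selections deterministic and nested in k.  Clustering uses
Euclidean distance over samples with average linkage by default; Ward
linkage is supported as well because both appear in practice, and on the
default synthetic cohort both recover the classes (the desk-scale
conclusion does not depend on the choice).  The tree is cut into a
user-chosen k (class counts are an analyst decision here — no automatic
model selection is claimed); labels are ordered by cluster size, then by
smallest member index.  t-SNE uses the Euclidean metric with pinned
defaults (perplexity 30 capped at (n−1)/3, 1000 iterations, fixed seed):
reproducibility is prioritized over fidelity to any particular library
default, and the contract is neighborhood preservation, not coordinates.
Cluster stability is the fraction of probe-bootstrap replicates in which
a sample co-clusters with the majority of its original cluster mates;
degenerate single-cluster replicates are tallied in the output's attrs.

## Copy number

Per-probe log2 ratios are log2(sample intensity / per-probe median of an
explicit reference panel), median-centered per sample; at least three
reference samples are required.  Segmentation is recursive binary
splitting per chromosome: the candidate split maximizing the two-sample
Welch t statistic is accepted iff |Δmean| ≥ `min_delta` (default 0.1),
the split p-value (t distribution with Welch–Satterthwaite df,
Bonferroni-corrected over candidate positions) is below `alpha` (default
0.01), and both children keep `min_probes` (default 5) probes; recursion
continues on accepted children.  The scan is O(n) per window via
cumulative sums and is tested against an exhaustive re-implementation.
Degenerate windows (zero pooled variance with a nonzero mean difference)
split with p = 0; a constant chromosome stays one segment.  Segment means
are plain probe means, so the probe-count-weighted mean of segment means
reconstructs the chromosome mean exactly.

States are called by strict exceedance of ±0.1 log2 (a mean of exactly
±0.1 is balanced).  The genomic index is GI = A²/C with A the number of
gained+lost segments and C the chromosomes carrying them; a whole-
chromosome alteration counts as one segment and one chromosome, and a
fully balanced genome scores 0 (the 0/0 case is defined as 0).  Sex
chromosomes are removed upstream, so GI covers autosomes.  Focal events
are segments beyond ±1.0 log2 no longer than `max_len` (default 1 Mb on
the reduced genome, standing in for ~20 Mb at physical scale) — a
declared rule replacing manual inspection.

## Methylation quantification and cohort statistics

Global methylation is the per-sample mean beta outside CpG islands
(CpG-dense islands are excluded from global quantification; the switch is
recorded in the summary's metadata and applies identically to the
CNV-state means).  Context means restrict to islands, gene bodies or
promoters (promoter status comes from the annotation's region field — no
TSS-distance inference).  For CNV-state means each probe inherits the
state of its covering segment; an empty stratum yields NaN, never 0.

The chi-squared test is Pearson's without continuity correction,
df = (r−1)(c−1), with p reported at full precision and rounded to three
decimals (the reporting convention of clinical tables).  Games–Howell
compares each pair with t = Δmean/√(s₁²/n₁ + s₂²/n₂), Welch df, and the
upper tail of the studentized-range distribution with k groups at
q = |t|·√2, computed by scipy's numerical integration of the
studentized-range CDF (cross-checked against an independent
implementation in the tests).  Note the Games–Howell p-value is
multiplicity-adjusted by construction: under a k-group null its
*familywise* error is the calibrated 5%, while the per-pair rejection
rate is necessarily below nominal — the calibration experiments measure
the familywise rate.

## Differential methylation

Per-probe tests are two-sided Welch t tests on betas (a deliberate,
documented choice of statistic with the same significance semantics as
moderated alternatives: BH adjustment across all tested probes,
significance at FDR < 0.05).  Probes with zero variance in both groups
and equal means get p = 1.  Δβ is mean(group B) − mean(group A); the
caller fixes the orientation.  Bands: hyper for Δβ > 0.1, hypo for
Δβ < −0.1, boundaries inclusive to mid.

DMR calling uses a single configurable lasso radius (default 1000 bp)
rather than feature-specific density quantiles: a window of ± radius is
drawn around each significant probe, windows capturing ≥ 5 significant
probes are retained, overlapping retained windows merge, and regions are
trimmed to their outermost member significant probes (hence no orphan
significant probe can sit inside reported bounds).  Regions whose member
deltas average exactly zero are discarded, so every region has a
direction.  Cross-comparison DMR intersection requires ≥ 1 bp overlap
AND matching direction sign.  Enrichment is the one-sided hypergeometric
upper tail against a declared gene universe with BH across sets; the
statistic is discrete, so its null rejection rate sits slightly below
the nominal level (the calibration uses large sets to keep the gap
small).

## Survival

Kaplan–Meier uses the standard tie convention (subjects censored at t
remain at risk at t), Greenwood standard errors, and 95% CIs via the log
transform exp(log S ± z·se(log S)) clipped to [0, 1].  The median is the
first event time with S ≤ 0.5 (infinite when never reached).  The
between-group comparison is the k-sample log-rank test — the field
standard companion to KM curves — computed as the quadratic form of
observed−expected counts against their hypergeometric covariance
(pseudo-inverse for numerical safety), df = k−1; a comparison with no
events returns p = 1 with an explicit flag.

## Synthetic cohort: what it emulates

The generator reproduces the statistical structure the pipeline assumes,
at a reduced scale (default 20 000 probes over 22 autosomes + X + Y at
1/20 physical length — all downstream statistics are scale-free):

- **Bimodal betas**: per-probe baselines around class means (islands low,
  default 0.15; open sea high) as clamped normal draws (probe effect SD
  0.05, per-sample noise SD 0.04).  Clamped normals were chosen over beta
  draws for direct control of the means that recovery tests assert.
- **Graded hypomethylation**: open-sea class means 0.60 / 0.52 / 0.45
  for the low-grade (LG), sarcoma (SARC) and intracranial-sarcoma (PIS)
  classes, 30 samples each — the class signal acts outside CGIs, and sex
  chromosome probes carry no class signal (so the filter step has real
  work and no leakage).
- **Copy number**: altered segment counts ~ Poisson with class rates
  2 / 8 / 20, segment lengths 30–150 probes, equal gain/loss odds, and a
  whole-chr8 gain with probability 0.10 / 0.80 / 0.30 — recurrent chr8
  gain is the sarcoma-class hallmark.  Copy states produce log2 effects
  of ±0.3 (clearly exceeding the ±0.1 call thresholds so state-calling
  recovery is well-posed) with bin-level noise SD 0.025, on a per-probe
  intensity baseline shared with a 20-sample CNV-free reference panel.
- **CNV-coupled hypomethylation**: betas inside gained segments drop by
  `gain_hypo_shift` (default 0.10).
- **DMR signal**: a fraction of probes is laid down in tight clusters
  (6–12 probes, 100–250 bp spacing), mirroring probe concentration at
  islands/promoters; class-specific blocks among these clusters shift by
  `dmr_delta` (default −0.20), giving window-based region calling
  realistic local density.
- **Survival**: exponential event times with monthly hazards
  0.002 / 0.010 / 0.020, independent exponential censoring (0.005/month)
  and an administrative cap at 240 months, so progression-free survival
  is graded LG > SARC > PIS.

Not emulated: raw two-channel intensities, batch/center effects, tumor
purity and cell-type composition, probe-specific error structure, and
spatial correlation of betas beyond the injected blocks.  Passing
recovery tests therefore demonstrates the correctness and calibration of
the algorithms under the stated generative model — not that real tumor
cohorts will separate this cleanly; real-data class structure is weaker
and confounded in ways this generator deliberately omits.

## Problem sizes and seeds

Recovery experiments use the full default cohort (20 000 probes × 90
samples); multi-seed claims (class recovery, methylation–GI correlation)
use ten independently simulated cohorts; breakpoint recovery uses 100
replicate step signals; null calibrations use 2000 Monte-Carlo
replicates.  Every stochastic component takes an explicit seed and fixed
seeds fix every output byte.  The acceptance script derives all
sub-experiment seeds from a single `--seed`.

## Known limitations

- The segmentation criterion is a self-contained recursive binary rule,
  not circular binary segmentation; very short alterations (< 5 probes)
  are invisible by design.
- The DMR window uses one global radius; probe-density-adaptive windows
  can be approximated via the optional per-feature scale of the radius
  but are not modeled.
- Games–Howell p-values rely on scipy's studentized-range integration,
  which is slow for large batch use; the calibration experiments use
  interpolated critical values with an exact fallback near the decision
  boundary.
- GI values depend on segmentation resolution: reduced-genome medians are
  ordering-comparable across classes but not numerically comparable to
  full-array cohorts.
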