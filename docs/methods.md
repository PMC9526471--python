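# Methods

## The problem setting

A rare-class diagnostic: identify medullary thyroid carcinoma (MTC) among
thyroid nodule FNAB specimens, where MTC is ~4% of the training cohort and
the non-MTC class spans many histologies (benign nodules, follicular
adenomas, papillary and follicular carcinomas, ...). The package
implements the development pipeline — feature selection, model
competition, locked-model selection, blinded validation, and the clinical
summary of the validation cohort — and supplies a synthetic-data generator
so the whole arc is executable and testable without any patient data.

## Synthetic cohort generator

Counts for gene $g$ in sample $j$ are negative binomial with mean
$s_j\,\mu_{g,k(j)}$ and variance $\mu + \alpha_g\mu^2$:

- **Baseline means** $\mu_g$: log-normal(meanlog 2.5, sdlog 1.3) — a
  typical bulk RNA-seq mean–abundance spread. Signature genes instead draw
  baselines from log-normal(0, 0.7): MTC marker genes (calcitonin pathway,
  neuroendocrine program) are near-silent in non-MTC tissue, which is what
  makes 64–1024-fold activation biologically and numerically plausible.
- **Planted signature**: 120 genes whose expected expression in MTC
  samples is multiplied by $2^{\beta_g}$, $\beta_g \sim U(6, 10)$ — the
  same $\beta_g$ in the FNAB and tissue contexts, since the phenotype is
  the tumor's, not the specimen type's. The first 34 signature genes form
  the mandatory cassette (first 5 flagged as the legacy "cassette" panel,
  29 as "literature" genes).
- **Non-MTC heterogeneity**: 50 nuisance genes with $|\log_2 FC| \le 1.5$
  separate benign from non-MTC-malignant samples (assigned alternately),
  so specificity is tested against within-class structure, mirroring a
  validation cohort with 10+ distinct non-MTC histologies.
- **Dispersions** $\alpha_g \sim$ Gamma(shape 2, scale 0.05) (mean 0.1),
  drawn once and shared across cohorts — matching the DE model and keeping
  parameter recovery well-posed. **Library sizes**: log-normal(0, 0.3)
  size factors.
- **Cohorts**: 21 MTC + 462 non-MTC training FNAB; 97 tissues (21 MTC; the
  76 non-MTC is a design choice — only the total of 97 is constrained);
  21 + 190 blinded validation FNAB. Bethesda categories are bookkeeping
  only (training MTC 5/6/6/4 over III/IV/V/VI; validation MTC 8/6/7 over
  III/IV/V) and never influence expression.
- **Controls**: 6 replicate groups × 3 technical replicates. Each group is
  one expected-expression vector — alternately benign-like and MTC-like,
  with per-gene log-normal(0, 0.6) jitter marking distinct biological
  pools — and replicates differ only by NB noise and library size.
- **Dilution**: mixing tumor with benign RNA is a convex combination of
  expected-expression vectors before count sampling.

What the generator does **not** emulate: sequencing-run batch effects, GC
and transcript-length bias, cross-sample dispersion heterogeneity, real
gene identities, and any correlation structure beyond the planted
signature/nuisance blocks. Passing tests therefore demonstrate that the
pipeline's logic is correct under its stated statistical assumptions —
not that the classifier would achieve these operating characteristics on
clinical material.

## Differential expression

Median-of-ratios size factors (rescaled to geometric mean 1); per-gene NB
dispersion by method of moments within each class, pooled by degrees of
freedom and floored at 1e-8; $\log_2 FC$ from normalized class means with
a 0.5 pseudocount applied only when a class mean is zero; delta-method SE
$\mathrm{Var}(\log \hat q_k) \approx \overline{s^{-1}}/(n_k \hat q_k) +
\hat\alpha/n_k$; two-sided normal Wald p; BH step-up adjustment per
context. Genes with all-zero counts in both classes get $p=1$. This is
deliberately the plain two-group special case — no dispersion shrinkage,
independent filtering, or outlier refitting — because the pipeline
consumes DE only as a ranked filter; on small planted simulations it
agrees with a reference NB-GLM implementation (log-fold-change correlation
> 0.98, identical strict-threshold calls in the cross-check test).

The $\log_2 FC > 6$ filter is read one-sided (over-expressed in MTC),
matching selection of a positively activated marker cassette; the
clustering pool (adj. $p < 0.01$) also requires dual-context significance,
consistent with the intersection rationale.

## Feature sets

Sets 1–2: dual-context threshold sets. Sets 3–5: average-linkage
hierarchical clustering on $1-$Pearson correlation of
$\log_2(\text{normalized count}+1)$ over training FNABs, cut into
$k=\max(2,\lceil\sqrt{\#DE}\rceil)$ clusters, then the top 1/20%/50% per
cluster by FNAB adjusted $p$ (ceil on fractions; ties broken by larger
$|\log_2 FC|$, then gene id). Sets 6–8: recursive 2-medoid partitioning on
the same distance — a reproducible stand-in for HOPACH-style recursive
partitioning. A proposed 2-split is accepted only when its mean silhouette
reaches 0.5 (i.e. the halves are genuinely separated), with minimum node
size 10 and maximum depth 4; this keeps cohesive blocks whole and recovers
well-separated correlation blocks exactly. Medoid initialization is the
most-distant pair, so the partition is deterministic. Per-leaf selection
of the top 10%/20%/50%. Every set is unioned with the mandatory cassette.
Ceil-based per-cluster selection makes sets 3⊆4⊆5 and 6⊆7⊆8 nested by
construction.

## Classifiers and scores

Features are $\log_2(\mathrm{CPM}+1)$ per gene (CPM from each sample's own
total count, hence library-size invariant), centered and scaled by
training-estimated parameters that are stored and reused unchanged at
prediction time. The SVM is linear-kernel soft-margin (C = 1, class
weights inverse to class frequency); a linear kernel keeps the score
interpretable and is the norm for ~100-gene expression classifiers. Its
"logit score" is the raw signed decision value (no Platt scaling). The
elastic net uses mixing 0.5 with penalty strength chosen by nested
stratified 3-fold CV over C ∈ {0.03, 0.3, 3} (ties toward the stronger
penalty; inner fits deliberately early-stopped — they only rank
penalties). The decision threshold is fixed at 0 rather than tuned: the
output is a binary positive/negative call with no operating-point search.
Locked models are plain (weights, intercept, normalization) records;
prediction is a dot product, serialization is JSON, and any mutation after
locking raises.

## Model selection

Fold assignments in the 10×5-fold CV depend only on (repeat, seed), so all
16 settings see identical partitions; normalization and penalty selection
are refit inside each training fold. Settings qualify for final selection
only with perfect mean CV sensitivity and specificity (resubstitution
accuracy is also computed and reported separately, since "perfect on the
training set" can mean either). The four criteria are combined by rank sum
— scale-free across heterogeneous quantities — with ties broken by fewest
genes, then set id. The reference cassette score (criterion 3) is the mean
standardized log-CPM of the 5 core cassette genes, a stand-in for the
unavailable legacy microarray score. If controls are missing the
variability criterion is dropped with a warning rather than imputed.

## Validation statistics

Clopper–Pearson intervals via beta quantiles with closed-form edges
($x=n$: lower $=(\alpha/2)^{1/n}$). The power analysis uses the
arcsine-transformation one-sample normal approximation, one-sided
"greater" by default: with $p_0=0.9$, $p_1=1.0$, $n=21$, $\alpha=0.05$
this gives 90.4% — the two-sided reading gives ≈84% and cannot support a
">90% power" design statement, which is why one-sided is the default; the
two-sided form is exposed.

## Clinical staging

AJCC 8th edition for MTC only (age-independent): M1→IVC; T4b→IVB; T4a or
N1b→IVA; N1a with assessable T1–T3→III; N0 with T1→I, T2/T3→II. Missing
data conventions of the cohort: NX→N0, MX→M0, unspecified N1→N1a; TX with
node-negative M0 disease is unstageable (NA). Percentages are rounded
half-up to integers to match clinical-table presentation. The packaged
21-case table's summary row prints nodule size as 2.1 under a "median
(range)" header, but the median of the 20 non-missing sizes is 1.65 (the
mean is ≈2.16); the summary reports median and mean separately rather
than reproducing 2.1 as a median.

## Problem sizes and numerical choices

Default end-to-end runs use 5000 genes and the full cohort sizes above;
the 16-setting 10×5-fold competition dominates the runtime (~1.5 minutes
on one CPU). Unit tests use scaled-down configs (hundreds of genes, tens
of samples) chosen to preserve every qualitative property being tested.
Degenerate inputs are handled explicitly: all-zero samples error naming
the sample; zero class means take the pseudocount; constant features get
unit scale; fewer than 2 DE genes collapse the clustering sets to the
mandatory cassette with a warning; classes too small for the inner CV fall
back to the middle penalty.

## Known limitations

- The planted signature is so strong (by design, matching the phenotype)
  that all 16 settings tie at perfect CV accuracy; the selection machinery
  is therefore exercised on robustness criteria, not accuracy differences.
- The moment dispersion estimator is noisier than shrinkage estimators at
  small n; it is adequate here because decisions use extreme thresholds
  ($10^{-6}$) against 60–1000-fold changes.
- The recursive partitioner is a deterministic approximation of
  HOPACH-style clustering, not a port of its mean-split-silhouette
  machinery.
- Real gene identities (the historical 108-gene list and 34-gene cassette)
  are not public; the mandatory cassette is the generator's designated
  signature subset.
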