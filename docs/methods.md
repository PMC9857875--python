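# Methods

`trfscape` implements an end-to-end 5′-tRF (tRNA-derived fragment)
biomarker workflow for tumor/normal small-RNA cohorts, together with a
synthetic-data module that generates every input with planted ground
truth.  This note documents the models, the numerical choices, and what
the synthetic cohorts do and do not emulate.

## 1. tRF reference and quantification

**Reference.**  Mature tRNA sequences are built from genomic gene models
by excising annotated introns, correcting for strand, and appending the
post-transcriptional `CCA` trinucleotide at the 3′ end.  Pre-tRNA
sequences retain introns and carry genomic 5′ leader / 3′ trailer flanks
(default 50 nt, truncated at chromosome ends) without `CCA`.  Candidate
5′-tRFs are defined as fragments anchored at mature position 1 whose 3′
ends range over a length window, default **14–32 nt** — wide enough to
span reported 5′-tRF sizes while excluding 5′ tRNA halves (which arise
from anticodon-loop cleavage at ~30–40 nt).  All prefixes in the window
are enumerated from mature sequences only (5′-tRFs derive from mature
tRNA); identical sequences from isodecoder gene copies are collapsed into
one candidate whose parent set is the union, which makes downstream read
assignment unambiguous.  Candidate identifiers are deterministic hashes
of the sorted parent set and the length.

**Quantification.**  Reads are assigned to candidates by exact
full-length sequence identity (hash lookup).  Under a zero-mismatch
full-read matching rule this is equivalent to running an aligner against
the candidate FASTA, and it is exactly testable: the suite checks it
against a naive all-pairs string comparison and against generator-planted
read counts.  Expression is reads per million (RPM) of total mapped
reads, where "mapped" by default means matching the tRNA sequence space
(candidate hit, or exact substring of a mature/pre-tRNA sequence on
either strand); a whole-library denominator is available
(`denominator="library"`) because the mapping universe of the original
BAMs is not recoverable.  The choice is recorded in the output manifest.

**Filtering and normalization.**  Features with 90th-quantile RPM below 1
across samples are removed; the boundary is inclusive (a feature exactly
at 1 is kept, reading the filter as "remove < 1") and quantiles
interpolate linearly between order statistics.  Remaining values are
log2(v+1)-transformed (the +1 pseudocount bounds the transform at 0 for
RPM-scale data) and then upper-quartile normalized across samples *in log
space*, matching the stated order of operations: per sample the 75th
percentile of log2 values is subtracted and the across-sample mean of
those quartiles added back.  The alternative order (UQ scaling on RPM,
then log) is available as `uq_then_log2_normalize`.

## 2. Differential expression and co-expression

Tumor-vs-normal comparisons use the two-sample unpaired Wilcoxon rank-sum
test — exact when both groups are small and tie-free, tie-corrected
normal approximation otherwise — with Benjamini–Hochberg correction
across features.  Differential features satisfy FDR < 0.01 and
|log2FC| > 1, where **log2FC is the difference of group means on the
normalized log2 scale** (the matrix the test itself uses); log2 of the
ratio of linear-scale means is available behind `fc_mode="mean-ratio"`.
Classifier features are the top 13 up-regulated features with
log2FC > 2 at FDR < 0.01, ranked by log2FC (ties by smaller FDR, then
id); fewer qualifying features are returned with a warning.

Guilt-by-association screens Pearson correlations between dysregulated
tRFs and mRNA genes (two-sided t-based p), keeping |r| > 0.3 at
FDR < 0.05 with BH applied **jointly over the whole tRF × gene pair
family** — the literal reading of a single FDR threshold on that family.
Correlations default to tumor samples only (co-expression claims concern
tumors); pass `samples=` to change.  Gene-set enrichment of the
co-expressed lists is out of scope (external annotation services).

## 3. Diagnostic classifiers

Samples are split 70/30 stratified by class; four scorers are fitted on
the training split with fixed, caret-style defaults: random forest (500
trees, √p features per split), RBF-kernel SVM (cost 1, standardized
inputs, decision values as scores), logistic regression with a negligible
ridge (so separable data converge), and PLS discriminant analysis with 2
components on a 0/1 response.  The class imbalance is preserved — no
resampling.  ROC curves and AUCs (trapezoidal, tie handling by the
Mann–Whitney convention) are reported on the held-out split only; train
and test ids are asserted disjoint.  Feature selection is performed on
the full cohort before splitting by default, mirroring the conventional
(optimistic) workflow this package reproduces; nested selection inside
the training split is a caller choice (select on the training samples
and pass the list in).

## 4. Prognostic tRF score

The funnel is: per-feature univariate Cox (a feature is a candidate when
both the Wald p and the score-test p are below 0.05 — the score test at
β=0 is the "log-rank" p that standard survival summaries print, here for
the continuous covariate), LASSO-Cox on the candidates with the penalty
chosen by 10-fold cross-validation, then a multivariate Cox refit
retaining features at Wald p < 0.05.  The tRF score is
ts = Σ βᵢxᵢ with no intercept; patients split at the median score
(ts ≤ median → low).

Numerical choices:

* **Ties:** Efron handling throughout.
* **Convergence:** fits are initialized by `lifelines` and polished by
  Newton–Raphson on the Efron partial likelihood until the gradient
  infinity norm is < 1e-9 (asserted < 1e-5 on every fit; summary
  statistics come from the polished estimate and observed information).
* **CV deviance:** per left-out fold, −2·(pl_full(β_k) − pl_train(β_k))
  (Verweij–van Houwelingen), Breslow partial likelihood on the coxnet
  path; `lambda_rule="min"` (deviance minimum) is the default, `"1se"`
  selects the sparsest λ within one standard error.
* **Selection endpoint:** progression-free survival; disease-free
  survival is evaluation-only.
* **Horizons:** 12/36/60 months (1/3/5 years) against month-scale times.

Kaplan–Meier curves and the two-group log-rank test come from
`lifelines`; the log-rank p is verified in the suite to equal the Cox
score test of the group indicator to 1e-6 on tie-free data.
Time-dependent performance is the IPCW cumulative-case/dynamic-control
AUC (Kaplan–Meier censoring estimator); horizons beyond follow-up or
without prior events are reported as NaN, not extrapolated.  The added
value of the tRF score over the Gleason score uses the linear predictor
of a bivariate Cox fit and a paired subject-level bootstrap
(default B=1000, seeded, bootstrap-SE normal test, two-sided; predictor
weights held fixed across resamples).  Per-sample survival probabilities
use the Breslow baseline: S(t|x) = S₀(t)^exp(lp − mean lp).

## 5. Expression subtypes

Features with interquartile range < 0.5 are removed (boundary inclusive:
IQR exactly 0.5 is kept).  NMF runs on the non-negative log2(RPM+1)
matrix — the upper-quartile-recentred matrix can contain negatives and is
not used here.  The factorization is Frobenius-objective multiplicative
updates, 30 seeded restarts per rank, max 2000 iterations.  Restarts used
for the consensus stop when the sample assignment (argmax of the
coefficient columns) has been stationary for 40 iterations (checked every
10) — the canonical consensus-NMF stopping rule.  This matters: restarts
run to deep objective convergence all reach the same optimum on
well-separated data, the consensus saturates at 1 for every rank, and
rank selection degenerates to numerical noise.  The reported factors are
the best restart polished to an objective tolerance of 1e-5 (relative
per-iteration decrease); the per-iteration error trace is retained and
asserted non-increasing.

For each rank k the consensus matrix is the co-clustering frequency over
restarts; the cophenetic coefficient is the correlation between consensus
dissimilarities and the cophenetic distances of their average-linkage
dendrogram, and the dispersion coefficient is mean 4(c−½)².  The rank is
the k maximizing the cophenetic coefficient, with values within 1e-3 of
the maximum treated as ties resolved toward the smaller k — the
coefficient is estimated from 30 restarts and differences at that scale
are sampling noise (an exact-equality tie rule would never fire).
Subtype membership comes from average-linkage clustering of
1 − consensus cut at k, not from a single restart's argmax: the
best-error factorization of clean block data is not always the block
partition, while the consensus is stable (verified in the suite).
Dispersion is reported but not used for selection.

Consensus K-means (80% sample subsampling, default 1000 repetitions,
Euclidean K-means, co-clustering frequency among co-sampled pairs, final
labels by average-linkage of 1 − consensus) corroborates the NMF
partition.  Subtype–clinical associations use Kruskal–Wallis for
continuous/ordinal variables (age, PSA, Gleason as ordered levels),
Pearson chi-squared without continuity correction for categorical ones,
and the multi-group log-rank test for survival.

## 6. Genomic instability

Inputs are allele-specific copy-number segments (sample, chrom, start,
end, total_cn, minor_cn; 1-based inclusive) scored against a
chromosome-arm model.  Per sample:

* **TMB** — non-synonymous mutations (Missense, Nonsense, Nonstop,
  Translation_Start_Site, Splice_Site, Frame_Shift_Ins/Del,
  In_Frame_Ins/Del) per megabase; the coding denominator defaults to
  38 Mb and is configurable (unknown classifications count as synonymous
  with a warning).
* **Large LOH** — per arm, maximal runs of contiguous LOH segments
  (minor_cn = 0, total_cn ≥ 1) longer than 15 Mb covering < 90% of the
  arm ("non-arm-level"; the 90% operationalization is configurable).
* **LST** — per arm, after removing segments < 3 Mb and merging
  equal-state neighbors, breakpoints whose flanks are each > 10 Mb and
  differ in copy state.  The 3 Mb smoothing follows the component's
  original literature and is configurable.
* **NtAI** — segments with allelic imbalance (total_cn ≠ 2·minor_cn)
  reaching a chromosome terminus (exact contact by default; a tolerance
  flag exists for real data) and not crossing the centromere.
* **HRD** = large LOH + LST + NtAI.
* **Aneuploidy score** — ploidy is the length-weighted *modal* total copy
  number (so focal amplification cannot shift a diploid genome); an arm
  is gained/lost when ≥ 80% of its assayed length lies above/below
  ploidy; AS = gains + losses over non-excluded arms.  The synthetic arm
  model excludes no arms; a human model would exclude the acrocentric
  short arms.
* **Segment count** — raw record count, deliberately not merged: it
  measures segmentation granularity as delivered.

All scores are invariant to chromosome/sample order and to splitting a
segment into equal-state halves *at or above the 3 Mb smoothing scale*;
splitting a 3–10 Mb segment into sub-3 Mb pieces removes it from the
smoothed landscape and can genuinely change the LST count, so the
invariance is asserted (and holds) only above that scale.

## 7. Synthetic cohorts: what they emulate, and what they do not

The generators draw from named, seed-derived substreams, so adding a
generator never perturbs existing fixtures and identical configurations
are byte-identical.

* **Genome/reads** — a small multi-chromosome genome with embedded tRNA
  gene models (mature body 60–100 nt, ~30% carrying a 10–20 nt intron,
  ≥ 50 nt flanks).  Planted reads are exact candidate copies with Poisson
  counts; background reads come from non-tRNA regions and are
  rejection-sampled to never equal a candidate, making assignment tests
  exact.  No sequencing errors, adapters, quality modeling, or germline
  variation — so read-level results say nothing about mismatch-tolerant
  mapping.
* **Expression** — log2-normal RPM (baselines U(3,8), noise sd 0.5 by
  default) with a planted tumor shift on a fraction of features (defaults
  mirror the analyzed cohort's proportions: ~20% differential, 90% of
  them up); co-expressed mRNAs share a latent factor with chosen tRFs at
  true r = 0.6.  Groups are independent (unpaired), matching the unpaired
  test; there is no sample pairing structure, batch effect, or
  count-level noise.
* **Survival** — exponential times (constant baseline hazard, chosen over
  Weibull for closed-form checks) with log-hazard Σβᵢxᵢ on centered
  log2 expression; independent uniform censoring with the scale
  calibrated by bisection to the target censor rate; Gleason sampled from
  {6..10} through a latent shifted by the linear predictor; log-normal
  PSA.  An optional `gleason_beta` adds a true Gleason effect to the
  hazard so predictor-comparison power tests have a genuinely prognostic
  baseline covariate.  Proportional hazards hold exactly by construction,
  so these cohorts cannot detect PH violations.
* **Segments/mutations** — events are placed one per chromosome arm on a
  4-chromosome arm model with geometries chosen so each planted event
  scores exactly once and nothing else: NtAI events are 6–9 Mb AI
  segments touching a telomere (too short to create an LST); LST events
  are 12 Mb gains placed interior to an arm (2 breakpoints) or abutting
  the centromere (1 breakpoint); large-LOH events are 16–20 Mb
  copy-neutral LOH runs guarded by 4 Mb buffer segments (which survive
  smoothing but are too short to turn the flanking breakpoints into
  LSTs); arm-level gains/losses cover 92% of an arm from the centromere
  side (≥ 80% → arm call, ≥ 90% → excluded from non-arm-level LOH, never
  touching a telomere → no NtAI).  The remaining genome is diploid
  balanced.  Real profiles have overlapping, interacting events; these
  profiles verify the scoring rules, not biological realism.

## 8. Problem sizes used in the test suite

The suite runs the full pipeline at desk scale: differential-expression
calibration/power at n = 60/60 over 20 seeds; the prognostic funnel at
n = 500 with 8 planted prognostic tRFs among 100 over 20 seeds (CI
coverage over 50 univariate cohorts at n = 400); classifiers at the
published class sizes 499 vs 52 with 13 selected features; subtype
recovery on a 200-tumor, 4×50-block cohort with 100 features; HRD/AS
exactness over 200 random planted profiles.  These sizes were chosen so
that every stochastic check has comfortable statistical margin while the
suite completes in minutes.

## 9. Known limitations

* Exact-match quantification cannot model sequencing errors or
  post-transcriptional modifications that break exact identity.
* The RPM denominator of the original BAM-based workflow is not
  recoverable; both supported denominators are explicit.
* The nomogram is reduced to its substance (the bivariate linear
  predictor and per-sample survival probabilities); no graphical
  rendering.
* Subtype discovery on real cohorts is sensitive to feature filtering
  and normalization; the synthetic block cohorts validate the machinery,
  not any particular biological subtype claim.
* The bootstrap AUC-difference test holds predictor weights fixed;
  selection uncertainty upstream of the comparison is not propagated.
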