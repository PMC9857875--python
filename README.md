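# trfscape

5′-tRF biomarker analysis for prostate adenocarcinoma cohorts — from
small-RNA reads to diagnosis, prognosis, tumor subtypes, and
genomic-instability profiles.

tRNA-derived fragments (tRFs) are small non-coding RNAs cleaved from
precursor or mature tRNAs.  5′-tRFs — fragments anchored at the 5′ end of
a mature tRNA — are systematically dysregulated in prostate tumors and
carry diagnostic and prognostic signal.  `trfscape` implements the full
analysis workflow a study of such fragments needs, as a tested, reusable
library with a thin CLI, plus a synthetic-data module that generates
every input with planted ground truth so the whole pipeline can be
validated without any external download.

## What it computes

| Stage | Core method |
| --- | --- |
| `trfscape.reference` | Mature (CCA-appended, intron-excised) and pre-tRNA (flanked) sequence sets; deduplicated candidate 5′-tRFs = mature prefixes of 14–32 nt |
| `trfscape.quant` | Exact full-length read assignment; RPM; 90th-quantile ≥ 1 detection filter; log2 + upper-quartile normalization |
| `trfscape.expression_stats` | Wilcoxon rank-sum DE (FDR < 0.01, \|log2FC\| > 1); top-13 classifier feature selection; guilt-by-association Pearson co-expression (\|r\| > 0.3, FDR < 0.05) |
| `trfscape.diagnostics` | RF / SVM / GLM / PLS tumor-vs-normal classifiers, 70/30 stratified split, held-out ROC/AUC |
| `trfscape.prognosis` | Univariate Cox (Wald + score test) → LASSO-Cox (10-fold CV) → multivariate Cox; tRF score ts = Σβᵢxᵢ, median split, KM/log-rank; IPCW time-dependent AUC at 1/3/5 years; bootstrap comparison of tRF+Gleason vs Gleason |
| `trfscape.subtypes` | IQR ≥ 0.5 filter; multiplicative-update NMF with restart consensus and cophenetic rank selection; consensus K-means; subtype–clinical association tests |
| `trfscape.instability` | TMB (non-synonymous/Mb); HRD = large LOH + LST + NtAI from allele-specific segments; ploidy-adjusted aneuploidy score; driver-event tables |
| `trfscape.simulate` | Planted-truth generators for all of the above |

The statistic at the core of the prognostic model is the **tRF score**,
the Cox linear predictor ts = Σᵢ βᵢ xᵢ over the signature fragments
(xᵢ = normalized log2 expression, βᵢ = multivariate Cox coefficients);
the **HRD score** is the sum of three segment-level counts: large
(>15 Mb) non-arm-level LOH regions, large-scale state transitions
(breakpoints flanked by >10 Mb segments after 3 Mb smoothing), and
subtelomeric allelic-imbalance regions.  See `docs/methods.md` for the
complete model documentation.

## Worked example

Simulate a cohort with planted segment events and score it:

```sh
$ trfscape simulate --config cfg.yaml --out cohort/ --seed 1
cohort written to cohort
$ trfscape genome --segments cohort/segments.tsv --maf cohort/mutations.tsv \
    --out scores.tsv
```

In Python, the same planted-truth loop in miniature:

```python
>>> import numpy as np
>>> from trfscape.instability import ArmModel, hrd_score
>>> from trfscape.simulate import plant_segment_profile
>>> am = ArmModel.synthetic()
>>> prof = plant_segment_profile({"loh": 2, "lst": 3, "ntai": 1},
...                              am, np.random.default_rng(0))
>>> hrd_score(prof, am)
{'loh_count': 2, 'lst_count': 3, 'ntai_count': 1, 'hrd': 6}
```

The profile embeds exactly two large LOH regions, three large-scale
state transitions and one subtelomeric allelic imbalance, and the scorer
recovers exactly those counts — the generator's plant is the oracle for
the scoring rules.

The published driver-event worked example reproduces directly:

```python
>>> from trfscape.stats import chi2_test
>>> chi2_test([[34, 12, 16, 84], [55, 40, 22, 63]])
(20.65803989536399, 0.0001239714886471489)
```

i.e. the ERG-fusion distribution across the four expression subtypes
differs with p = 1.24 × 10⁻⁴ (Pearson chi-squared, df = 3), with a
fusion prevalence of 84/147 = 57.14% in the fourth subtype.

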