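# Methods notes

## Analysis model

The pipeline treats a cohort as a genes × samples matrix of RSEM-normalized
expression values plus per-sample annotations (tissue class, pathologic
stage, overall-survival time and event).  All inference is hub-centred:
rather than an all-pairs network, each sample group's "network" is the star
of genes whose Spearman correlation with the hub satisfies
r_s ∈ (0.3, 1] with p < 0.05.  Design choices worth stating explicitly:

- **One-sided positive threshold.** Only positive correlations qualify; the
  window (0.3, 1] is read literally with strict inequalities at both ends
  (`rs_min=1.0` therefore yields an empty set).  An `use_abs` flag admits
  |r_s| for sensitivity analyses but is off by default.
- **Raw p-values.** The coexpression screen applies no multiple-testing
  correction; the thresholds are a set-definition rule, not a discovery
  claim, and downstream intersections (four stages × two cohorts) are the
  real false-positive filter.
- **Constant genes** within a group are excluded (rank correlation is
  undefined on them) and counted in the run log, never assigned r_s = 0.
- **Spearman p-value** uses the two-sided t-approximation
  t = r_s √((n−2)/(1−r_s²)), the standard behaviour of statistical packages
  at the group sizes of TCGA cohorts (tens to hundreds).  At n ≤ 8 the exact
  permutation null can differ from the approximation by up to ≈ 0.08 in p;
  the test suite bounds this at 0.1.  Perfect correlations report the
  smallest positive double rather than p = 0.
- **Mann–Whitney U** auto mode enumerates the exact null when
  n₁·n₂ ≤ 400 and the pooled sample is tie-free, otherwise the normal
  approximation with tie and continuity corrections.  All tests two-sided.
- **Log-rank** is the 1-df Mantel–Cox chi-square; the "worse" group is the
  one with the lower restricted-mean survival over the pooled follow-up.
- **Quartile split** for the prognostic arm takes samples strictly above
  the 75th / strictly below the 25th percentile (linear interpolation,
  numpy default); boundary ties fall in neither arm, which keeps the split
  deterministic and the arms disjoint.  Quartiles are computed over tumour
  samples with usable survival only, since the split exists solely to feed
  the survival comparison.
- **Percentage reporting.** Loss %, gain % and percent-DE are truncated
  (not rounded) at two decimals: truncation is the convention that
  reproduces the published renal-cohort worked examples exactly
  (125/264 → 47.34, 999/1173 → 85.16), where round-half-even would give
  47.35 / 85.17.  The cross-cohort Jaccard matrix is rendered at integer
  percent with round-half-to-even (210/1243 → 17%).
- **Set identity across cohorts** uses the Entrez ID when known, falling
  back to the symbol, so symbol aliases do not break intersections.

### Firehose dialect conventions

Tumour vs normal is decided by the TCGA barcode sample-type code (01–09
tumour, 10–19 normal; 20–29 control codes are rejected) — the files contain
no other marker.  Stage sub-letters (IA/IB/IIA/…) collapse to the parent
stage.  Clinical rows are joined on the 12-character patient prefix and a
patient's stage annotates all their tumour samples; multiple tumour samples
per patient are kept (recorded in the run log).  Missing expression values
default to dropping the gene (correlation on partially missing rows is
otherwise ill-defined); `impute_zero` is available.  Duplicate gene rows
keep the row with the larger total expression, ties by file order.

## Synthetic cohorts

`synthetic_cohort.generate` emulates exactly the structure the analysis
assumes:

- Within each group, the hub follows a standard-normal latent signal h; a
  planted gene is a·h + (1−a)·ε with loading a (`coexpr_strength`), then
  mapped through exp(6 + ·) to a positive RSEM-like scale.  Spearman
  correlation is invariant under that monotone map, so the planted rank
  correlation is governed by a alone: a = 0.95 gives near-perfect hub
  tracking, a = 0 gives the null.
- Tumour-vs-normal differential expression is a constant log-scale shift
  (default 1.0 ≈ 2.7-fold) on the configured DE genes in tumour groups.
- Methylation β-values are logit-normal: expit(logit(m_g) + 0.5·z), which
  keeps them in (0, 1) by construction; group means default to 0.6 in
  normal vs 0.3 in tumour (hypomethylation of the hub promoter).
- Survival is exponential (baseline hazard 1/1500 per day ≈ 4-year median)
  with the hazard multiplied by `hazard_ratio_high` (default 3) for tumour
  samples in the top expression quartile of the designated prognostic gene;
  censoring is independent with probability `censor_rate` (default 0.2) at
  a uniform fraction of the event time; times are rounded to whole days so
  they survive a file round-trip.
- One global seed expands into separate substreams for expression,
  methylation and survival, so enlarging the gene panel never perturbs the
  survival draws.

The bundled scenario (`default_scenario`) plants two cohorts of 1,200 genes
× 100 samples/group: a 180-gene normal module disjoint from the tumour
modules, 100-gene stage modules sliding so consecutive stages share 50
genes (planted Jaccard 1/3) and so that the intersection over all four
stages is exactly a 4-gene core common to both cohorts; core gene 1 is both
differentially expressed and the prognostic gene.  These sizes keep the
full two-cohort run at a few seconds while leaving the false-positive
budget meaningful (≈ 1,100 null genes per group against a 0.1–0.2% per-gene
false-positive rate at 100 samples).

**What passing tests do not show.**  The generator is Gaussian-copula-like:
it has no count noise (negative binomial dispersion, library-size effects),
no batch effects, no correlated non-hub modules, no copy-number or probe
artefacts, and its survival model is exponential with a single binary
covariate.  Recovery results on it demonstrate correctness of the
implementation under its own assumptions, not robustness of the thresholds
on real TCGA data.

## Numerical details

- Vectorized coexpression computes the Pearson correlation of mid-ranks for
  all genes at once; it is verified gene-by-gene against the scalar
  Spearman routine, and r_s within 1e-12 of ±1 is snapped to ±1.
- Jaccard of two empty sets is defined as 0.
- A log-rank comparison with no events in either group returns p = 1 with
  no direction; an all-censored Kaplan–Meier curve is flat at 1.
- Genes that cannot be screened (missing tissue class, < 8 usable survival
  samples, degenerate quartiles) return `passes=False` with a reason code
  rather than raising.
- `summary.json` is written with sorted keys and fixed float formatting;
  identical config + seed reproduces it byte for byte.

## Known limitations

- No Cox regression, median-split survival, or confidence bands; the
  prognostic arm is exactly the quartile log-rank screen.
- Pathway enrichment is out of scope; consistent/common gene lists are
  emitted one-ID-per-line for external enrichment tools.
- The per-stage diagnostic mode exists behind a flag but the default pools
  all tumour stages against normals.
- Statistical significance of Jaccard overlaps (e.g. hypergeometric nulls)
  is not computed; the index is descriptive.
- The loss/gain percentage definitions (loss relative to the source set,
  gain relative to the destination set) are anchored to the published
  clear-cell renal worked example, where counts, gain percentage, conserved
  count and Jaccard are mutually consistent.  The published pan-kidney
  stage III/IV figures (loss 66.29%, gain 74.19%, 16% similarity against a
  65-gene stage-IV set) cannot be reconciled with any single convention we
  tried and are treated as an erratum rather than reverse-engineered.
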