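# Methods

This note documents the statistical procedures `seropanel` implements, the
synthetic-data model it is validated against, and the design choices made
where the methodology left room.

## Seroreactivity model

Protein-microarray serology data are heavily right-skewed: most
(sample, antigen) intensities sit in a lognormal-looking background band,
with a sparse upper tail of true antibody reactions. The pipeline treats
positivity as an outlier property per antigen: the cutoff is placed at

    cutoff_a = Q75_a + 2.5 × IQR_a

over the normalized intensities of a basis sample set, and a sample is
seroreactive for antigen *a* iff its intensity is strictly greater than
`cutoff_a`. For positive calls the signal-to-cutoff ratio
`S/C = intensity / cutoff > 1` measures the strength of the reaction.

Quantiles use linear interpolation between order statistics (the common
"type 7" convention). The convention matters — on the values 1…8 it gives
Q75 = 6.25, IQR = 3.5 and a cutoff of exactly 15.0 — so it is recorded in
the cutoff-table metadata. The basis set is `all` samples by default, with
`controls`-only as a first-class option; results always record which basis
produced them, and validation cohorts recompute cutoffs internally by
default (a frozen-cutoffs mode applies discovery cutoffs instead).

Per antigen and cohort the biomarker score is

    score = N_pos × (mean S/C)^(1/3)

a product of reaction frequency and (dampened) reaction strength; the cube
root keeps a single extreme S/C from dominating the count. Antigens are
ranked by `score_diff = score_patient − score_control` and candidates must
exceed `score_diff > 5` (strict). The threshold is applied to the
difference, not the raw patient score, since the ranking that precedes it is
on the difference. No multiple-testing correction is applied at this stage
(a Benjamini–Hochberg helper exists for users who want one).

The per-sample serum score over an antigen subset S is
`Σ_{a∈S} intensity_a · 1[intensity_a > cutoff_a]` — the full intensity, not
the excess over the cutoff — and the breadth of response is the count of
positive antigens. Degenerate case: an antigen whose cutoff is ≤ 0 (possible
when it is identically zero after background flooring) is unscorable and is
excluded from calls with a warning.

## Normalization

Processing order is fixed and recorded in the matrix provenance:
background subtraction (floored at zero — negative fluorescence is
non-physical and would break the positive-median precondition) → replicate
collapse (median of the replicate spots; for four replicates, the mean of
the two central values) → QC exclusion → intra-array normalization →
quantile normalization. Re-ordering the last two changes results, so the
pipeline enforces the order.

Intra-array normalization divides each array by its overall median across
antigens, excluding control spots (antigen ids prefixed `CTRL_`); afterwards
every row median equals 1 to machine precision, and the operation is
invariant to rescaling an array. Quantile normalization sorts each array,
averages order statistics across arrays, and hands every array the averaged
values in its own rank order; tied values receive the mean of the averaged
order statistics over the tied rank range (the classic behavior of the
standard implementation), which makes the operation idempotent and
bit-reproducible.

Array QC compares each array to the reference-serum profile by Spearman
correlation (`min_rho = 0.5` by default, the threshold used for cross-site
concordance of replicate aliquots) and flags arrays whose median replicate
coefficient of variation exceeds `max_cv = 0.5`. The numeric defaults are
configuration values, not facts about any particular dataset; failed arrays
are excluded before normalization, and the counts are logged in the run
manifest.

## Two-stage panel selection

Stage 1 fits `n_runs` random forests (default 1000; the scaled-down
validation setting uses 100) of the numeric 0/1 cohort label on the
candidate antigens' normalized intensities — regression forests, matching
the "random forest regression" framing of a binary outcome, with a
classification-forest / Gini-importance mode behind a flag. Importance is
permutation importance: the mean increase in MSE of the forest's prediction
when one feature column is permuted (3 permutations per feature by default,
computed in one batched prediction for speed). Each run ranks its top 20
antigens with rank scores 20 (best) … 1; ties break by stable input order.
Per antigen, aggregation over runs yields the inclusion proportion, the
average rank score over the runs where it appeared, and their product, the
weighted mean rank (WMR). Stage 2 receives the union of all top-20 lists
(default) or the top-m by WMR.

Forest hyperparameters not fixed by the methodology — `n_trees` (default
500; 100 in the scaled-down setting), `mtry = ⌊√p⌋`, full bootstrap — are
configurable and recorded in output metadata. Every forest run derives its
seed from the master seed and its run index (`SeedSequence((master, key,
run_index))`), so the 1000-run stage is bit-reproducible and any single run
can be reproduced in isolation.

Stage 2 grows a binary CART (Gini impurity) on the stage-1 list and prunes
it along its cost-complexity path. Three pruning rules are provided:

* `cap` (default): the largest tree on the path whose distinct split
  antigens number at most `max_panel_size` (default 10). The tree here is a
  marker *selector* feeding the any-positive decision rule, not the deployed
  classifier, and the forest stage has already screened the features — that
  screening, not tree pruning, is the overfitting guard in the two-stage
  design. Selecting the pruning level by the tree's own cross-validated
  accuracy (the `1se`/`min` rules below) systematically under-fills the
  panel: a CART needs only ~3–9 strong continuous splits to classify well,
  while the any-positive rule keeps gaining sensitivity with every marker up
  to the cap. We verified this behavior against an independent CART
  implementation (R `rpart`, 10-fold CV, both min-error and 1-SE pruning),
  which selects the same small trees on the same data.
* `1se`: cross-validated 1-SE cost-complexity rule (stratified folds,
  accuracy), the classic choice for a parsimonious tree-rule classifier.
* `min`: the penalty with the best mean CV accuracy.

The panel is the tree's distinct split antigens in first-use (pre-order)
order. Both decision rules are always reported: the tree's leaf-probability
rule, and the any-positive rule (patient ⇔ seroreactive for ≥1 panel
antigen) whose integer positive-marker count also serves as a ROC score.
Cumulative any-positive sensitivity (non-decreasing) and specificity
(non-increasing) per added marker are tabulated. Training-cohort metrics are
resubstitution estimates and are optimistic; the honest estimate comes from
an independent cohort, as in `examples/05_evaluate_validation.py`.

## Statistical evaluation

AUC is the Mann–Whitney concordance probability (ties count ½), computed by
the rank formula; the ROC curve is a threshold sweep over unique scores.
Rank-sum comparisons use exact enumeration when the combined sample size is
≤ 20 without ties, otherwise the normal approximation with tie and
continuity corrections; the variant used is recorded in each result. All
tests are two-sided at α = 0.05. Kruskal–Wallis covers ≥3 groups, Spearman
paired continuous measures, and Shapiro–Wilk is available as a normality
screen that is reported but never gates the nonparametric analyses.
Cross-site concordance is per-specimen Spearman rho between two intensity
vectors with a pass threshold of 0.5.

## Synthetic-data model

The generator emulates the screen the pipeline targets, with all randomness
derived from a single seed through fixed sub-streams (antigen baselines,
planted-antigen choice, cohort draws, reference serum, QC corruption), so
that a validation cohort can redraw only the sera (`cohort_seed`) while
keeping the array and the true biomarkers.

* **Background.** Antigen baselines are lognormal, drawn once per seed:
  log-mean `ln 500` (arbitrary rfu scale), log-sd 0.8 across antigens —
  enough spread that rank correlation against the reference serum is
  informative. Per (sample, antigen) latent intensities add sample noise
  (log-sd 0.35) and a per-array batch scale factor (log-sd 0.1) that makes
  intra-array normalization non-trivial. Replicate spots add log-sd 0.15
  noise, and a small lognormal local background (log-mean `ln 50`) is added
  to each spot and recorded for subtraction.
* **Planted reactions.** A chosen number of antigens are patient-biased.
  Reactivity is a latent Bernoulli per (sample, planted antigen) — default
  probabilities 0.15 for patients and 0.02 for controls — expressed as a
  multiplicative intensity spike of 6× (log-sd 0.3). These defaults put
  single-marker sensitivity in the ~15% range at ~98–100% specificity,
  the regime where single markers are useless but panels work, and they are
  the conditions all recovery checks use. Full-scale defaults mirror the
  study design this emulates: 1627 antigens, 104 patients + 105 controls,
  quadruplicate spots; `SimConfig.recovery_default()` is the scaled-down
  setting (200 antigens, 15 planted, 100+100) used by the tests and the
  acceptance script.
* **QC failures.** With rate `qc_fail_rate`, an array's intensities are
  replaced by i.i.d. lognormal noise matched to its own scale — structure
  destroyed, scale kept — and flagged in the metadata, giving the QC stage
  a ground truth to be scored against.
* **Reference serum.** One spike-free array sharing the antigen baselines,
  under the reserved sample id `REFERENCE`.

What the generator does **not** emulate: spot-level image artifacts and
spatial effects, antigen-specific replicate variances, cross-site batch
structure beyond a scalar per-array factor, plasma-vs-serum differences,
correlated antibody responses between antigens, and per-antigen
heterogeneity in reaction probability. Passing recovery tests therefore
shows the pipeline's statistics behave as designed under a clean generative
model — not that the biological assumptions hold in any particular real
dataset.

## Numerical and reproducibility choices

* Quantile convention: type 7 everywhere (cutoffs, summaries).
* Strictly-greater-than positivity at the cutoff: a constant antigen yields
  cutoff = value and an all-negative call column.
* Ties: top-20 importance ties break by stable input order; candidate and
  WMR orderings break ties by antigen id.
* Seed scheme: `SeedSequence((master, stage_key[, counter]))`, truncated to
  31 bits where an integer seed is required; the manifest records every
  derived seed. Two runs with the same configuration produce byte-identical
  stage outputs, verified by the SHA-256 hash chain in the run manifest.
* Problem sizes in the test suite and acceptance script (200 antigens,
  100+100 sera, 100 forest runs × 100 trees, 20-seed medians, 400 null
  replicates) are the package's scaled-down validation conditions, chosen to
  exercise every stage at cohort sizes where the planted effects are
  recoverable.

## Known limitations

* Training-cohort panel metrics are resubstitution estimates; no nested
  cross-validation of the whole pipeline is attempted.
* No confidence intervals on AUC.
* The candidate threshold (> 5) interacts with cohort size: at much smaller
  sample counts the biomarker-score difference of a true marker can fall
  under the threshold, and the pipeline reports an empty candidate list
  rather than guessing.
* `rank-sum` p-values for heavily tied serum scores rely on the
  tie-corrected normal approximation; its type-I error is validated at ~5%
  under the null generator, not proven for arbitrary tie structures.
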