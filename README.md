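# seropanel

Autoantibody (AAb) seroreactivity profiling and diagnostic panel selection
for high-density protein microarrays.

Cancer sera contain autoantibodies against tumour-associated self-antigens.
Screening a serum on an array of ~1600 immobilised proteins yields, per
sample, a vector of fluorescence intensities (rfu) in which a handful of
antigens show strong, patient-biased reactions. Individually these markers
are weak — single-marker sensitivity of a few percent at near-perfect
specificity — so a diagnostic test must combine many of them into a panel.
`seropanel` implements the full path from spot-level fluorescence to a
validated marker panel, for researchers analysing serology microarray
screens (patients vs healthy controls) and for methodologists who want a
testbed with known ground truth.

## Method

Starting from replicate spot intensities (background-subtracted, collapsed
to the per-antigen median of the quadruplicate spots, QC'd against a
reference serum by Spearman correlation):

1. **Normalization.** Intra-array: each array is divided by its overall
   median intensity across antigens (row median becomes exactly 1).
   Inter-array: classic quantile normalization, forcing every array onto the
   common mean-quantile distribution while preserving within-array ranks.
2. **Seroreactivity calls.** Per antigen, the positivity cutoff is
   `Q75 + 2.5 × IQR` over a stated basis sample set. A sample is positive
   for an antigen iff its intensity is strictly above the cutoff; positive
   calls carry the signal-to-cutoff ratio `S/C = intensity / cutoff`.
3. **Biomarker scores.** Per antigen and cohort,
   `score = N_pos × (mean S/C)^(1/3)`; antigens are ranked by
   `score_diff = score_patient − score_control`, and candidates are those
   with `score_diff > 5`.
4. **Panel selection.** Stage 1: 1000 random forests (regression on the 0/1
   label, permutation importance) each contribute a top-20 list with rank
   scores 20…1; an antigen's weighted mean rank is
   `WMR = inclusion proportion × average rank score`, and the union of all
   top-20 lists goes to stage 2. Stage 2: a CART classification tree, pruned
   along its cost-complexity path until it uses at most 10 distinct split
   antigens — the panel, in first-use order.
5. **Evaluation.** The deployed decision rule is *any-positive*: a sample is
   called a patient iff it is seroreactive for ≥1 panel antigen. Reported
   alongside: the tree rule's sensitivity/specificity/AUC, cumulative
   panel metrics, per-sample *serum scores* (sum of intensities above their
   cutoffs over a stated antigen subset) compared by Mann–Whitney rank-sum,
   and ROC analysis where AUC is the Mann–Whitney concordance probability.

A synthetic-data generator emulates the screen (lognormal antigen baselines,
batch scale factors, replicate spot noise, latent Bernoulli reactions
expressed as multiplicative intensity spikes, QC-failing arrays, a reference
serum) and returns the ground truth, so every stage is testable without
access to patient data. See `docs/methods.md` for model details and
limitations.

## Worked example

```python
import seropanel as sp
from seropanel.config import stage_seed

config = sp.SimConfig.recovery_default(seed=7)   # 200 antigens, 15 planted, 100+100 sera
dataset, truth = sp.generate_cohort(config)
matrix, qc = sp.normalize_pipeline(dataset)

cutoffs = sp.compute_cutoffs(matrix, basis="all")
calls = sp.dichotomize(matrix, cutoffs)
candidates = sp.select_candidates(sp.biomarker_scores(calls, matrix.labels), threshold=5)

runs = sp.run_forests(matrix.values[candidates], matrix.labels,
                      n_runs=100, master_seed=7, n_trees=100)
stage2 = sp.select_stage2_features(sp.aggregate_runs(runs))
model = sp.fit_panel_tree(matrix.values[stage2], matrix.labels,
                          max_panel_size=10, seed=stage_seed(7, "tree"), calls=calls)

print(f"{len(candidates)} candidates; "
      f"{len(set(candidates) & set(truth.planted_antigen_ids))} planted antigens recovered")
print(f"panel ({len(model.panel)} markers): {', '.join(model.panel)}")
print(f"any-positive rule: sensitivity {model.anypos_sensitivity:.2f}, "
      f"specificity {model.anypos_specificity:.2f}, AUC {model.anypos_auc:.3f}")
```

prints:

```
15 candidates; 15 planted antigens recovered
panel (10 markers): AG_0068, AG_0067, AG_0164, AG_0006, AG_0088, AG_0007, AG_0098, AG_0156, AG_0066, AG_0117
any-positive rule: sensitivity 0.83, specificity 0.86, AUC 0.874
```

The candidate antigens each react in only ~17% of patients at ~99–100%
specificity; the 10-marker panel combines them so that one positive marker
suffices for a patient call, trading a little specificity for much higher
sensitivity. On an independent validation cohort (same array, new sera) the
same panel reaches sensitivity 0.74 / specificity 0.80 (see
`examples/05_evaluate_validation.py`) — the honest, out-of-sample estimate.

The `examples/` directory has one short script per capability (simulation,
normalization + QC, biomarker discovery, panel selection, validation). The
same stages are available from a shell:

```bash
seropanel simulate --seed 7 --prefix cohort
seropanel normalize cohort.spots.tsv --output matrix.tsv
seropanel discover matrix.tsv --outdir disc
seropanel panel matrix.tsv --candidates disc/candidates.txt --seed 7
seropanel run-all --seed 7 --outdir out && seropanel report out
```

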