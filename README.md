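# cfrag

cfDNA fragmentomics toolkit for treatment-response analysis: fragment
filtering, 4-mer 5' end-motif profiling with differential calling and the
motif-ratio statistic, promoter (TSS) coverage scores with differential gene
calling and per-gene AUC, longitudinal cfDNA concentration analytics
(the T2/T1 cfDNA ratio, paired Wilcoxon tests, SCC-Ag comparison panel),
single-lesion RECIST response labeling, IHC scoring, and ROC-based
evaluation including a multiple-logistic clinical classifier.

Because no patient data accompany the method, the package ships a fully
self-contained synthetic cohort generator (`cfrag.synthetic`) that produces a
reference genome, TSS annotations, per-sample fragment files, concentration
series and clinical tables with known planted group effects, so the entire
pipeline is testable end to end offline.

## Layout

| module | contents |
|---|---|
| `cfrag.synthetic` | synthetic cohort generator + ground truth |
| `cfrag.fragment_io` | fragment records/frames, SAM collapsing, fragment-table dialect, retention filters with exact accounting |
| `cfrag.end_motif` | 256-category end-motif profiles, differential motifs, motif ratio, terminal-base fractions |
| `cfrag.tss_coverage` | per-base depth, TSS scores, differential TSS genes, gene-set overlap, per-gene AUC |
| `cfrag.concentration` | concentration series, cfDNA ratio, paired time-point tests, SCC-Ag panel, correlations |
| `cfrag.response_labeling` | RECIST classification, IHC expression score |
| `cfrag.evaluation` | Mann-Whitney/Wilcoxon/Kruskal-Wallis, BH q-values, rank AUC + bootstrap CI, clinical covariate binarization, logistic classifier |
| `cfrag.pipeline` / `cfrag.cli` | end-to-end orchestration and the `cfrag` command |

## CLI

```sh
# generate a synthetic cohort (FASTA, TSS table, fragment tables, clinical
# and concentration tables, ground-truth JSON)
cfrag simulate --out cohort/ --seed 7

# post-alignment retention rules with per-rule accounting
cfrag filter --in cohort/fragments/R01.tsv --out R01.filt.tsv --stats stats.json

# end-motif profile / differential motifs / motif ratio
cfrag motif profile --fragments R01.filt.tsv --ref cohort/reference.fa --out R01.motifs.tsv
cfrag motif diff --group-a a1.tsv --group-a a2.tsv --group-b b1.tsv --group-b b2.tsv \
    --lfc 0.04 --alpha 0.05 --out diff.tsv
cfrag motif ratio --profile R01.motifs.tsv --increased inc.txt --decreased dec.txt

# TSS scores, differential genes, per-gene AUC
cfrag tss score --fragments R01.filt.tsv --fragments R02.filt.tsv \
    --ref cohort/reference.fa --tss cohort/tss.tsv --out scores.tsv
cfrag tss diff --scores scores.tsv --labels labels.tsv --out tss_diff.tsv
cfrag tss auc --scores scores.tsv --labels labels.tsv

# concentration analytics and labeling
cfrag conc ratio --table cohort/concentrations.tsv
cfrag conc paired-test --table cohort/concentrations.tsv --a T1 --b T2
cfrag label recist --clinical cohort/clinical.tsv
cfrag label ihc --intensity 2 --area-fraction 0.5

# ROC evaluation
cfrag eval roc --scores ratios.tsv --labels labels.tsv --positive non-responder

# whole pipeline from a YAML config (synthetic mode)
cfrag run --config run.yaml --out out/ --seed 3
```

`run.yaml` mirrors `PipelineConfig` (all keys optional):

```yaml
synthetic:
  seed: 3
  n_responders: 12
  n_nonresponders: 8
  fragments_per_sample: 20000
motif_lfc_threshold: 0.04
tss_lfc_threshold: 0.5
bootstrap_reps: 2000
motif_discovery_split: false   # true = held-out motif-ratio AUC
classifier_cross_validated: false  # true = leave-one-out classifier probabilities
```

Re-running with the same config and seed reproduces every output file
byte-identically.

## Conventions

- Coordinates are 0-based half-open throughout (BED convention); SAM input
  is converted at the boundary.
- Filters default to the published retention rules: MAPQ >= 30, <= 5
  mismatches, proper pairs only, insert size < 600 bp, duplicates and
  multi-mapped templates dropped. Removed fragments are charged to the first
  failing rule in a fixed documented order.
- The non-responder group is the positive class in every ROC, and motif/TSS
  fold changes are non-responder over responder.
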