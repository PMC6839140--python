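# methcap

Derivation and evaluation of a triple-negative (TN) breast-cancer-specific
CpG methylation signature from subtype-labelled beta-value matrices, with:

- **methio** — TSV I/O for beta matrices, probe annotation, receptor status
  and clinical tables; receptor-based subtype assignment (TN / HER2p /
  luminal) and 10-year survival capping.
- **preprocess** — probe QC filtering (detection p, SNP, cross-reactive,
  sex-chromosome), per-sample two-peak M-value ("peak-based") normalization,
  and probe-to-gene collapse by the most negative methylation–expression
  correlation.
- **diffmeth** — empirical-Bayes moderated-t differential methylation
  (moment-matched prior on log s²), Benjamini–Hochberg adjustment, and the
  intersection signature of the luminal-vs-TN and HER2p-vs-TN contrasts;
  overall-profile ANOVA.
- **cluster_purity** — Ward hierarchical clustering (Euclidean or 1−r),
  cluster purity curves over cuts k=1..10, PCA projection and a linear
  (max-margin) separation check.
- **classify_eval** — bagged decision trees with an OOB-tuned per-tree
  leaf-node cap scanned over 1..n−1, ROC/AUC, and confusion-matrix metrics
  (per-class F1, MCC, diagonal sum).
- **survival** — univariate Cox proportional hazards (Breslow ties,
  Newton–Raphson) with score/logrank test, Kaplan–Meier curves, per-site
  favorable/unfavorable direction calls, the averaged per-sample prognostic
  score, and median-split stratification.
- **enrichment** — one-sided Fisher's-exact (hypergeometric tail) gene-set
  over-representation against GMT collections with BH FDR and GeneRatio.
- **synthetic_cohort** — a generator for methylation/expression/clinical
  cohorts with planted subtype-differential CpGs, negatively correlated
  expression and planted survival effects, so every stage is testable with
  no external data.
- **pipeline** / CLI — end-to-end orchestration from a flat key=value
  config.

## CLI

```sh
methcap simulate --out fixture/ --seed 1            # synthetic cohort
methcap preprocess --betas betas.tsv --annotation annot.tsv --out filtered.tsv
methcap diffmeth --betas filtered.tsv --receptors receptors.tsv --out dm.tsv
methcap cluster --betas sig.tsv --receptors receptors.tsv --out purity.tsv
methcap classify --train tr.tsv --train-receptors r1.tsv \
                 --test te.tsv --test-receptors r2.tsv --out report.tsv
methcap survival --betas sig.tsv --clinical clinical.tsv \
                 --directions-out dirs.tsv --scores-out scores.tsv
methcap enrich --genes genes.txt --gmt sets.gmt --out enrichment.tsv
methcap run --config config.txt --outdir run/                # full pipeline
```

The pipeline config is a flat `key=value` file; required keys are
`discovery_betas`, `validation_betas`, `annotation`, `discovery_receptors`,
`validation_receptors`, `discovery_clinical` (optional: `gene_sets`,
`detection_p`, `alpha_dm`, `alpha_surv`, `distance`, `max_k`, `n_trees`,
`scan_trees`, `seed`). Relative paths resolve against the config file.
All outputs are TSV with a provenance header line (`# methcap stage=...
config_hash=...`); reruns with an identical config are bit-identical.

## Conventions

- Beta values in [0,1]; M = log2(β/(1−β)) for normalization/simulation.
- Subtypes: luminal = ER+ or PR+; HER2p = ER−PR−HER2+; TN = ER−PR−HER2−;
  unknown deciding markers exclude the sample.
- Signature direction "hyper" = higher methylation in the non-TN group
  relative to TN; both contrasts are oriented non-TN minus TN.
- Survival times are capped at 120 months at read time (events beyond the
  cap become censored at 120).
- Prognostic score = per-sample fraction of signature sites in the
  survival-favorable median-split state.
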