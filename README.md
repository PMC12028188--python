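# tyromark

Multi-model machine-learning ranking of routine follow-up biomarkers by
their ability to predict alpha-fetoprotein (AFP) alteration in tyrosinemia
type 1 cohorts, exercised end-to-end on a synthetic cohort generator
(the clinical datasets the method was designed for are not publicly
available).

The pipeline:

1. **synthetic** — generates per-visit follow-up records for three cohorts
   (A/B/C) with right-skewed biomarker distributions, a planted logistic
   dependence of AFP-altered status on configurable covariates (ALT,
   alkaline phosphatase, age variables by default), patient-level HCC
   status, and MCAR missingness at per-cohort rates.
2. **preprocess** — record eligibility filtering (≥70% of the 15 modeled
   variables, AFP and SUAC present), AFP binarization at 5 ng/mL
   (strictly-above = altered), chained-equations imputation, and an
   optional 2-D UMAP embedding for cohort-overlap visualization.
3. **association** — Spearman screen of every variable against AFP with
   pairwise deletion, Kruskal–Wallis + Dunn post hoc comparisons, and an
   Anderson–Darling normality gate.
4. **multimodel** — repeated rounds of fresh stratified 70:30 splits of
   cohort A, randomized hyperparameters, gradient-boosted-tree training,
   and evaluation (AUROC + mean-|SHAP| per feature) on the internal test
   set and the external cohorts; rounds with internal AUROC > 0.7 are
   retained. SHAP values come from a built-in path-dependent TreeSHAP
   implementation (numba-accelerated, verified against brute-force Shapley
   enumeration).
5. **consensus** — corrected importance (mean over retained rounds of
   SHAP × AUROC), per-cohort rankings, pairwise importance-distribution
   tests, and hierarchical consensus clustering of variables across
   cohorts (run with and without age variables).
6. **ablation** — four-variable logistic regression with leave-one-out
   ablation over the consensus candidates on a shared 60/20/20 partition.
7. **cutoff** — per-patient means, Youden-optimal ALT threshold for HCC
   discrimination with a stratified bootstrap AUC CI, and the combined
   AFP+ALT screening table.

## CLI

```bash
tyromark simulate --out records.csv --seed 1
tyromark associate --records records.csv --out association.csv
tyromark preprocess --records records.csv --out prep/ --seed 1
tyromark multimodel --records records.csv --out mm/ --rounds 200 --seed 1
tyromark rank --rounds-file mm/rounds.jsonl --features ntbc,phe,... --out rank/
tyromark ablate --records records.csv --variables alt,alkaline_phosphatase,age_at_diagnosis,age_at_control --out ablation.csv
tyromark cutoff --records records.csv --variable alt --out cutoff.json
tyromark all --out run/ --rounds 200 --seed 1          # full pipeline
tyromark all --config pipeline.yaml                    # or from a config file
```

`tyromark all` writes every artifact (records, association screen,
imputed matrices, retained rounds as JSON-lines, importance tables,
rankings, cluster trees, ablation report, cut-off and screening tables)
plus a `manifest.json` echoing the configuration and seeds needed to
reproduce the run bit-for-bit.

Example YAML config:

```yaml
output_dir: run
synthetic:
  seed: 1
  cohort_sizes: [20, 10, 5]
n_rounds: 5000
auc_threshold: 0.7
master_seed: 1
```

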