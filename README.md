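# quiescence-mirnome

A tested, reusable re-implementation of the computational pipeline behind a
microRNA study of fibroblast quiescence:

* **miRNA differential expression** (`mirna_diffexp`) — total-intensity
  normalization, a per-feature linear model with quiescence / serum-starvation /
  isolate indicators plus a data-driven surrogate variable (residual-SVD with a
  permutation null), a nested-model F test on the quiescence coefficient,
  Benjamini–Hochberg FDR, and reconstruction of per-condition responses with a
  Fisher-z Pearson confidence interval comparing the two quiescence signals.
* **Eigengene analysis** (`eigengene_analysis`) — SVD of the 16-array mRNA
  timecourse, a per-gene *proliferation index* (projection on the first
  eigengene, oriented so the deepest-quiescence array is negative), variance
  fractions, and centroid-linkage hierarchical clustering.
* **Target-set enrichment** (`target_enrichment`) — context-score filtering of
  predicted microRNA target sets and a two-tailed bootstrap p-value for each
  set's mean proliferation index against same-size random gene sets
  (zero-exceedance results are reported as a `< 1/N` bound).
* **Overexpression target calling** (`overexpression_targets`) — one-sided
  t tests on replicate log2 fold changes, two-fold + FDR "changing" calls,
  intersection with conserved predictions (P_CT filter), ECDF/KS target-vs-
  non-target comparison, and percent-repression conversion.
* **Phase-composition statistics** (`cellcycle_dirichlet`) — maximum-likelihood
  Dirichlet fits via alternating mean/precision updates (digamma fixed point +
  safeguarded Newton) and a likelihood-ratio test on χ²(3) comparing
  transfections to a control, plus the pooled-residual phase summary.
* **Synthetic data** (`synthetic_data`) — seeded generators for every pipeline
  input with planted, recoverable structure (responsive miRNAs, a hidden batch
  pattern, a dominant quiescence-depth expression pattern, an enriched target
  family, repressed genes, per-group Dirichlet concentrations).
* **Orchestration** (`cli_pipeline`) — a single entry point running every
  stage end to end with a JSON report including planted-truth recovery
  metrics.

## Command-line usage

Run the full pipeline on synthetic data:

```sh
quiescence-mirnome synth --seed 1 --out pipeline_out
```

or from a YAML config (`synthetic: false` mode takes TSV paths for each
input; see `cli_pipeline.PipelineConfig`):

```sh
quiescence-mirnome run --config cfg.yaml
```

Stage-level tools: `mirna-diffexp`, `eigengene`, `target-enrich`,
`call-targets`, `phase-lrt` (each has `--help`).

All TSV formats are plain tab-delimited text with `NA` for missing values;
see `core_io` docstrings for the exact column contracts.

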