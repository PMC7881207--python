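# tsnet

Correlation-network scoring of tumor-suppressor (TS) genes in tumor/normal
expression cohorts.

Given a log-scale expression matrix, per-sample metadata and candidate TS
gene lists, the pipeline:

1. checks replicate quality via Pearson correlation (`qc`);
2. finds differentially expressed (DE) genes per tumor stage with a Welch
   t-test and Benjamini–Hochberg FDR control (`diff_expression`);
3. defines the TS gene set as DE genes intersected with candidate lists,
   minus an optional denylist (`ts_selection`);
4. computes the TS×DE Pearson correlation matrix and a Bonferroni-calibrated
   correlation threshold `T = |t| / sqrt(t² + df)` with
   `t = t-quantile(alpha/m, n−2)` (`correlation_scores`);
5. scores each TS gene: `S⁺` (share of positive correlation mass at or above
   `T`), `S⁻` (mirror for negative mass), `S` (signed supra-threshold sum);
6. binarizes the correlations into positive/negative networks and computes
   shared-node `N⁺`/`N⁻` ratios (thresholded vs sign-only sharing), plus
   edge-list exports (`network_scores`);
7. builds ranked score-accumulation curves and the largest plus/minus gap
   (`accumulation_profiles`).

A seeded synthetic-cohort generator (`synthetic_data`) plants strong TS
genes (down-shifted, factor-loaded), weak TS genes (down-shifted,
uncorrelated), co-varying down-/up-regulated DE blocks and null genes, with
machine-readable ground truth, and drives the test suite end to end.

## CLI

```bash
# write a synthetic cohort (expression.tsv, samples.tsv, truth.tsv)
tsnet simulate --seed 1 --out cohort/

# full pipeline on a simulated cohort
tsnet run --simulate --seed 1 --out results/

# full pipeline from files (config file optional; flags win over config)
tsnet run --expression expr.tsv --samples samples.tsv \
          --ts-list list1.txt --ts-list list2.txt \
          --stage 2 --alpha 0.05 --tails one --out results/

# S/N score table for explicit TS and DE gene lists
tsnet scores --expression expr.tsv --samples samples.tsv \
             --ts-list ts.txt --de-list de.txt --out scores.tsv

# replicate-pair QC
tsnet qc --expression expr.tsv --pairs pairs.tsv --out qc.tsv
```

`tsnet run` writes `de_table.tsv`, `ts_genes.tsv`, `threshold.tsv`,
`score_table.tsv`, `network_pos_edges.tsv`, `network_neg_edges.tsv`,
`accumulation.tsv` and `run_report.json`; identical config + seed gives
byte-identical TSVs.

### File formats

- **Expression matrix** — TSV, header `probe_id<TAB>sample1<TAB>...`, one
  probe per row, log scale (`linear_scale` applies log2(x+1) at load).
- **Sample table** — TSV with columns
  `sample_id condition stage subject_id smoking`; condition is
  `normal`/`tumor`, unknowns are `NA`.
- **Gene lists** — one identifier per line, `#` comments allowed.

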