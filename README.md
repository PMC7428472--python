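# crosskingdom

Analysis toolkit for two-kingdom (bacterial 16S + fungal ITS) gut microbiome
case/control studies:

- **table_io** — abundance-table I/O (taxa×samples TSV, BIOM v1.0 JSON),
  QIIME-style lineage parsing and rank collapsing, relative abundance,
  major-genus (mean RA ≥ 0.01) and prevalence (strictly > fraction) filters,
  cross-kingdom sample alignment.
- **diversity** — alpha indices (Shannon in nats, reciprocal Simpson,
  bias-corrected Chao1, ACE with rare cutoff 10), Bray-Curtis and
  unweighted/weighted UniFrac distances, PCoA, PERMANOVA group tests,
  rank-sum alpha comparisons, optional rarefaction.
- **lefse** — differential-abundance screen: per-sample normalization to
  1e6, per-taxon Kruskal-Wallis/rank-sum filter (p < .05), bootstrapped
  linear-discriminant effect size; features reported at |LDA score| > 2,
  signed positive for the reference (control) group.
- **networks** — within-kingdom Spearman correlation networks and
  interkingdom distance-correlation networks with permutation significance
  (raw p < .05, no multiplicity correction by default; Benjamini-Hochberg
  optional); relative connectedness (edges/nodes) and Mann-Whitney degree
  comparisons; TSV edge lists and GraphML export.
- **classifier** — multivariable logistic regression on genus-panel relative
  abundances (presets: `bacterial4`, `fungal4`, `combined8`), rank-based
  AUC, stratified bootstrap 95% CI; apparent or repeated stratified-CV
  evaluation (the CV estimate is the honest one).
- **simulate** — synthetic two-group, two-kingdom count tables via a
  Gaussian copula on log abundances (exact planted latent correlation
  matrices, planted log2 fold-changes, multinomial counting at sampled
  depths) with recoverable ground truth.
- **pipeline / CLI** — end-to-end orchestration with one YAML config, fixed
  seeds, and a hashed run manifest.

## CLI

```bash
crosskingdom simulate --scenario default --seed 1 --out-dir sim/
crosskingdom diversity --bact-table sim/bacteria_counts.tsv \
    --metadata sim/metadata.tsv --mode alpha --out alpha.tsv
crosskingdom lefse --bact-table sim/bacteria_counts.tsv \
    --metadata sim/metadata.tsv --reference-group HC --out lefse.tsv
crosskingdom network --bact-table sim/bacteria_counts.tsv \
    --fungi-table sim/fungi_counts.tsv --metadata sim/metadata.tsv \
    --mode interkingdom --group HC --prevalence 0.2 --permutations 199 \
    --seed 1 --out edges.tsv
crosskingdom classify --bact-table sim/bacteria_counts.tsv \
    --fungi-table sim/fungi_counts.tsv --metadata sim/metadata.tsv \
    --panel combined8 --case-group CDE --seed 1 --out clf.tsv
crosskingdom run --config config.yaml        # full pipeline
```

`crosskingdom run` writes per-stage TSVs plus `manifest.json`; identical
configs and seeds reproduce bit-identical outputs (the manifest hash covers
every output file).

## Notes

- Group-separation testing uses PERMANOVA (999 permutations by default).
- Apparent (resubstitution) AUC is reported for comparability; prefer
  `--cv 5` for an honest estimate at small n.
- Edge significance is deliberately uncorrected (p < .05) to match the
  networks being reproduced; pass `fdr=True` to the network builders for
  Benjamini-Hochberg control.
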