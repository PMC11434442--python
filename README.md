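# rhizonet

Co-occurrence network analysis for rhizosphere community profiles. The
package takes taxon-abundance count tables (samples × taxa, TSV) plus
taxonomy and sample-metadata tables, and produces:

- filtered abundance tables (read-depth ≥ 10,000; mean relative abundance
  ≥ 0.001, both configurable),
- all-pairs Spearman correlations with Benjamini–Hochberg FDR adjustment,
- a correlation-magnitude cutoff chosen by random-matrix-theory eigenvalue
  spacing statistics (with a configurable fallback),
- undirected weighted co-occurrence networks (edges require both
  `p_adj < 0.01` and `|rho| ≥ threshold`; positive correlations only by
  default) with degree, weighted degree, closeness, betweenness, and
  clustering per node,
- community modules by greedy hierarchical modularity maximization
  (CNM-style, deterministic tie breaking),
- keystone taxa by a five-criterion centrality filter, functional-category
  classification from a taxon × EC gene-presence table, and
  ANOVA/Tukey-HSD group comparisons with compact letter displays,
- per-stratum orchestration (3 domestication groups × 2 fertilization
  levels plus two combined networks), phylum connection shares,
  chord-diagram matrices, and GEXF export,
- a synthetic-data generator (latent-factor lognormal–multinomial) with
  planted correlation modules, hub taxa, and a stratum-dependent network
  density gradient, used throughout the tests.

## CLI

```sh
# generate a synthetic dataset (abundance/taxonomy/metadata/gene tables + ground truth)
rhizonet simulate --preset paper-like --seed 42 --out data/

# filter an abundance table
rhizonet filter --abundance data/abundance.tsv --min-reads 10000 \
    --min-mean-abund 0.001 --out filtered.tsv

# run the full per-stratum pipeline (writes metrics, modules, chord
# matrices, GEXF graphs, keystone reports, and a manifest.json)
rhizonet run --abundance data/abundance.tsv --taxonomy data/taxonomy.tsv \
    --metadata data/metadata.tsv --out networks/
```

An optional YAML config (`--config run.yaml`) controls filters, the
threshold grid (`threshold.grid_min/grid_max/grid_step/fallback`, or
`threshold.optimize: false` with `threshold.fixed`), `alpha`,
`positive_only`, and the keystone criteria.

## Layout

| module | contents |
| --- | --- |
| `rhizonet.datasets` | abundance/taxonomy/metadata tables, TSV I/O, sample and taxon filters |
| `rhizonet.correlation` | all-pairs Spearman (mid-rank Pearson, t-approximation p-values), BH FDR |
| `rhizonet.threshold` | RMT eigenvalue-spacing threshold scan |
| `rhizonet.network` | graph construction, node metrics, network summaries |
| `rhizonet.community` | greedy agglomerative module detection, modularity |
| `rhizonet.keystones` | keystone filter, EC-based function catalog, ANOVA + Tukey HSD |
| `rhizonet.pipeline` | per-stratum orchestration, phylum shares, chord matrices, GEXF |
| `rhizonet.simulate` | synthetic community generator and paper-like preset |
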