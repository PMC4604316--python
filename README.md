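# rhizopan

Compartment-aware comparative analysis for panels of bacterial isolates
sampled from two isolation compartments (rhizosphere / endosphere):

* **pan-genome partitioning** — collapse OrthoMCL-style ortholog groups
  into a binary presence matrix and classify every cluster by its
  occupancy (`all` / `some` / `none`) in each compartment, yielding the
  compartment Venn decomposition (core, compartment-exclusive and
  shared accessory clusters) plus per-genome accessory averages;
* **consensus identity** — per-column majority consensus of a
  pre-aligned marker gene and percent similarity of every sequence to
  it (gaps and `N` neither vote nor count);
* **trait enrichment** — Pearson chi-square tests (no continuity
  correction) for compartment non-homogeneity of binary traits, with a
  label-permutation p-value as the recommended small-sample result and
  an optional Benjamini–Hochberg correction;
* **carbon utilization** — per-strain substrate counts,
  all/none/differential partitions, pooled per-class bias tests and
  top-k biased compound ranking for phenotype-microarray matrices;
* **model validation** — confusion counts and accuracy of metabolic-model
  growth predictions against observed utilization, predicted/observed
  core-compound sets, and compartment bookkeeping of model reactions;
* **synthetic data** — seeded generators for every input, with an exact
  planting mode (recover counts bit-perfectly) and a Bernoulli mode
  (power / type-I simulations).

All inputs and outputs are plain text: ortholog groups text, TSV
matrices and label tables, aligned FASTA, YAML/JSON configs.

## CLI

```sh
# write a complete synthetic input bundle (default: study-shaped
# profile with 4 + 15 strains, 190 compounds, 1500-site marker)
rhizopan simulate --out bundle --seed 7

# run every stage from the bundle's config
rhizopan all --config bundle/config.yaml

# individual stages
rhizopan pangenome --groups groups.txt --labels labels.tsv --out venn.tsv
rhizopan consensus --alignment aln.fasta --out similarity.tsv
rhizopan enrich --traits traits.tsv --labels labels.tsv \
    --alpha 0.05 --permutations 1000 --seed 0 --out enrichment.tsv
rhizopan carbon --utilization util.tsv --labels labels.tsv \
    --classes classes.tsv --alpha 0.01 --out carbon_reports/
rhizopan validate --predictions pred.tsv --observations util.tsv \
    --reactions reactions.tsv --labels labels.tsv --out validation/
```

Every report is TSV with one `#` header line recording the tool
version, seed and thresholds; identical config + seed reproduce every
file byte for byte.

## Layout

```
src/rhizopan/
  io_cli/        readers/writers, domain types, config, pipeline, CLI
  pangenome.py   occupancy Venn partition, accessory averages, summaries
  consensus.py   majority consensus + similarity scoring
  enrichment.py  chi-square + permutation non-homogeneity tests
  carbon.py      utilization partitions, class bias, top-k compounds
  validation.py  prediction scoring, core compounds, reaction Venn
  simulate.py    seeded generators (exact planting + Bernoulli modes)
  reference.py   bundled panel statistics and published category counts
  data/          study-shaped simulation profile (YAML)
```
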