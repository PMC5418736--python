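# agelink

Gene-set overlap analysis linking longevity-modulating genes to age-related
disease genes. The package covers the full pipeline:

* **catalog** — GMT / TSV ingestion, longevity-set assembly (per-organism
  anti/pro sets with dual-annotation exclusion, pooled ortholog sets) and
  disease-catalog filtering (minimum gene count, age-related class list,
  eye-class-at-class-level-only rule, respiratory negative control).
* **pbc** — publication-bias correction: per-gene publication-count
  filtering, threshold sweeps, per-set mean/median summaries.
* **overlap** — the core engine: hypergeometric upper-tail p-values,
  expected overlap, the dual significance rule (observed > expected AND
  p < alpha), background policies (genome / interactome / seed unions) and
  shared-gene (CAD) extraction; a Benjamini–Hochberg column is emitted for
  reference.
* **network** — interaction-graph summaries (degree, mean local clustering,
  connected core), within/between edge partition, first-order and
  co-expression expansion, random-set degree nulls, publication–degree
  Spearman correlation.
* **cadprops** — shared-gene frequency profiles, hub (degree) comparisons,
  dN/dS group comparisons (Mann–Whitney, Bonferroni), enrichment-score
  transforms.
* **drugrank** — direction-aware drug scoring: interaction-type
  classification (Anti / Pro / Neither, shipped 44-type default map),
  one-tailed hypergeometric enrichment of direction-matched targets,
  Bonferroni-ranked output.
* **synthetic** — deterministic benchmark generator (preferential-attachment
  network, degree-correlated publication counts, planted set overlaps at a
  controlled odds ratio, co-expression pairs, drug tables, shifted dN/dS)
  with a planted-truth manifest.
* **pipeline / cli** — end-to-end orchestration with plain-TSV + JSON
  outputs; byte-identical re-runs.

## Test

```sh
python -m pytest -q
```

## CLI

```sh
agelink simulate --seed 0 --n-genes 5000 --out bundle/
agelink run-all --bundle bundle/ --out run/
agelink pbc-sweep --sets bundle/aging.gmt --pubs bundle/pubs.tsv --min 8 --max 20 --out sweep.tsv
agelink overlap --sets bundle/aging.gmt --diseases bundle/diseases.tsv \
    --universe bundle/universe.tsv --level class --out grid.tsv
agelink drugs --interactions bundle/drugs.tsv --sets bundle/aging.gmt \
    --universe bundle/universe.tsv --out drugs_ranked.tsv
```

`run-all` executes the stage sequence — baseline overlap grids,
publication-bias-corrected grids, interactome-restricted grid, first-order
and co-expression expansion grids, shared-gene properties, dN/dS
comparisons and drug ranking — writing one TSV per stage plus
`summary.json`.

## File formats

All inputs and outputs are plain text: gene sets as GMT; disease catalogs
as TSV (`disease_id`, `class`, `gene`); edges as TSV (`gene_a`, `gene_b`,
optional `interaction_type`, filtered by default to physical association /
direct interaction); per-gene annotations as TSV keyed by `gene`;
co-expression pairs as TSV (`gene_a`, `gene_b`, `p`).

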