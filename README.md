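# phenomap

Cross-ontology mapping of Human Phenotype Ontology (HPO) terms to Gene
Ontology (GO) terms from annotation co-occurrence, and phenotype-term
prediction for proteins built on those mappings.

## The problem

HPO annotations link human genes to the phenotypic abnormalities their
disease-causing variants produce; GO annotations link the same genes to
molecular functions, processes and cellular components. GO coverage of the
gene space is far broader than HPO coverage. If a phenotype term and a GO
term keep turning up on the *same* genes, the lost function plausibly
explains the abnormality — and that link can transfer phenotype annotations
to the many proteins that have GO annotations but no HPO annotations.
`phenomap` is for computational biologists who want to build such term-term
mappings from annotation corpora, prune the ones that arise by chance, and
benchmark the resulting protein→phenotype predictions with the CAFA-style
metrics used in the function-prediction community.

## The method

For every HPO term *i* and GO term *j* that share at least one annotated
gene, the co-occurrence similarity is the Dice-style ratio

    S(i, j) = 2 · n_ij / (N_i + N_j)

where `n_ij` is the number of genes annotated with both terms and `N_i`,
`N_j` are each term's total gene counts. `S` lies in (0, 1]; `n` is a second
reliability parameter, because two rarely-annotated terms can reach S = 1 on
a single shared gene purely by chance.

Chance pairings are pruned by a permutation null: gene identities in the HPO
corpus are relabeled by a random bijection (every per-term count is
preserved, the cross-ontology coupling is destroyed) and the mapping table
is rebuilt. For each candidate threshold pair (s_min, n_min) on a grid, both
tables are filtered and their binned similarity distributions compared with
a two-sample Kolmogorov–Smirnov test; the lowest thresholds at which the
observed table significantly diverges from the null (p < 0.01) are selected,
and mappings failing them are discarded.

A protein annotated with GO term *j* then receives HPO term *i* with
probabilistic score `S(i, j)` (the maximum over its GO annotations).
Predictions are scored against benchmark annotation sets with protein-centric
precision/recall/Fmax (plain and information-content-weighted), the minimum
semantic distance Smin = min_τ √(Ru(τ)² + Mi(τ)²), term-centric AUROC, and
coverage — with true-path-rule propagation applied to both predictions and
truth.

## Worked example

Everything below runs on a synthetic corpus with 50 planted HPO–GO
associations (3–6 co-annotated genes each) over 1,000 genes plus random
background annotations, so there is a known ground truth:

```python
import phenomap as pm

config = pm.SyntheticConfig(seed=7)
hpo, go, truth = pm.generate_planted_dataset(config)

raw = pm.build_raw_mapping(hpo, go)
null = pm.build_raw_mapping(
    pm.randomize_annotations(hpo, seed=1007), go, provenance="null")

grid = pm.select_thresholds(raw, null)
mappings = pm.filter_mapping(raw, *grid.selection)
preds = pm.predict_hpo(mappings, go)
```

which prints, with the counts reported by each stage:

```
corpora: 532 HPO and 634 GO annotations over 306 shared genes
raw mapping: 310 term pairs; null mapping: 493
selected thresholds: S >= 0.0, n >= 2 (alpha = 0.01)
filtered mapping: 53 pairs (50/50 planted recovered)
predictions: 362 (protein, HPO term) pairs for 319 proteins
```

The raw table mixes the 50 planted pairs with ~260 chance co-occurrences;
the null table is pure chance. The KS scan finds that requiring at least two
co-annotated genes (n ≥ 2) already separates the observed distribution from
the null, and the filtered table recovers all 50 planted pairs while
discarding 99% of the chance pairs. The same stages are available from the
shell as `phenomap simulate`, `phenomap map`, `phenomap predict` and
`phenomap evaluate`; every run writes a manifest with input hashes, the seed
and all parameters, and identical invocations produce byte-identical files.

## Layout

- `src/phenomap/ontology.py` — OBO parsing, DAG validation, ancestor
  closure, true-path-rule propagation, information content
- `src/phenomap/annotations.py` — HPO/GO annotation table I/O, evidence
  filtering, the `AnnotationSet` container
- `src/phenomap/mapping.py` — co-occurrence similarity and mapping tables
- `src/phenomap/resampling.py` — permutation null, similarity histograms,
  KS machinery, threshold-grid selection
- `src/phenomap/prediction.py` — HPO-term prediction and CAFA exchange format
- `src/phenomap/evaluation.py` — Fmax / weighted Fmax / Smin / term-centric
  AUROC / coverage
- `src/phenomap/simulate.py` — synthetic corpora, toy ontologies, benchmark
  generators
- `src/phenomap/cli.py` — the `phenomap` command

See `docs/methods.md` for the modelling choices, parameter defaults and
known limitations.
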