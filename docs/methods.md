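# Methods

This note records the statistical model behind `phenomap`, the parameter
defaults and why they were chosen, what the synthetic-data generators do and
do not emulate, and the numerical conventions a maintainer should know
before changing anything.

## Co-occurrence mapping

The unit of evidence is the deduplicated (gene, term) annotation pair.  The
HPO corpus is read from the `genes_to_phenotype` dialect (asserted
annotations only, by default — propagating the inputs up the DAG is an
explicit flag, since propagation also multiplies any false-positive source
annotation); the GO corpus from a QuickGO-style TSV or GAF 2.1, keeping the
thirteen curator-assigned evidence codes (EXP, IDA, IPI, IMP, IGI, IEP,
IBA, IC, IKR, ISS, NAS, ND, TAS) and dropping electronic (IEA) annotations
unless explicitly included.  The two corpora join on the exact,
case-sensitive gene symbol; no alias resolution is attempted, because
silent symbol aliasing would change the mapping counts invisibly.

For each HPO term *i* and GO term *j* with at least one shared gene the
mapping record stores the co-annotation count `n_ij` and the similarity
`S = 2 n_ij / (N_i + N_j)`.  `N_i` and `N_j` are whole-corpus gene counts,
not counts within the joined gene subset: the similarity is a property of
each term's full annotation profile, and restricting the denominators to the
shared genes would inflate S for terms that are mostly annotated outside the
join.  Records are kept in lexicographic (hpo_id, go_id) order so that every
serialization is reproducible byte-for-byte.

## Permutation null and threshold selection

The null model relabels the gene identities of the HPO table by one uniform
random bijection (optionally over a wider gene universe).  This preserves
every per-term count and each table's internal degree structure exactly,
while destroying the cross-ontology coupling; the expected null
co-annotation count for a pair with totals (N_i, N_j) over G genes is the
hypergeometric mean N_i·N_j/G.  Relabeling only one table is sufficient —
the coupling is a property of the joint assignment — and relabeling both is
available as a flag.

Filtering thresholds are selected on a grid (defaults: S ∈ {>0, ≥0.1, …,
≥0.6}, n ∈ {≥1, …, ≥5}, i.e. 35 cells).  For each cell both tables are
filtered, their S values are histogrammed over (0, 1] in half-open bins
(default width 0.02; a value equal to a bin edge falls in the bin whose
upper edge it is), and the two binned distributions are compared with a
two-sample Kolmogorov–Smirnov test:

- The KS distance D is taken between the two count-weighted cumulative
  distributions over the bins at or above the cell's similarity cut.
- The *number of bins* — not the number of mappings — acts as the effective
  sample size on both sides when D is converted to a p-value (classic
  asymptotic two-sample formula with the Stephens small-sample correction).
  Per-bin frequencies within one table are strongly dependent, because the
  same term-degree structure populates many bins at once; treating every
  mapping as an independent observation would declare microscopic
  distribution differences significant at any realistic corpus size and the
  scan would terminate at the weakest possible thresholds.  With bins as the
  sampling units the test only reacts to gross shape divergence, which is
  exactly the signal of interest: a filtered observed table that still looks
  like the filtered null has not yet shed its chance pairings.
- A cell where either histogram occupies fewer than 3 bins is reported as
  `insufficient` (no statistic), mirroring the untestable cells that heavy
  filtering produces.

The scan walks similarity thresholds outward and co-annotation-count
thresholds inward: at each S level every n level is tried before the S cut
is raised, and the first cell with p < alpha (default 0.01) is selected.
The rationale for the scan order is that raising n discards whole mappings
by evidence volume, while raising S discards them by profile shape; the
gentler evidence-volume cut should be exhausted before the shape cut is
tightened.  On planted-signal corpora this selects (S > 0, n ≥ 2): a single
shared gene is never accepted as evidence, matching the observation that
singleton co-occurrences reach arbitrarily high S by chance.  If no cell is
significant the selection is absent and the command-line front end falls
back to the grid maxima with a warning.

No multiple-testing correction is applied across the 35 cells: the scan is
a sequential search for the first significant cell, not 35 simultaneous
inferences.  Per-pair exact tests (e.g. Fisher) are deliberately out of
scope — most pairs have far too few co-annotated genes for per-pair power.

## Prediction

A filtered mapping table acts as a rule set: each protein receives every
HPO term reachable through its GO annotations, scored with the mapping's S
(already in (0, 1], usable directly as a probabilistic score).  When
several GO terms map to the same HPO term for one protein, the maximum S
wins, with ties broken toward the lexicographically smallest supporting GO
id for determinism.  Predicted ontology roots are suppressed when an
ontology is supplied.  Predictions are *not* propagated to ancestors at
emission time by default — the evaluator propagates internally, and emitted
files stay small — but pre-propagated output is a flag.  Scores below a
floor (default 0.01, the resolution of the two-decimal CAFA exchange
format) are dropped.

## Evaluation

Both truth and predictions are propagated by the true path rule (is_a and
part_of edges only; other relationship types are ignored with a log line)
and ontology roots are removed from both sides before comparison.
Propagation of a score map assigns each ancestor the maximum score over its
predicted descendants, which makes thresholding-then-propagating equal to
propagating-then-thresholding at every τ.

At each score threshold τ (default grid 0.01, 0.02, …, 1.00):

- precision is averaged over proteins with at least one prediction at τ;
- recall is averaged over all benchmark proteins in `full` mode, or over
  predicted proteins in `partial` mode;
- Fmax is the maximum harmonic mean of the two over the grid, and the
  weighted variant replaces set cardinalities with sums of per-term
  information content;
- remaining uncertainty Ru(τ) and misinformation Mi(τ) are per-protein
  means of the information content of missed and spurious terms, and
  Smin = min_τ √(Ru² + Mi²).  The all-predictions-discarded point is always
  included in the Smin scan, because the minimum can sit there (predicting
  a heavy wrong term can cost more than predicting nothing).
- a τ with zero predicted proteins contributes precision 0 (flagged by the
  predicted-protein count) and F = 0 rather than NaN.

Information content is estimated as information accretion: for term v with
parent set P, ia(v) = −log2 of the fraction of entities annotated with all
of P that also carry v, computed on a propagated corpus (roots therefore
carry 0 bits).  Base 2 is the default and configurable.  Truth terms
without an information-content estimate are dropped with a warning by
default (`missing_ic="error"` makes this fatal); the per-protein mean
convention is used for Ru/Mi.

Term-centric AUROC treats each benchmark term independently: positives are
universe proteins whose (propagated) truth contains the term, negatives are
the rest of the universe (closed world within the benchmark, not the whole
proteome), scores are the propagated prediction scores with 0 for missing
predictions, and ties are handled by the rank-average (Mann–Whitney)
convention.  Terms with no positives or no negatives are excluded and
reported.  Coverage is the fraction of benchmark proteins with at least one
prediction at any score.

## Synthetic data

`generate_planted_dataset` emulates the statistical structure the mapping
method assumes: a shared gene universe in which some HPO–GO pairs are
genuinely co-annotated (the planted signal) on top of independent Bernoulli
background annotations.  Defaults: 1,000 genes, 150 HPO terms, 200 GO
terms, 50 planted pairs seeded on 3–6 genes each (pairwise-disjoint gene
blocks, so planted pairs do not cross-contaminate), background probability
0.002 per (gene, term) — about two background annotations per term, giving
a raw table in which chance pairings outnumber planted ones roughly five to
one.  The corpus is sized so the full pipeline runs in seconds on one CPU.
Setting `n_planted_pairs=0` yields a pure-noise corpus for null-behaviour
checks.  An optional power-law gene-degree mode is *not* implemented: the
generator does not reproduce real HPO/GO term-frequency distributions, hub
terms, or disease–gene etiology, so passing tests demonstrate correct
mechanics and statistical behaviour of the pipeline, not real-data
performance.

`generate_toy_dag` builds random rooted DAGs (a random tree plus optional
extra is_a edges, always pointing from later to earlier terms, hence
acyclic by construction).  `generate_benchmark_case` builds a flat toy
ontology and a balanced prediction/benchmark pair in which every protein is
scored on every term of a shared pool; the `separability` parameter
interpolates between exchangeable positive/negative scores (0) and
perfectly separated ones (1), so downstream metrics have known limits
(macro AUROC 0.5 and 1.0 respectively, Fmax = 1 and Smin = 0 at full
separation).

## Numerical conventions and degenerate inputs

- Histogram bin indices are computed with a 1e-9 relative guard so exact
  bin-edge ratios (e.g. S = 0.1 at width 0.1) land in the lower-exclusive
  bin deterministically.
- The generic two-sample KS helper uses scipy's exact method for small
  samples and the asymptotic approximation otherwise; samples shorter than
  a configurable minimum (default 3) yield an `insufficient` status rather
  than an error.
- Empty corpora, empty joins and empty mapping tables produce empty results
  with warnings (or distinct exit codes 2/3/4 in the CLI); an empty
  benchmark is a hard error because coverage is undefined.
- Obsolete ontology terms are retained but flagged and never carry edges;
  alternate ids resolve to their primary term at parse time; annotations to
  terms absent from the ontology are dropped with a warning by default.
- All randomness flows through explicit integer seeds via numpy's
  `default_rng`; every CLI run records its seed, parameters and input
  hashes in a manifest, and identical invocations are byte-identical.

## Known limitations

- The gene-symbol join is exact; symbol drift between corpus snapshots
  silently reduces the shared universe.
- The threshold scan returns a single global threshold pair; no per-pair
  significance is attempted (by design, see above).
- The evaluator is a faithful re-implementation of the standard
  protein-centric and term-centric metrics but is not intended to be
  bit-compatible with any particular external evaluation toolkit.
- Mapping one HPO term to multi-aspect GO term combinations is out of
  scope.
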