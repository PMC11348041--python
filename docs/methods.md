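# Methods

## Inference model

A chemical's candidate disease terms are scored by over-representation
analysis (ORA). Let the universe be the set of genes with at least one
Disease Ontology annotation after ancestor propagation (size *N*), the
target the chemical's interacting proteins intersected with that universe
(size *n*), and for each term let *K* and *k* be the annotated genes in
universe and target. The one-sided p-value is the hypergeometric upper tail
P(X ≥ k) (scipy's survival function, which works in log-combinatorics and
is exact at double precision); p-values are Benjamini–Hochberg adjusted
across all terms tested within one run — one (chemical, mode, tissue,
level) combination, never across chemicals — and terms with adjusted
p < alpha (default 0.05) are reported. Only terms hit by at least one
target gene are tested; depletion is never tested. Result ordering is
(adjusted p, term id), so identical inputs give byte-identical reports.

Annotations are propagated to all `is_a` ancestors before testing (the
true-path rule); only `is_a` edges are traversed, other relationship types
are ignored. Propagation can be disabled (`propagate=False` /
`--no-propagate`) since an ORA can also be run on direct annotations only.

## The tissue expression filter

The augmented mode removes, before testing, every interactor whose
expression in the selected tissue does not strictly exceed the threshold of
the selected stringency. Values exactly at a threshold are filtered out, at
every level, in both numeric dialects. Defaults:

| dialect | low | medium | high | unit |
|---|---|---|---|---|
| rna_tpm | 0.5 | 1 | 5 | TPM |
| protein_ppb | 500 | 1000 | 1500 | ppb |
| protein_semiquant | keep {2,3} | keep {3} | keep {3} | ordinal level |

On the 3-level semi-quantitative scale only three levels exist, so the
medium and high filters necessarily coincide; this is documented behaviour,
not an oversight. Thresholds apply to raw values; the 0.01 pseudo-count and
log10 transform exist only for the distribution summaries
(`log_summary`, `summarize-expression`), never for filtering.

An empty cell in an expression TSV means *not measured*, which is distinct
from zero. Interactors absent from the dataset (or unmeasured in the
tissue) are dropped by any filter level other than `none` under the default
`missing_gene_policy="drop"` — absence of evidence of expression should not
rescue a gene from a tissue filter — with `"keep"` available for the
opposite convention. `level=none` applies no filtering at all and
reproduces the conventional protein set exactly.

With `background="filtered"` (default) the universe is restricted by the
same tissue filter as the target, so the background ratio K/N refers to the
same tissue-expressed gene population as the gene ratio k/n;
`"unfiltered"` keeps the global annotated universe instead. Both are
legitimate ORA conventions; the filtered default avoids comparing a
filtered foreground against an unfiltered background.

## Evaluation

Inferred terms are restricted to the tissue's disease vocabulary before
rates are computed — each tissue's vocabulary is the set of DO terms whose
name or exact synonym matches the tissue name as a case-insensitive whole
word (substring matching available). On restricted association sets *x*
(inferred) and *y* (curated): discovery rate = |x∩y|/|y|, enrichment rate =
|x∩y|/|x|. A rate with an empty denominator is undefined; undefined
chemicals are excluded from averages (and counted) rather than scored
zero, because a chemical with no curated kidney disease says nothing about
kidney recall. Two aggregation modes are provided: per-chemical averaging
(`evaluate_disease_inference`) and pooling the association pairs across
chemicals per tissue (`evaluate_chemical_identification`). Improvements
are reported as absolute percentage-point differences by default; a
relative-percent mode exists because "X% improvement" phrasing is ambiguous
in the literature. Tissues with few associated diseases make rates noisy,
so `top_k_tissues` selects the k best-annotated tissues (descending count,
lexicographic tie-break for reproducibility).

## Synthetic bundles

`toxinfer.simulate` generates the complete input set from one seeded
`numpy` Generator; a manifest records the config and per-file sha256
checksums, and regeneration from the same config is byte-identical.

The ontology is a random DAG: one branch per tissue under a single root,
each branch a random tree of depth ≤ `ontology_depth` plus occasional
second parents (always earlier in the branch, so acyclicity holds by
construction). Term names embed the tissue keyword, so keyword matching
recovers each branch as that tissue's vocabulary.

Background expression is log-normal per gene × tissue with ln-mean −1 and
ln-sd 2, chosen so the fixed 0.5/1/5 TPM thresholds fall near the 56th /
69th / 90th percentile of background values — the same regime in which the
published thresholds sit (average percentiles in the 57–75 range on real
RNA-seq tissue panels). The ppb dialect uses ln-mean ln(700) so the
500/1000/1500 thresholds are similarly interior. Tissue-specific genes
(`frac_tissue_specific`, default 0.3) get a ×200 multiplicative shift in
their home tissue, floored just above the high threshold. 2% of background
cells are left unmeasured to exercise the missing-data path.

Each planted (chemical, term, tissue) triple wires in three gene groups,
drawn from disjoint blocks of the gene pool:

* 8 **signal** genes annotated to the planted term, 6 expressed above the
  high threshold in the tissue and 2 forced below the low threshold — true
  mechanism, partly tissue-silent;
* 5 genes supporting a **sacrificial** curated sibling term, all below the
  low threshold — a true association the filter must lose, so discovery
  cannot improve under filtering;
* 3 decoy terms × 6 genes each, same branch, all below the low threshold —
  false leads the conventional method enriches and the low filter removes
  by construction.

All planted interactions score 750–999 (above the default 700 cut); noise
interactions to background genes (rate 0.01 per chemical × gene) span
150–999. Curated truth is the planted term, its in-branch ancestors and
the sacrificial term, per chemical. Defaults (500 genes, 50 terms, 4
tissues, 10 chemicals) keep a full 20-seed benchmark under a few seconds.

What the generator does **not** emulate: realistic STITCH score
distributions, correlated expression across tissues, annotation bias toward
general terms, incomplete curation, or identifier-mapping noise. Passing
tests therefore demonstrate that the pipeline's machinery and the
direction of the precision/recall trade-off are correct, not that any
particular improvement magnitude transfers to real databases.

## Numerical and degenerate-input choices

* BH adjustment delegates to `statsmodels.multipletests(method="fdr_bh")`;
  the test suite cross-checks it against an independently coded step-up
  formula to 1e−12 and asserts permutation invariance.
* The hypergeometric tail is cross-checked against exhaustive enumeration
  of all draws for every parameter combination with N ≤ 12.
* Empty target set, unknown chemical, or a filter that removes every
  partner produce an explicit empty report (with a flag), never an error.
* A value exactly equal to a threshold never passes; quartile summaries use
  linear-interpolation percentiles (numpy default).
* Tie-breaks everywhere are lexicographic (term id, tissue name) for
  determinism.

## Known limitations

* Protein and gene identifiers are assumed to share one namespace; an
  optional two-column map handles simple renamings only.
* No GO/KEGG/pathway enrichment, no term–term dependency corrections
  (parent–child ORA), no semantic similarity.
* The evaluation bench measures precision/recall-like rates only; accuracy
  and specificity are deliberately absent because the curated truth is
  incomplete (unknown associations are not true negatives).
* Benchmark magnitudes are properties of the synthetic generator's effect
  sizes; only their sign and ordering are claimed.
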