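# Methods

## Model

`overrep` performs over-representation analysis: for a query gene list
and each gene set in a collection, it asks whether the overlap is larger
than expected if the query were a uniform draw from a reference
background.  The sampling model is the central hypergeometric
distribution on the 2×2 table (N, n, K, k) — background size, query
genes in background, set genes in background, and overlap — and the
reported p-value is the upper tail P(X ≥ k).  The one-sided Fisher exact
test is mathematically identical to this tail and is exposed under both
names; the identity is asserted in the test suite rather than assumed.
The χ² test (Pearson, 1 df) is provided for large tables; it is a
two-sided large-sample approximation and the implementation warns
whenever any expected cell count falls below 5.  Over-representation
(the upper tail) is the default everywhere; depletion is not a use case
of this tool, though a two-sided Fisher option exists.

Assumptions worth stating: genes are exchangeable under the null
(no gene-length or GC bias modeling), the background honestly reflects
the assayable universe, and the query is a set (duplicates carry no
weight — they are removed and reported, not counted).  Query and set
members outside the background are dropped before counting and fully
itemized in the query audit, since silently keeping them would inflate
n or K relative to N.

## Multiple testing

Six family-wise/FDR procedures are implemented in-package as the step
procedures they are (Bonferroni; Holm step-down; Hochberg step-up;
Hommel's closed-testing shortcut over Simes local tests; Benjamini–
Hochberg step-up; Benjamini–Yekutieli, i.e. BH with the harmonic factor
c(m) = Σ 1/i).  The default is Benjamini–Yekutieli: tested gene sets
overlap heavily (GO ancestors contain their descendants by
construction), so the arbitrary-dependence guarantee is the honest one.
The family is all sets tested in the run, pooled across categories; a
per-category family mode exists because per-category displays are a
common reporting convention, but pooling is the default since the user
sees — and acts on — one combined ranking.  Adjusted values are compared
against statsmodels' implementations at 1e-12 in the tests; the package
deliberately does not call statsmodels at run time so that the test is a
genuine two-route check.

Significance selection is strict (`p_adj < cutoff`, default 0.05), with
ties broken by larger overlap then name so output order is total and
deterministic.

## Ontology propagation

The ontology is a DAG with child→parent `is_a` and `part_of` edges;
other relationship types are dropped with a warning, following the
true-path convention that only these two relations license annotation
inheritance.  Propagation materializes, for every term, the union of
genes directly annotated to the term or to any descendant — computed in
one pass over a topological order, and verified in tests against a
brute-force repeated-edge-expansion closure.  Namespaces are node
attributes; because namespace roots are disjoint, propagation never
crosses them without needing an explicit check.  Terms left empty after
propagation get no gene set, so "every term becomes a set" means every
term with evidence.

The hierarchy chart of significant terms is the induced subgraph of the
significant set plus all ancestors, emitted as Graphviz DOT (rendering
is the user's concern).  Node fill encodes the adjusted-p bin with
default edges {1e-10, 1e-5, 0.01, 0.05} on a dark-to-light four-step
ramp — bin edges are configurable and carry no inferential meaning, they
are display resolution.  Ancestor-only context nodes stay uncolored.
Node order, edge order and label formatting are all sorted/fixed so the
output is byte-deterministic.

## Identifier handling

IDs are case-sensitive and whitespace-stripped by default; plant locus
conventions make case folding unsafe, so case-insensitive matching and
transcript-suffix stripping (`.1`-style) are opt-in CLI flags.
Locus/symbol/probe relations are many-to-many; conversion keeps every
target of every input (no "best" pick), because any arbitration would
silently bias K and k downstream.  Enrichment always runs in locus
space: probe or symbol queries are expanded first and the expansion
(unmapped inputs, one-to-many fan-outs) is recorded in the conversion
report.  The `_at`-suffix probe heuristic is advisory only; a declared
`--id-type` always wins, and a mixed-looking list without a declaration
is an error rather than a guess.

## Synthetic data

The fixture generator emulates a desk-scale enrichment study.  Defaults:
a 5,000-gene universe; 200 sets of 20–100 genes (sizes uniform over the
range, members uniform without replacement, categories assigned
round-robin over the four categories); a 150-gene query with signal
fraction 0.5, i.e. 75 genes drawn from one planted set and 75 from the
rest of the background; a layered random DAG (single root, 1–3 parents
per term drawn from earlier terms, ~80% `is_a`, Poisson(3) direct
annotations per term); and a mapping table with 0–2 symbols and 0–3
probes per locus, 10% of probes attached to a second locus.  One integer
seed feeds an independent named RNG stream per generator, so adding a
generator never shifts existing fixtures.

Planted sets are drawn uniformly among sets large enough to carry their
share of the signal; a configuration in which no such set exists is an
error.  Without this eligibility constraint, a 75-gene signal frequently
cannot be realized from a single 20–100-gene set and the scenario would
be ill-posed.

What the generator does not emulate: correlated gene membership
(pathway co-occurrence), realistic set-size or annotation-depth
distributions, gene-length/GC ascertainment bias, or noisy ID mappings.
Passing tests therefore demonstrate statistical and algorithmic
correctness under exchangeability — not robustness to the biases of any
real annotation corpus.

## Numerical choices

- Hypergeometric tails come from scipy's log-space survival function; no
  normal approximation anywhere in the exact tests.  Exhaustive
  comparison against an exact integer-rational tail sum over all ~46,000
  tables with N ≤ 30 bounds the error at ~3e-16.
- p-values are clamped to [0, 1] after vectorized computation to absorb
  last-ulp excursions.
- An adjusted p of exactly 0 (possible only by underflow) is floored at
  1e-300 in the −log10 chart data so plot values stay finite.
- Coverage percentages are rounded to one decimal in display frames;
  the underlying counts are exact and kept.
- k = 0 sets are retained with p = 1 in the full result list (the
  annotation table must stay complete) but can never pass the strict
  significance cutoff.
- Set-size filter defaults are permissive (min 2, max = background
  size) and configurable; a singleton set cannot be "enriched" in any
  meaningful sense, hence the minimum of 2.

## Problem sizes

The test suite and the acceptance script use: exhaustive table
enumeration at N ≤ 30; 1,000 random p-vectors of length up to 500 for
the correction cross-check; 1,000 null-query replicates against 200
sets; 100 seeded planted-recovery runs at the default scenario; and 100
random DAGs of up to 200 terms for propagation.  These sizes make every
check exhaustive or tightly concentrated while keeping a full run in the
low minutes on one core.

## Known limitations

- GMT carries no category information, so a collection read without a
  metadata sidecar is all-Curated until told otherwise.
- The OBO reader targets the 1.2 subset used by GO/PO distributions:
  `[Term]` stanzas, `is_a`, `relationship: part_of`, obsolete flags.
  Intersections, cross-products and typedef semantics are out of scope.
- The χ² path reports the standard two-sided p; users comparing it
  against the one-sided exact tests should halve it themselves (the
  cross-consistency test in the suite does exactly that).
- No π₀ estimation or permutation nulls; FDR control relies on the
  step-up procedures' guarantees.
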