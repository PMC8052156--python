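# Methods

This note documents the statistical and algorithmic choices behind
phytonet: what each stage computes, the parameters that matter, what the
synthetic-data generator does and does not emulate, and the numerical
conventions.

## Ingredient screening

A compound is admissible when OB ≥ `ob_min` (percent, default 30) and
DL ≥ `dl_min` (unitless, default 0.18). Both comparisons are inclusive —
the convention reads "not less than" — and can be made strict via
`ScreenConfig(inclusive=False)` for sensitivity analysis. The screen is
idempotent and monotone: raising either threshold can only remove
compounds.

The literature merge is a union keyed on molecule id only, because names
vary across sources (the packaged fixture itself contains a compound
known under two names, acteoside/verbascoside). The screened entry wins a
conflict; literature-only entries are flagged `source="literature"`. The
packaged Plantaginis Herba table retains 11 of 15 rows under the default
screen; one of those 11 also appears in the five-compound literature
list, so the merged set is 15 unique molecules either way. (Published
descriptions of this herb's screen sometimes quote 10 database-derived
actives; one borderline compound, eupatorin at OB 30.23 / DL 0.37,
satisfies the stated rule, so we apply the rule as written and note the
discrepancy here rather than special-casing it.)

## Target sets and the Venn stage

Gene symbols are compared case-insensitively and stored uppercased.
Normalization against an identifier service is replaced by a flat,
user-supplied raw→symbol lookup table; unmapped identifiers are dropped
by default (with a logged count), which keeps the downstream intersection
conservative — an identifier nobody could map should not create a common
target. `policy="keep"` retains them verbatim for exploratory runs.

Disease sources are plain per-source gene lists. Aggregation reports
per-source sizes next to the deduplicated union; the n-way
`venn_report` gives exclusive region counts for any number of sets, so
the two-set drug/disease diagram and the five-way source overlap use the
same machinery. Wherever a gene set is serialized it is sorted
lexicographically, which is what makes whole-pipeline reruns
byte-identical.

## PPI topology and core-target selection

Networks are simple undirected `networkx.Graph`s throughout; readers
collapse duplicate and reversed edges and drop self-loops with a logged
count. A STRING-style third column in an edge list is treated as a
confidence score and filtered only if `min_score` is given (default:
keep all edges, since no universally right cutoff exists).

Closeness centrality comes in two normalizations:

* `standard`: |R(v)| / Σ_{u∈R(v)} d(v,u), with R(v) the set of nodes
  reachable from v (v excluded); an isolated node scores 0.
* `wf_scaled` (default): the standard value times |R(v)|/(N−1)
  (Wasserman–Faust). This is the default because it remains meaningful on
  disconnected graphs, where the unscaled value over-rewards tiny
  components.

The core rule selects nodes with degree ≥ mean degree **and** closeness ≥
mean closeness, means over **all** nodes of the analyzed network
(including isolated ones) and comparisons inclusive. On a
vertex-transitive graph every node is core, which is the intended
degenerate behaviour. Both centralities are computed by networkx and are
cross-checked in the test suite against a hand-written all-pairs-BFS
oracle on hundreds of small random graphs.

The tripartite ingredient–target–pathway network retains the genes of the
selected pathways that occur in the association table, the ingredients
with at least one association to a retained gene, and all selected
pathway nodes; edges are the ingredient–target associations plus the
target–pathway memberships. Pathway selection is deliberately a user
input (`selected_terms`) because the choice of "disease-relevant"
pathways is a judgment call; `top_k` (default 6, the typical number
hand-picked in such studies) falls back to the smallest adjusted
p-values. Ranked outputs break ties lexicographically by node id.

## Over-representation analysis

The enrichment test is the one-sided hypergeometric upper tail
P(X ≥ k | N, K, n), evaluated as a log-space sum of log-pmf terms
(log-gamma binomials + logsumexp), which is stable for the extreme tails
that planted signals produce. The DAVID-flavoured EASE variant
(substituting max(k−1, 0)) is available via `mode="ease"`; the exact
hypergeometric is the default, a deliberate divergence from web-service
behaviour in favour of the textbook test. The implementation is verified
in the tests against exhaustive draw-enumeration for every parameter
combination with N ≤ 12 and against `scipy.stats.hypergeom.sf` at larger
sizes; scipy is the cross-check, not the implementation.

The default background universe is the union of all annotated genes of
the database, the conventional choice when no explicit background is
supplied; a user list is supported (`universe="user_list"`). Query genes
outside the universe are dropped with a logged count. Terms with zero
overlap are omitted from the output: they carry p = 1 and would only
inflate the BH denominator. Benjamini–Hochberg step-up (via statsmodels,
validated against the direct formula q_(i) = min_{j≥i} p_(j)·m/j) is
applied within one namespace at a time. Because practice is split on
whether studies threshold raw p (< 0.01) or FDR (< 0.05), both flags are
computed and reported side by side.

## Synthetic data: what it emulates, and what it does not

The generator produces every pipeline input with planted, recorded truth.
Defaults were chosen once to mirror a typical single-herb study's
magnitudes:

| parameter | default | rationale |
|---|---|---|
| gene universe | 2000 symbols `G000001…` | large enough to hold both pools; synthetic names avoid implied biology |
| merged ingredients | 15 (10 screened + 5 literature) | typical screened-compound count |
| targets per ingredient | NB(mean 30, dispersion 10), ≥ 1 | ~30 predicted targets per compound |
| druggable pool | 300 genes | gives an expected drug-target union ≈ 233 |
| disease sources | 65/196/668/6/0, overlap 0.2, pool 1200 | expected union ≈ 760–780 |
| planted common targets | 41 | the drug∩disease overlap, exact by construction |
| interactome | ER, 188 expected edges on the 41 | mean degree ≈ 9.2 |
| planted hubs | 3, +20 edges each | pushes degree ~3σ above the mean |
| annotation terms | 100 background + 3 planted, sizes U[100, 200] | pathway-sized gene sets |
| enrichment factor | 8 | planted terms over-sample query genes eightfold |

The druggable and disease pools intersect exactly in the 41 planted
genes, and each planted gene is forced into at least one ingredient's
target list and into the largest disease source — so the pipeline's
common-target set equals the planted overlap *exactly*, not just in
expectation. With term size ~150 of a 2000-gene universe and factor 8,
a planted term's expected overlap with the 41-gene query is ≈ 22 genes
against a null mean of ≈ 3, which is why planted terms are recovered at
FDR < 0.05 in essentially every seed; with factor 1 the same machinery is
an honest null. Each generator stage draws from
`SeedSequence(seed, spawn_key=(stage,))` with fixed stage indices, so
every component is a pure, byte-reproducible function of (config, seed).

What the generator does **not** emulate: realistic interactome topology
(only Erdős–Rényi and a Poisson configuration model are provided — no
scale-free degree tails, no clustering), correlated annotation terms
(real GO terms nest; synthetic terms are sampled independently),
compound chemistry, and database-specific biases in disease-gene
curation. Passing the recovery tests therefore shows the pipeline's
*bookkeeping and statistics* are right under known truth; it does not
certify performance on real interactomes or real annotation DAGs.

## Numerical and operational conventions

* All tabular output is TSV, sorted; networks export to TSV/SIF/GraphML.
* The pipeline halts with a stage-named error (and writes the partial
  report) on any failure; an empty common-target set stops the run before
  the PPI stage, since every later stage would be vacuous.
* The run report embeds the configuration echo (minus the output
  directory) and SHA-256 checksums of all inputs, so identical inputs are
  verifiable from the report alone.
* Problem sizes in the test suite: oracle equivalence enumerates all
  hypergeometric urns with N ≤ 12 and 500 random graphs of ≤ 12 nodes;
  recovery uses 100 generator seeds; the null calibration uses 1000
  replicates of a 100-term database. These sizes make the full suite run
  in well under a minute while keeping the binomial error of the measured
  rates small.
* The floating-point tolerances: oracle comparisons at rel. 1e−9
  (enumeration) or 1e−12 (closed-form transcriptions); recovered counts
  are compared exactly.

## Known limitations

* "Compactness" as reported by some network tools is implemented as
  closeness centrality, the standard degree-companion attribute; a study
  using a different definition would need a custom profile function.
* The enrichment stage tests each term independently; GO-DAG-aware
  methods (elim/weight) and rank-based (GSEA-style) methods are out of
  scope.
* Identifier normalization is a flat lookup; one-to-many mappings are not
  supported (the table is many-to-one by construction).
* Published per-database target counts depend on database versions and
  query dates and are treated as descriptive context, not reproducible
  quantities; the synthetic generator matches their magnitudes instead.
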