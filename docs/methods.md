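# Methods

## Model and assumptions

The package treats gene-family evolution as a presence/absence character on
a rooted, purely topological species tree. Branch lengths are read and
discarded: phylostrata are ordinal internodes, not time, so every statement
is about topological depth. Polytomies are accepted and never resolved; a
consensus tree assembled from literature is expected to be partially
unresolved.

Under Dollo parsimony a family originates exactly once. The unique
minimum-loss single-origin reconstruction then places the gain at the LCA of
the family's extant species set and a loss on every maximal subtree below
the gain node that contains no carrier. Rather than running an explicit
dynamic program, presence at a node v is evaluated with the closed form

    present(v)  ⇔  gain-node ancestor-or-equal of v  ∧  subtree(v) ∩ species ≠ ∅

and the loss phylostratum on a focal lineage is the first path position
where presence switches off. The equivalence of this closed form with a
brute-force enumeration over all single-gain choices and loss-branch
subsets is not assumed: `dollostrat.exhaustive` checks it over every rooted
shape with up to 6 leaves (bifurcating and multifurcating, 2543
shape×pattern combinations) and verifies along the way that the minimum-loss
solution is always unique. Shapes rather than labeled trees are enumerated:
since every presence/absence pattern over the leaves is tested, relabelings
are isomorphic and add nothing.

Two structural rules follow from the reconstruction and are enforced rather
than merely documented. A loss can never be reported earlier than two
phylostrata after the gain, and never before ps3; the exhaustive sweep
shows the bound ps3 is attained. A gain at ps k with a loss at ps k+1 is
reachable only through a polytomy and means the family is specific to a
side branch; such families are excluded from the lineage and written to a
side-channel report (`excluded.tsv`) instead of being silently dropped.

The terminal singleton filter — species-specific clusters with fewer than
two member proteins are removed — is implemented globally. A single-species
cluster can only ever be assigned to that species' terminal phylostratum on
its own lineage, so the global rule is equivalent to applying the filter
per lineage at the terminal stratum.

The whole-tree union of events is computed directly (one gain at the LCA,
one loss per maximal carrier-free branch) rather than by deduplicating 
per-lineage runs; a test asserts that every per-lineage event is contained
in the direct union and that all lineages agree on each family's gain node.

## Enrichment statistics

Each (term, phylostratum, direction) is a 2×2 table: k term-carrying
families with the event at that stratum, n families with the event there,
K term carriers in the universe, N universe size. The universe is the set
of families with an event of the requested direction on the lineage — all
event families for gains, loss-bearing families for losses, and optionally
the loss-bearing subset for gains too (`lost_only`), which is the right
universe for comparing gain-side against loss-side enrichment on an equal
footing.

* Two-sidedness uses the minimum-likelihood convention (sum of all
  outcomes whose pmf does not exceed the observed one), the standard exact
  convention for Fisher-type tests; "two-tailed" alone does not pin down a
  convention, so this choice is documented here. pmf values within a
  relative 1e-9 are treated as tied, absorbing floating-point noise in
  symmetric tables. Against exact integer enumeration over all ~635,000
  achievable tables with N ≤ 60 the maximum absolute deviation is below
  1e-12. One caveat worth writing down: the two-sided p is ≥ the *smaller*
  one-sided tail, not the upper tail specifically — for depletion-side
  observations the upper tail can exceed it.
* Effect sizes are log2 odds ratios with +0.5 added to all four cells
  (Haldane–Anscombe), keeping k = 0 and k = n tables finite and making the
  statistic antisymmetric under swapping the annotated column.
* BH correction (statsmodels step-up) is applied, by default, jointly
  across all (term, ps) pairs of one focal species × run × direction — the
  conservative pool; a `per_term` switch restricts the pool to one term's
  strata. Significance means adjusted p < α, with α = 0.05 by default.
* Families with no transferred annotation carry the reserved pseudo-term
  `NA`: they stay in N and the `NA` row is itself testable, so annotation
  sparsity is visible rather than silently shrinking the universe.
* Records with k = 0 are kept — depletion is a legitimate two-sided
  outcome.

Annotation transfer is either *any-member* (the family carries the union of
its members' terms) or *fraction* (≥ 50% of member proteins, threshold
inclusive, unannotated members counted in the denominator — the conservative
reading; fraction-mode terms are provably a subset of any-member terms). GO
identifiers are flat labels; no DAG propagation is attempted, the
annotation tool's export is taken as-is.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `c` label | study-defined | alignment-coverage cutoff of the upstream clustering run; the default grid `c_grid()` is 0.0–0.8 in 0.1 steps (9 runs). The package never clusters; c is a run tag that keys every output table. |
| `alpha` | 0.05 | significance level on adjusted p |
| `transfer_mode` | `any` | annotation transfer rule (`any` / `fraction`) |
| `universe_mode` | `all` | enrichment universe for gains (`all` / `lost_only`) |
| `bh_scope` | `joint` | BH pool (`joint` / `per_term`) |
| `loss_prob` q | 0.1 | generator: per-branch loss probability below the gain node, in [0, 1) |
| `paralog_mean` | 1.5 | generator: mean of the geometric per-species paralog count (support ≥ 1) |
| `background_rate` | 0.1 | generator: per (family, term) background annotation rate |

## The synthetic generator

`simulate` draws, per family: a gain node (uniform over nodes or explicitly
weighted), independent branch losses with probability q strictly below the
gain node (a lost branch prunes its whole subtree — no regain, matching the
inference model so that parameter recovery is well-posed), geometric paralog
counts for surviving species, and protein ids `species|family|index` so the
prefix species convention applies. Families losing every species are
regenerated so the family count is exact; the regeneration count is kept in
the ground truth. Annotations are planted per (term, ps, enriched rate,
background rate) relative to the *inferred* event table of one focal
lineage, with remaining terms scattered uniformly. A `violation_rate`
option plants a second, Dollo-violating origin to exercise the
mis-assignment paths.

What the generator does **not** emulate: clustering noise (families are
exact partitions — no split/merged homologs, no contamination), multiple
origins or horizontal transfer (except the explicit violation mode),
correlated losses across branches, annotation errors, and any relationship
between the c label and the partition other than the one the study scripts
choose. Passing tests therefore demonstrate correctness of the
reconstruction and statistics under the Dollo model, not robustness to
clustering artifacts in real proteomes.

When survivors of a family are confined to one child clade of the true gain
node, its LCA — and hence the inferred gain — is the shallower node; this
is an identifiability limit of presence/absence data, not an implementation
artifact, and the ground-truth comparison in the test suite measures it
rather than hiding it.

## Validation studies and problem sizes

The acceptance script and `analysis/05_validate.py` recompute, from
scratch: the exhaustive loss-bound and oracle sweeps (all shapes ≤ 6
leaves), the exact-test sweep (all tables N ≤ 60), and three seeded
simulation studies sized to run in seconds on one CPU — planted recovery
(12-leaf caterpillar, 400 families, half the gain mass on the 6th path
node, term rate 0.8 vs 0.1 background, 100 replicates; detection means the
planted (term, ps) record is significant at adjusted p < 0.05), null
calibration (same regime with rate 0.1 everywhere; fraction of significant
records pooled over 100 replicates), and the burst regime (16-leaf
caterpillar, 70% of gain mass on the 2nd path node, q = 0.12, 150 families,
100 replicates; checked for a content peak strictly before the terminal
phylostratum). The conservation study checks the telescoping identity
Σgains − Σlosses = tip content = carrier count exactly, over 5 datasets ×
all 10 leaves as focal lineages.

## Numerical and degenerate-input choices

* log2 gain/loss ratios are left undefined (empty/NaN) when either count is
  zero or before ps3 — no pseudocounts, no ±inf; raw counts are always
  emitted next to the ratio.
* `peak_range` spans ties: the reported peak is the inclusive ps interval
  attaining the maximum content.
* Readers are strict where silence would corrupt results (a protein in two
  clusters, ragged rows with the offending line number, unresolvable
  species listing the first 10 offenders) and lenient with a logged warning
  where dialects genuinely vary (missing representative self-row,
  within-line duplicates in MCL output).
* All randomness flows through one `numpy.random.Generator` per run;
  sub-seeds for replicate studies are derived arithmetically and stay below
  2^31. Identical configs give byte-identical fixture bundles and output
  tables.

## Known limitations

* Dollo parsimony cannot place multiply-acquired features (endosymbiotic or
  horizontal acquisitions): their single "gain" lands at the LCA of all
  carriers, which may predate every true acquisition.
* Gain/loss dating is ordinal; no absolute-time calibration is attempted.
* The enrichment model treats families as exchangeable and annotations as
  fixed labels; phylogenetic non-independence among families gained at the
  same node is not modeled — consistent with treating each (term, ps) table
  as a descriptive screen rather than a causal estimate.
* Probabilistic alternatives (birth–death gene-content models, gene-tree
  reconciliation) are out of scope by design.
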