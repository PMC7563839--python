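# Methods

## The analysis model

The pipeline treats transcriptional drug response as a two-layer
inference problem. The first layer is *structural*: a background RNA
interactome — a heterogeneous directed graph whose nodes are TFs,
miRNAs, mRNAs and lncRNAs and whose edges are binary regulator→target
associations compiled from evidence databases. Associations are treated
as unweighted regulations; when two databases report the same (source,
target) pair the edge is stored once with the union of evidence labels.
mRNA targets that code for transcription factors (as declared by a TF
registry) are relabeled TF, which is what creates miRNA→TF edges out of
CLIP-style miRNA→gene records and makes miRNA-mediated and mixed loops
expressible at all. A registry id declared lncRNA or miRNA anywhere is
a hard error rather than a silent relabel.

The second layer is *condition-specific*: the DEG set of one condition
induces a subnetwork (background edges with both endpoints DE, isolated
DE nodes retained with degree zero), and that subnetwork is mined for
feed-forward loops, shared-miRNA ceRNA triples, degree hubs, and
prioritized lncRNA candidates.

Assumptions worth stating: the background network is taken at face
value (no edge weighting, no significance filtering of database
evidence); DE statistics are computed upstream and consumed as a table;
and subnetwork induction is purely set-theoretic — an optional
expression-correlation filter (|r| ≥ threshold) exists but is off by
default, because dropping edges on an unstated correlation threshold
would silently change motif counts. Edge *signs*
(stimulatory/inhibitory by the sign of endpoint expression correlation,
miRNA-source edges defaulting to inhibitory when expression is absent)
are annotation only; they never gate enumeration.

## Feed-forward loop classification

A triple (TF t, miRNA m, target x ∈ {mRNA, lncRNA}) is a loop when
t→x, m→x and at least one of t→m / m→t exist. Mutual t⇄m pairs are
classified *mixed exclusively*: the per-type counts are then a
partition of the loop set, which is the reading consistent with
reporting the three counts side by side as disjoint categories. The
alternative (counting a mutual triple under all three types) is
available via `mixed_exclusive=False`. Targets are restricted to mRNA
and lncRNA biotypes, so a node never fills two roles in one motif; the
three nodes are distinct by construction. Output order is
(tf, mirna, target) lexicographic, making every downstream file
deterministic.

The enumerator intersects successor sets per regulator pair,
O(|TF|·|miRNA| + output). The test suite keeps an independent O(n³)
triple-scan oracle and checks set equality on random typed graphs of
mixed size and density, plus permutation invariance under node
relabeling.

## Statistics

**DEG thresholds.** FDR < 0.05 and |FC| > 2 (mRNA/TF) or > 1.5
(miRNA/lncRNA), strict at the boundary. The fold-change scale is a
config flag (`log2` default, `linear` available) because published
threshold statements are genuinely ambiguous between "|log FC| > 2"
and "fold change > 2"; a flag is cheaper than guessing.

**ORA.** One-sided hypergeometric tail P[X ≥ k] via
`scipy.stats.hypergeom.sf`, checked in tests against direct
combinatorial summation on small universes. Multiple testing uses
Benjamini–Hochberg across the gene sets of one query (statsmodels);
BH was chosen as the field default where no correction is named.
Query ids outside the universe are dropped with a warning.

**Guilt by association.** Per lncRNA, mRNAs ranked by |r| (Pearson
default, Spearman optional); selection by `top_n` (default 200 — a
documented choice where no published threshold exists, exposed in
config) or by an `r_min` floor. Constant rows are excluded with a
warning since their correlation is undefined.

**Survival screen.** Cohort split at the median expression of the
gene, ties to the low arm (deterministic). Log-rank chi-square and
p-value come from `lifelines.statistics.logrank_test`; the hazard
ratio is the O/E approximation (O_high/E_high)/(O_low/E_low) computed
from an in-package life-table tabulation, matching log-rank + HR
reporting without a Cox regression dependency. The O/E estimator is
known to be mildly conservative (it recovers ≈1.9 at a true HR of 2 in
the acceptance run); it preserves direction and ordering, which is
what a screen needs. A median-split arm with zero events raises a
degenerate-input error naming the gene rather than returning a
meaningless statistic. The 6-subject fixture in the tests is frozen
against R `survival::survdiff` (chisq = 0.4848762603).

## The synthetic-data generator

Defaults define the benchmark conditions: node universes of 107 TFs,
1851 miRNAs, 10,970 lncRNAs and 18,812 mRNAs, and per-class Bernoulli
edge densities (0.15 TF→mRNA, 0.08 TF→lncRNA, 0.10 TF→miRNA, 0.014
miRNA→mRNA, 0.0118 miRNA→lncRNA) chosen once so the expected
deduplicated background is ≈1.145M regulations, the scale of the
compendium the pipeline is aimed at. Edges are independent Bernoulli
draws within class (Erdős–Rényi per class) — the simplest null that
preserves biotype structure; degree-sequence realism is a non-goal.
A 5% fraction of miRNA→lncRNA rows is re-emitted under a second
database label to exercise evidence-union deduplication, and miRNA→TF
regulations are emitted inside the miRNA→mRNA table against registry
ids, exercising the relabeling rule.

Planted structure: FFLs of all three types and ceRNA triples sit on
unique (TF, miRNA) regulator pairs; their edges are injected and their
nodes forced into the first condition's DE set. Randomly drawn reverse
edges between planted TF-mediated or miRNA-mediated pairs are removed,
because a chance mutual edge would reclassify the loop as mixed and
make 100% *typed* recall unattainable by construction rather than by
implementation error. Planted ceRNA miRNAs are reused from the planted
loops so they survive the pipeline's loop-miRNA allowlist. DE
statistics guarantee threshold separation: DE genes draw
FDR ~ U(0, 0.05) and |log2FC| = threshold + |N(0, effect)|; non-DE
genes draw FDR ~ U(0.05, 1) with |log2FC| strictly below threshold.
Default DE fractions (3.3% mRNA/TF, 2.8% miRNA, 1.9% lncRNA)
reproduce the order of magnitude of a strongly responding condition
(~600 mRNAs, ~50 miRNAs, ~200 lncRNAs genome-wide).

Expression is log-normal: log-expression is N(0, 0.25²) noise plus,
for each planted ceRNA pair, a shared latent N(0,1) factor with weight
1, giving sponge partners a high positive correlation (exactly r = 1
in the noise-free degenerate case). Survival cohorts (default n = 400,
the order of a TCGA-style glioma cohort) have exponential event times
with base hazard 0.1, hazard multiplied by `survival_hr` (default 2.0,
a realistic prognostic-marker effect; no published value exists for
the motivating markers) in the above-median arm of each effect gene,
and U(0, 15) censoring (~25–30% censored), chosen for closed-form
sanity checks.

What the generator does *not* emulate — and hence what passing tests
do not show: realistic degree distributions (hubs arise in real
compendia from binding-site biology, not Bernoulli sampling),
count-level DE statistics (no negative-binomial read model; the
generator emits post-test statistics directly, since the upstream test
is out of scope), correlated miRNA–target expression beyond the
planted pairs, and annotation mess (identifier spaces are clean
prefixed strings; cross-reference reconciliation is explicitly out of
scope). Recovery of planted structure validates the graph machinery
and statistics, not robustness to noisy annotation.

## Numerical and design choices

- Determinism throughout: all randomness flows from
  `numpy.random.default_rng` seeded per sub-stream from one seed;
  outputs are sorted before writing; hub ties break lexicographically;
  median ties go to the low survival arm. Equal (inputs, config, seed)
  give byte-identical files.
- The interactome edge store is a pandas DataFrame, not a graph
  object: at ~10⁶ edges the background is only ever filtered.
  networkx graphs are built for DE subnetworks, which are small.
  Evidence merging takes a fast path (only pairs reported by >1
  database go through a Python-level union).
- Isolated DE nodes stay in subnetworks with degree 0, so the biotype
  composition of a response is visible even off-network.
- Degenerate inputs error loudly rather than silently: duplicate
  (gene, condition) DE rows, unknown biotypes, biotype conflicts,
  zero-event survival arms, constant expression rows (warn + exclude),
  n_samples < 3 for correlation, planted demand exceeding the node
  universe.
- Problem sizes in the test and acceptance runs (e.g. 100 oracle
  graphs of ≤50 nodes, 500 null survival cohorts of n = 60, one
  compendium-scale build per run) were chosen as the smallest sizes at
  which the checked properties are non-trivial and Monte-Carlo margins
  are tight; all are package defaults, configurable upward.

## Known limitations

- The hazard ratio is an O/E approximation, not a Cox estimate; use it
  for screening and direction, not effect-size reporting.
- No motif significance testing against degree-preserving network
  randomizations; counts are descriptive.
- ceRNA derivation is structural (shared miRNA only); expression
  correlation of the sponge pair is reported as an annotation column,
  never used as a filter, and no binding-site-level evidence is
  modeled.
- Whether DE direction consistency (e.g. miRNA up ⇒ target down)
  should gate subnetwork edges is unsettled upstream; it is not
  enforced here.
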