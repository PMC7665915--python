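# Methods

This note documents the statistical procedures, the synthetic-data model and
its calibration, the numerical choices, and the limits of what the test
suite demonstrates.

## Cohort statistics

The user/nonuser comparison follows the conventions of published
claims-database tables: per-level counts with percentages rounded half-up
to one decimal (exact decimal arithmetic, so printed-table cells re-derive
bit-for-bit from their counts), and Pearson χ² on the level×group
contingency table without continuity correction. Yates correction is
available as an option for 2×2 tables; for the multi-level tables here it
does not apply, and the uncorrected statistic reproduces the published
significance calls. Two APIs exist deliberately: a row-level one for
patient tables and a counts-level one so published grouped tables can be
verified without patient-level data. Published grouped tables occasionally
carry internal off-by-one inconsistencies (one medication-type column sums
to one more than its stated group size); the counts-level API therefore
takes the group size as the explicit percentage denominator rather than
inferring it from column sums.

"Share on multiple medication classes" is implemented as membership in the
{2, ≥3} medication-type levels; this is the only reading that reproduces
the published pooled and per-group shares (54.4% / 50.1% / 57.0%) from the
published count rows.

## Association-rule mining

Transactions are herb-code sets (duplicates collapsed); support denominators
are prescriptions, not patients. Only pair rules are mined by default —
the network's edges are pairwise — with an apriori k-itemset extension
(k ≤ 4) for exploration. Metrics come from exact counts with no sampling.
Lift is computed in the symmetric integer form `n(A∧B)·n / (n(A)·n(B))` so
that both directions share one lift value exactly and the identity
`lift · support(consequent) = confidence` holds to float rounding (≤1e-12).

Threshold defaults are support ≥ 1.0%, confidence ≥ 15%, lift ≥ 1.0. The
source analysis preset its thresholds without publishing them; these values
sit just below the weakest published top-10 pair (support 1.068, confidence
15.413, lift 1.425) so that all published pairs would survive, and they are
fully configurable. Top-N selection collapses each unordered pair onto its
higher-confidence direction and ranks by support, then confidence, then the
lexicographic pair name, making the ranking deterministic under ties.

## Network analysis

The rule graph is undirected, one edge per unordered pair, with pair support
as edge weight. Community detection is greedy modularity agglomeration
(Clauset–Newman–Moore style) implemented in-package rather than delegated,
because reproducibility requires a *stated* tie-break: among merges with
equal modularity gain (within 1e-12), the lexicographically smallest
community pair (keyed by each community's smallest member) merges first.
This makes the partition invariant to node and edge input order; networkx's
`community.modularity` is the quality oracle in tests, and seeded Louvain is
exposed as an alternative method. Only edge-joined communities are merge
candidates (merging disconnected communities always lowers Q), so connected
components — including isolated dyads — can never coalesce. Merging stops
when no merge increases Q; on a complete graph this yields the single
trivial cluster (Q = 0).

Degree centrality is the raw incident-edge count (unweighted), matching the
small-integer degree columns of published prevalence tables; clustering uses
the support weights. The core herb of a cluster maximises (degree,
prevalence, lexicographic name) — an explicit operationalisation of the
qualitative "highest prevalence and most connections" criterion.

## Synthetic claims model

The generator is the study-conditions surrogate for a non-redistributable
claims extract; its defaults are calibrated once against the published
summaries and are not tuned per experiment.

**Cohort.** Each variable is drawn independently per group from the
published grouped marginals (counts normalised per column). The joint
patient-level distribution is unknown, so cross-variable correlations are
not modelled; tests of the cohort generator therefore validate marginal
fidelity (χ² goodness of fit over 20 seeds) and nothing more.

**Prescription sizes.** Mode 5, ~6.3% of prescriptions with ≥ 10 herbs,
bins 1–9 at masses {.03, .05, .10, .15, .17, .15, .12, .09, .076} with the
6.3% tail split geometrically (ratio 0.1) over 10–15 and the vector
normalised. These bin masses force a mean ≥ 5.654 for any tail split (the
tail's conditional mean cannot fall below 10), so the published mean of 5.6
herbs/prescription is approached from above: the distribution's true mean is
~5.667, within the 0.1 band the tests assert.

**Planted communities.** Each transaction draws a size, then a community
with its configured weight (leftover mass gives background-only
prescriptions), always includes the community's core herb, and fills the
remaining slots from still-unused cluster members or background herbs with
relative weights (co_draw, background_mass) — by default 0.8 and 0.05,
i.e. ~5.9% of non-core slot fills are background — spilling to the other
pool when one is exhausted. The demo roster has six communities
(10/9/4/4/2/2 herbs, the last two isolated pairs) over a 20-herb
background; community weights 0.255/0.229/0.162/0.191/0.06/0.06 place the
four larger cores at their published prevalences, while the two pair
weights are unconstrained by publication and fixed at 0.06. Communities are
closed (members never appear outside their community; cross-community
mixing is left to the background), reflecting the largely disjoint
published network. Because background herbs can ride into the top-100
network without a planted label, recovery metrics (adjusted Rand index,
core hit rate) are computed over planted herbs present in the network.

**Ingredients, targets, comparators.** 31 network herbs × 78–79 ingredients
(~2,430 total, the published scale); OB ~ Beta(2, 3) and DL ~ Beta(1.2, 3.5)
on [0, 1], 5% inorganic, 1–4 targets per ingredient from a 10,000-protein
universe. The comparator set has 39 drugs in four categories whose
per-category protein pools (55/32/7/29) match the published comparator
set sizes; the 12/15/2/10 drug split is a design choice, as only the total
is published. OB thresholds treat the published "0.30" as a fraction;
because TCMSP publishes OB in percent, a units flag (`fraction`/`percent`)
is accepted and documented.

**Planted pathway coverage.** The demo collection has 300 pathways of
20–40 members: 140 planted as covered by the herb-network target union,
55 by the comparator union (30 by both), with the immune-system blocks
arranged as 19 herb-covered vs 8 comparator-covered, reproducing the
published complementary pattern (innate/adaptive for herbs,
interleukin-signaling for drugs). Covered pathways draw 80% of members
from the covering target set(s); uncovered pathways draw uniformly, so a
handful of uniform pathways clear the FDR threshold by chance and measured
coverage can exceed the planted count by a few pathways — the measured
values are what the acceptance script reports.

## Enrichment

The hypergeometric upper tail is summed in log space (log-gamma binomials,
suffix log-sum-exp), exact against integer enumeration to 1e-10 over the
full N ≤ 60 grid and stable to N ~ 1e5; tails at or below the support floor
are returned as exactly 1. The annotated universe defaults to the full
protein universe supplied with the collection (all proteins appearing in
pathways if none is supplied); target proteins outside it are dropped with
a warning. Only pathways with overlap k ≥ 1 are tested, and adjustment runs
across exactly the tested pathways. "Covered" means BH-adjusted q ≤ 0.05
with k ≥ 1 — the publication never states its criterion, so the standard
ORA default is used, with Bonferroni and raw-p modes for sensitivity.
Category comparison rolls paths up to their first two levels.

## Pipeline and determinism

A single integer seed drives all generators through CRC-32-derived
`SeedSequence` spawn keys, so stages can be regenerated independently.
Every artifact is plain text with `#`-comment metadata (version and seed;
deliberately no timestamps) and a stable row/attribute ordering, making two
runs of the same configuration byte-identical — asserted by the test suite
at the artifact level.

Default problem sizes — 20,000 prescriptions, 20-seed recovery batteries,
a 10,000-protein universe, cohort at 20% of the published group sizes in
the demo — were chosen as the smallest scales at which the planted
structure is comfortably identifiable and binomial noise on reported
percentages stays well inside a tenth of a percent; all are configurable.

## Known limitations

- The cohort generator models marginals only; no patient-level correlation
  structure, and prescriptions are not linked to cohort rows.
- Planted communities are closed and unweighted by dose; real
  co-prescription networks have porous communities and dose effects (dose
  is carried through but unused analytically, mirroring the source
  analysis's own exclusion).
- Support scales in the synthetic fixture are an order of magnitude above
  published ones because the fixture's herb universe is ~51 codes, not a
  full formulary; rankings and network structure, not absolute supports,
  are the comparable quantities.
- Protein and pathway identifiers are opaque synthetic strings; no
  identifier normalisation or live database access is attempted, so
  published absolute target-set sizes are matched only in spirit.
- Passing planted-recovery tests demonstrates the pipeline recovers
  structure of the kind published; it cannot validate the published
  partition itself, which would require the original records.
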