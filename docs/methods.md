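# Methods

## The analysis in brief

The package implements descriptive symptom-network analysis for a
battery of 17 psychometric items in three domains (9 neurocognitive, 2
affective, 6 psychosocial). A network is estimated per cohort arm
(cohort × timepoint), summarized by weighted centralities and node
predictability, and arms are compared descriptively. No inferential test
of network differences is performed: deltas are descriptive, matching
the analysis the pipeline reproduces.

## Network estimation

Edges are zero-order Spearman correlations, not partial correlations and
not regularized. The estimator ranks each column with the average-rank
convention (these integer scales tie heavily) and computes Pearson
correlation on ranks. Two-sided p-values use the t approximation
t = ρ√((n−2)/(1−ρ²)) on n−2 degrees of freedom, which is adequate for
n ≥ 10; for very small arms (the smallest study arm has n = 16) a seeded
permutation test (default 10,000 permutations) is available via
`p_method="permutation"`. An edge is kept iff p < α with α = 0.05 by
default; no multiple-testing correction is applied by default because
the per-edge rule is the one being reproduced, but Holm and
Benjamini–Hochberg are available via `correction=`.

Missing data: the default is listwise deletion (`complete_rows`), with
`pairwise` complete cases as an option. Any pair with fewer than 3
complete cases is an error naming the pair. A zero-variance column
yields ρ = 0, p = 1 for its pairs (no monotone association is
determinable); this case is unreachable for generated data but can occur
with degenerate real input.

## Centrality

All path-based measures use absolute weights: a strong negative
correlation is a strong connection, and Dijkstra requires positive
costs. The signed sum Σw<sub>ij</sub> (expected influence) is reported
alongside strength so sign information is not lost.

- Blended degree CD<sup>wα</sup> = k<sup>1−α</sup>s<sup>α</sup>, with
  k = 0 mapping to 0 for every α (0⁰ is resolved to the isolated-node
  convention). α = 0 and α = 1 reproduce degree and strength exactly,
  bit for bit, because those branches bypass the power functions.
- Edge cost is (1/|w|)<sup>α</sup>. The default tuning parameter is
  α = 1 (cost 1/|w|, CD = strength); the analysis being reproduced does
  not state its α, so it is a configurable parameter rather than a fixed
  constant.
- Shortest-path multiplicities are counted by dynamic programming over
  nodes in order of distance from the source; an edge (u, v) lies on a
  shortest path iff d(s,u) + cost(u,v) equals d(s,v) within a relative
  tolerance of 1e−9, so floating-point path sums that are mathematically
  equal count as tied. Through-counts use the decomposition
  g<sub>jk</sub>(i) = g<sub>ji</sub>·g<sub>ik</sub> when
  d(j,i) + d(i,k) = d(j,k) (same tolerance).
- Betweenness sums g<sub>jk</sub>(i)/g<sub>jk</sub> over unordered pairs
  excluding endpoints, giving fractional credit across ties — Freeman's
  definition with Brandes-style accumulation. The distance, count,
  betweenness and closeness paths are validated against exhaustive
  simple-path enumeration on hundreds of random graphs of up to 7 nodes,
  and against an independent library implementation on tie-free graphs.
- Closeness is 1/Σd over reachable nodes (isolated node → 0); no formula
  is prescribed by the source analysis, so the reciprocal-total-distance
  convention was adopted, with harmonic closeness behind a flag because
  it degrades more gracefully on disconnected networks.
- Centrality tables are z-standardized per column across the 17 nodes
  (population SD; a constant column standardizes to zeros), which is the
  scale on which cohort centrality profiles are plotted and compared.

## Predictability

"How well is a node predicted by its neighbors?" is answered with an
in-sample OLS regression of the node on the nodes it shares an edge with
in the thresholded network (not all 16 others), with intercept.
Predictability is R² = 1 − SSE/SST floored at 0; the RMSE of the fit is
also reported. A node with no neighbors has predictability 0 by
definition, and a constant node (SST = 0) is also assigned 0. In-sample
rather than cross-validated R² matches the nodewise-regression
predictability methodology for continuous variables; note that in-sample
R² is optimistic in small arms with many neighbors.

When complete cases fall below n_neighbors + 2 the OLS problem is
ill-posed. The default is an error; `ridge_fallback=True` substitutes a
lightly penalized fit (penalty 1e−3·trace(XᵀX)/p applied to slopes
only), which the comparison pipeline enables because the smallest arm
(n = 16) can have nodes with a dozen neighbors. Table construction never
aborts on a single node: per-node failures are recorded in an `error`
column.

## Synthetic cohorts

The generator emulates what the pipeline assumes about real data:
bounded integer scores, block-correlated domains, a few cross-domain
bridges, and a follow-up with fewer subjects and weaker associations.
Mechanism: a target correlation matrix is assembled block-wise
(within-domain value per domain, between-domain value per domain pair,
item-pair bridge overrides applied last), projected to the nearest
positive-semidefinite correlation matrix (eigenvalue clipping at zero,
re-standardization to unit diagonal, iterated to convergence), sampled
as latent multivariate normals, then each column is mapped through its
item's mean/SD, rounded to integers and clamped to the instrument's
published range.

What it does **not** emulate: item-level ordinal response processes
(an IRT model would), floor/ceiling-induced skew beyond what clamping
produces, informative dropout (retention is a uniform random subset),
and any treatment mechanism (the T0→T1 change is a mean shift plus a
global correlation attenuation factor). Passing tests therefore show the
pipeline recovers planted rank-correlation structure from bounded
integer data at realistic sample sizes — not that any clinical claim
about real cohorts is true.

Rounding and clamping attenuate Spearman correlations slightly
(≈0.57 observed for a 0.6 latent target at central means); this is
documented rather than corrected, since real bounded scales behave the
same way.

Preset parameters: the MDD-like and BD-like presets are illustrative
fixtures chosen once as clinically plausible values for moderately to
severely depressed cohorts (e.g. MoCA 22 ± 4, BDI-II 28 ± 9, elevated
FAST domain scores), with the qualitative structure of the two
disorders: the MDD-like arm has strong affective↔psychosocial coupling
and no direct affective↔neurocognitive association; the BD-like arm has
a hyperconnected psychosocial block with bridges through global
cognition (MCA). Cross-domain correlations involving the neurocognitive
block are negative because those items are scored higher-is-better while
the others are higher-is-worse; the generator never auto-flips signs.
Default sample sizes are the study's: 87 → 16 (MDD-like) and 56 → 29
(BD-like), with attenuation 0.4 emulating the observed loss of
connectivity. Monte-Carlo checks in the test suite use 20–50 replicates
at n = 150–300, sizes at which the planted structure is reliably
recoverable while the whole suite runs in seconds.

## Layout and rendering

The Fruchterman–Reingold layout uses constant k = √(area/N) with unit
area, attraction d²/k scaled by |w| along edges, repulsion k²/d
truncated beyond radius 3k (distant-vertex forces ignored), a linearly
cooling temperature starting at 0.1, 500 iterations, and seeded initial
positions on the unit disc (default seed 42). The layout is
deterministic given (network, seed, iterations) and is centered at the
origin. Coordinates are not comparable with other force-directed
implementations — only the qualitative geometry (dense blocks cluster,
bridges sit between them) is asserted. Rendering follows the field's
figure conventions: domain-colored nodes, black positive / red negative
edges with thickness proportional to |w|, and a blue ring arc per node
proportional to predictability.

## Pipeline determinism

A full comparison run is a pure function of its configuration: seeds are
explicit everywhere (generator config, permutation test, layout), CSV
floats are written at full precision and read back with round-trip
parsing, JSON is serialized with sorted keys, and wall-clock timings go
to a plain-text log rather than the JSON report. Two runs with identical
configuration produce byte-identical CSV/JSON/GraphML artifacts; this is
asserted in the test suite.

## Known limitations

- Thresholded zero-order correlation networks conflate direct and
  indirect associations; partial-correlation or regularized models are
  out of scope by design.
- Betweenness/closeness on |w| discard edge sign; interpretation of
  paths through negative edges is the user's responsibility.
- In-sample predictability is biased upward at small n; the ridge
  fallback trades that for shrinkage bias.
- The unstated tuning parameter α means centrality magnitudes (though
  rarely rankings at moderate densities) depend on a user choice.
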