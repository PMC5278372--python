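# Methods

## Model overview and assumptions

The package backcasts a categorical land-use map for a historical date from
later observed maps. Three assumptions underpin the reconstruction:

1. the present spatial pattern of land use is intrinsically dependent on the
   historical pattern (so suitability inferred from observed maps is
   informative about the past);
2. human-driven classes (arable land, settlement) never extend beyond the
   union of their observed extents across the study period;
3. natural suitability factors (soil, geomorphology, terrain) are stable over
   the century-scale study window.

All rasters share one grid geometry (square cells, row 0 northernmost,
0-based row-major indices); no resampling is performed. A cell that is nodata
in *any* input of an operation is excluded from that operation's statistics —
the treatment of border/nodata cells is a package contract, chosen because it
is the most conservative option. Areas are reported in hectares with
`cell_area = cell_size² / 10000` (0.81 ha for the default 90 m cell).

## Quantity control

Per-class historical totals are the weighted sum of available source
estimates; each class carries its own weight vector over sources (weights sum
to 1 over *available* sources). Classes whose source breakdown is unavailable
can carry a directly supplied fused value. Fused areas are rescaled
proportionally so they sum exactly to the study-area total (the last class
absorbs the sub-0.01 ha float residual).

Backcasting treats an edited later-interval cross-tabulation as the model of
the reconstruction interval. Only the later-year margins are known, so each
column is rescaled in a single pass by `target_margin / column_total`; the
historical quantities are the rescaled row sums. Iterative proportional
fitting is deliberately not used: with one known margin, column rescaling is
the unique solution and preserves the column-composition structure of the
model. A zero model column with a nonzero target margin is an error — the
model offers no pathway into that class.

Transition edits are explicit `move_flow(from, old_to, new_to, amount)` rules
applied sequentially in list order; each preserves its source-row total
exactly, so the matrix grand total is invariant under any rule list. Rules
live in the run configuration, never in code, because they encode
case-specific reasoning (e.g. climatic regime changes making a conversion
implausible in the earlier interval).

Area-to-cell conversion uses largest-remainder apportionment after scaling
out rounding drift, so per-class integer quotas sum exactly to the number of
allocatable cells; it refuses totals that disagree with the grid by more
than 1%.

## AHP weights

Weights are the principal eigenvector of a positive reciprocal pairwise
matrix, computed by power iteration (tolerance 1e-10, cap 10 000 iterations —
deterministic and dependency-light; verified in tests against a
repeated-matrix-squaring oracle to 1e-8). `lambda_max` is the mean Rayleigh
ratio at the converged vector; `CI = (lambda_max − n)/(n − 1)`;
`CR = CI/RI(n)` with Saaty's random-index table and `CR ≡ 0` for `n ≤ 2`.
`CR > 0.10` warns but does not fail: published studies often proceed with
mildly inconsistent judgements, and the caller sees the number. Because
published work usually reports only resulting weights, a validated direct
weight vector is accepted everywhere a pairwise matrix is.

## Suitability

Factors are standardized to 0–255:

* **Categorical factors** (soil, geomorphology, aspect class; elevation and
  slope after binning into configured intervals): category `k` scores
  `round(2.55 × percent)` where percent is the share of the class's union
  extent lying on `k`. The linear ×2.55 stretch with round-half-away-from-zero
  is the only standardization applied. The percentage is of the class union
  across factor categories (a partition, so percents sum to 100), not of the
  factor category across classes.
* **Distance factors** (to settlements, rivers, roads) and
  **autocorrelation factors** (to existing patches of the class itself in a
  reference map): Euclidean distance (scipy's exact transform, scaled by cell
  size) normalized by its maximum over the valid study mask — not by a fixed
  radius, since no cap is part of the model — then reverse-stretched:
  `round(255 × (1 − d/d_max))`. Feature cells score 255, the farthest valid
  cell 0.

Constraints are binary: water cells exclude every class but water; a
persistence (unchanged) map fixes its class and excludes all others at those
cells; human classes are confined to their union ranges (assumption 2).
Class suitability is `round(Σ w_i x_i) × Π c_j`, clipped to [0, 255]; weights
must sum to 1, so the combination is convex and monotone in every factor.
Distance/autocorrelation factors apply only to classes for which weights are
supplied — a blank weight means the factor is absent for that class.

## Spatial allocation

Allocation is an ordered, deterministic cellular automaton. Defaults:

| parameter | default | meaning |
|---|---|---|
| class order | settlement, arable, water, wetland, forest, grassland, other-unused | most-constrained (human/aquatic) classes first |
| neighbour threshold | 5 of Moore-8 | strict-pass contiguity requirement |
| relaxation schedule | neighbour → max-suitability → evidence | order in which rules are dropped |

Step 0 pre-assigns every persistence-fixed cell and debits quotas; these
cells seed the neighbour rule. For each class, candidate cells (unassigned,
constraint-allowed) are visited in descending suitability, ties broken by
row-major index. A strict pass accepts a cell only if the class's suitability
is the *strict* maximum across classes there (ties fail and fall through to
relaxation, where class order decides — this keeps the algorithm
deterministic), any evidence value agrees, and the neighbour count meets the
threshold (off-grid neighbours count as non-matching, making the rule
effectively stricter at borders — the simplest explicit contract). Passes
repeat while they assign cells; a stalled pass drops the next rule in the
schedule. The schedule is a completion of the underlying flow chart, which
does not specify behaviour when quotas cannot be met under the strict rules;
dropping the neighbour rule first and the evidence rule last keeps quantity
control binding while honouring hard evidence longest. Realized counts always
equal quotas exactly; constraint-zero cells are never assigned the class; a
class left with quota but no candidates after all relaxations is an error
naming the class.

Feasibility is *not* guaranteed for arbitrary constraint sets: the sweep is
greedy and sequential, so earlier classes may consume cells a later class
needed even when a global assignment exists. The supported workflow avoids
this by construction — exclusive masks (water) are pre-assigned to their
class with a covering quota, union-range constraints apply to classes early
in the order, and remaining classes are unconstrained. The allocation
property tests generate random scenarios of exactly this structure.

Class-order sensitivity is real: permuting the order can change the map.
Tests assert determinism and invariants for a fixed order only.

## Three-map validation

Per cell: observed change iff `ref_t1 ≠ ref_t2`; predicted change iff
`ref_t1 ≠ sim_t2`. Binary mode scores any co-occurring change as a hit;
categorical mode additionally requires `sim_t2 = ref_t2`, and counts
both-changed-wrong-class cells (partial hits) as misses. Partial hits are
always reported separately. Both modes are exposed because published
component tables are often computed in binary bookkeeping (predicted change
PC = H + F) while figure-of-merit prose removes partial hits from the
numerator; reports state the mode used. Percentages are over cells valid in
all three maps; component sums are accepted to 100 ± 0.01% because published
tables are rounded to 0.01. Budget identities (OC = H + M, EQ + EA = M + F,
HOC + MOC = 1) hold exactly by construction and are exercised by property
tests; HOC/MOC/FOC are NaN with a warning when no change was observed.

## Synthetic data

The generator emulates what the pipeline needs from real data, with a single
seed determining every output:

* **Landscape**: per-class Gaussian fields smoothed by a uniform box filter
  (default radius 3 cells — a dependency-light source of spatial
  autocorrelation), rank-calibrated to [0, 1], then labelled by best class
  under exact per-class quotas (largest remainder), so realized proportions
  match targets to within one cell. The default composition is the
  reconstructed seven-class study landscape (grassland 63.2%, arable 24.4%,
  wetland 9.7%, minor classes < 2% each) at 200×200 cells of 90 m.
* **Factors**: each categorical factor category preferentially overlaps one
  class (75% adherence, 25% uniform noise), giving positive class-factor
  mutual information; features are random points (settlements) and sinuous
  polylines (rivers, roads); evidence is the landscape on a random 30% of
  cells.
* **Forward change**: default transition matrix keeps 85% of each class in
  place and spreads the rest evenly — a mild-change regime. Without
  suitability, destinations are sampled independently per cell (realized
  rates converge to the matrix by the law of large numbers, verified at
  500×500); with suitability, destination counts are fixed by largest
  remainder and filled with the most-suitable cells, preserving marginal
  rates exactly while structuring change spatially.

What the generator does **not** emulate: real terrain gradients and
hydrology, historically plausible settlement siting, classification
inconsistency between map sources (a dominant error source in real
validations), and registration error. Passing tests therefore demonstrate
algorithmic correctness and invariant preservation, not real-world
reconstruction accuracy.

## Problem sizes used in the test suite

Unit examples run on toy grids; property suites use 100 scenarios at 100×100
for allocation, 500×500 for transition-rate recovery, 300×300 (3 seeds) for
end-to-end backcast recovery, and a 200×200 full-pipeline run — sizes at
which the stochastic tolerances asserted (±2% composition, ±0.02 transition
rates) have comfortable statistical margin.

## Known limitations

* The allocation sweep is greedy per class; it does not search for globally
  optimal or even globally feasible assignments under adversarial
  constraints.
* Settlement-like classes driven by socioeconomic factors are modelled only
  through distance/autocorrelation proxies.
* GeoTIFF support covers single-band integer rasters with pixel-scale,
  tiepoint and nodata tags; CRS metadata is not interpreted (co-registration
  is checked on grid geometry only).
* Quantity fusion trusts the supplied source weights; no uncertainty is
  propagated to the allocation stage.
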