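# Methods

## Scope of the pipeline

`greenaccess` measures walking access to urban green space (UGS) and its
equity across a study region. Demand units are residential areas; supply
units are green spaces reached through entrances; travel happens on a
pedestrian road graph; and all results are reported for three walking "life
circles": 500 m (5 min), 1000 m (15 min) and 2000 m (30 min) of network
distance. A nominal walking speed of 5 km/h is carried as metadata on each
scope, but the distance thresholds are authoritative — they are the
conventional life-circle radii, not exact speed × time products.

## Population disaggregation

Census population is known per sub-district (`SP`) and spread over the
sub-district's residential polygons proportionally to their footprint area:
`D_k = RA_k / RA × SP`. This assumes uniform density inside residential
areas and ignores building height — the standard dasymetric simplification
when floor counts are unavailable. `D_k` is kept real-valued; rounding is
purely a presentation concern. A sub-district with population but no
residential polygons raises a warning and its population is reported as
unassigned rather than silently dropped, so the study-wide conservation
check (`Σ D_k = Σ SP − unassigned`) stays exact. The
`validate_population_estimate` helper compares `D_k` with surveyed household
counts × persons-per-household (default 3.5) using the symmetric ratio
`min/max`; the direction-free ratio is a deliberate choice since an
"accuracy rate" does not specify which side over- or under-counts.

## Network distances

Demand points and green-space entrances are attached to the road graph by
perpendicular projection onto the nearest edge (ties broken toward the
smallest edge id). Snapping is to edges, not nodes: node-only snapping
distorts exactly the short 500 m catchments that matter most. The
straight-line connector from the original point to its projection is
included in every distance by default (`include_connectors` switches it
off); excluding it would make buildings far from any road look artificially
close. Distances between snapped locations are shortest paths through the
graph, evaluated by multi-source Dijkstra per green space (which implements
the nearest-entrance rule as a by-product), with the within-edge direct
segment handled separately because it passes through no node. Unreachable
pairs are `+inf`, never a large finite placeholder — a silent sentinel
would leak into the Gaussian weights.

The catchment boundary is inclusive (`d ≤ d₀`). Because the decay weight
vanishes exactly at `d₀`, including the boundary with weight zero makes the
inclusive and exclusive conventions numerically identical, which is why the
package does not expose a choice.

## G2SFCA

The decay is the truncated Gaussian
`G(d) = (e^{-(d/d₀)²/2} − e^{-1/2}) / (1 − e^{-1/2})`, normalised to
`G(0) = 1`, `G(d₀) = 0`. Step 1 forms `R_j = S_j / Σ G D_k` over the
catchment of green space `j`; a green space whose catchment holds no
positive weighted demand has an undefined ratio and is excluded (with a
logged notice, not an error). Step 2 sums `A_k = Σ G R_j` over green spaces
within `d₀` of demand point `k`. Both steps use the same radius — there is
no evidence for asymmetric supply/demand radii in this setting. The scheme
satisfies `Σ_k D_k A_k = Σ_{served j} S_j` exactly (floating point aside);
the pipeline logs this residual at every run and the tests require it below
1e-6 relative.

A residential area is *accessible* when any green space lies within `d₀`,
whatever that space's ratio status; inaccessible units get `A_k = 0` and a
separate "Inaccessible" category. Natural-breaks grading (five classes:
Very low … Very high) runs on the positive accessible scores only —
including the zero-inflated mass would waste the lowest class on a zero
bucket and misplace every break. The classifier is Fisher's exact dynamic
program for the minimum within-class sum of squared deviations (the Jenks
criterion), deterministic with ties resolved toward the earliest split; it
is implemented in-package and tested against exhaustive partition
enumeration. When fewer distinct positive scores than classes exist, the
grading degrades to the number of classes the data supports, labelled from
"Very low" upward.

## Equity statistics

*Gini/Lorenz.* Units sorted ascending by per-capita accessibility;
`W_i` = cumulative accessibility share; `G = 1 − (1/n)(2 Σ_{i<n} W_i + 1)`
(the trapezoidal form; 0 under perfect equality, bound `(n−1)/n` when one
unit holds everything). Units enter unweighted by default — one observation
per unit; a population-weighted variant is available behind a flag and
reduces to the unweighted formula under equal weights. Sub-district scores
are the population-weighted means of member residential scores.

*Location entropy.* `AALQ_j = A_j / (S/P)` with `S/P` the study-wide
per-capita supply, graded into fixed half-open bins [0, 0.5), [0.5, 0.75),
[0.75, 1.2), [1.2, 2.0), [2.0, ∞); `AALQ > 1` flags better-than-average
service. Bin closure is a convention choice (interval notation in the
literature leaves it open); half-open-left keeps every value in exactly one
bin. Sub-district entropy defaults to the aggregated (population-weighted
mean) score; an independent sub-district-level G2SFCA run — demand placed
at the sub-district's representative point with its full census population —
is available as `subdistrict_entropy_mode: direct`.

*Service coverage.* `T_j` = covered residential area / sub-district area,
`U_j` = covered population / sub-district population, where "covered" means
at least one green space within the scope. Reading the effective service
area as the covered *residential* footprint (rather than buffered
green-space area) keeps `T_j ≤ 1` structurally and matches the definition
of the covered units; it is recorded here as an interpretive choice.
`U_j` is undefined (reported missing) for zero-population sub-districts.

*Share tables.* Percentages are one decimal, rounded half-up (two decimals
for the supply inventory split). The "Accessible" summary row reports the
sum of the displayed accessible-grade percentages, so the printed table
stays additive: summary row = sum of its parts at the printed precision.
The direct half-up share is carried alongside (`percent_direct`); the two
can differ by one least digit when rounding of the parts does not commute
with rounding of the whole.

## Synthetic city generator

No public data accompany this kind of analysis (residential outlines and
census layers are proprietary), so the generator builds study regions with
the structure the method assumes, from a single integer seed:

- **Road network**: rectangular lattice over the extent (default 10 km ×
  10 km, 250 m spacing) with 10% of edges removed at random under a
  connectivity-preserving rule — a controllable stand-in for an imperfect
  street grid.
- **Sub-districts**: recursive binary splits of the extent into `n`
  rectangles (default 39), so the polygons partition the extent exactly.
- **Residential areas**: default 2020 random rectangles (40–160 m sides)
  placed inside sub-districts, counts proportional to sub-district area
  with at least one each. Census totals come from a Dirichlet(α=2) split of
  the total population (default 1.3 million), integerised by largest
  remainder; `D_k` then follows the area-weighting rule above, so
  population is conserved by construction.
- **Green spaces**: default 85 rectangles with log-uniform areas between
  0.5 and 50 ha — median 5 ha, so the two size classes (≥ 5 ha with 2–4
  boundary entrances, < 5 ha with centroid access) are roughly balanced.
  A `clustering` knob `c ∈ [0, 1]` places each center inside one focus
  quadrant with probability `c`, uniformly otherwise: `c = 0` is spatially
  uniform supply, `c → 1` concentrates supply in one corner, producing the
  empirically relevant regime of many unserved units at 500 m and high
  Gini values. Default `c = 0.8`.

The defaults give a per-capita supply near 7 m²/person, the magnitude
typical of dense main urban areas. What the generator does *not* emulate:
realistic street morphology, building heights, non-rectangular parcels,
spatially correlated density, or land-use constraints — so passing tests
demonstrate correctness of the computation and the qualitative regime, not
calibration to any real city.

## Numerical and design choices

- Edge lengths must be ≥ the straight-line distance between endpoints
  (within 1e-6 m); parallel edges keep the shorter; self-loops are
  rejected.
- The layers are GeoJSON FeatureCollections (plus a CSV for sub-district
  populations) in a projected CRS with meter units, declared by a
  `crs_units: "m"` field; the reader rejects undeclared layers whose
  coordinates fit geographic degree ranges. The pipeline never reprojects.
- Demand points are polygon centroids, falling back to an interior
  representative point for non-convex polygons whose centroid lies outside.
- All randomness derives from one seed through per-stage `SeedSequence`
  streams; identical configurations give byte-identical layer files.
- Problem sizes in the test suite are chosen for fast feedback: the
  conservation property runs on 50 randomized cities of 80–200 residential
  units (the identity is size-independent), oracle comparisons use graphs
  of ≤ 12 nodes where exhaustive path and partition enumeration is
  feasible, and the behavioural checks use a 400-unit clustered city. The
  acceptance script runs the full default scale (2020 units).

## Known limitations

- Uniform-density disaggregation misstates populations where building
  heights vary; the household validation helper quantifies but cannot fix
  this.
- Catchments ignore turn restrictions, crossings, slopes and time-of-day
  effects; only pedestrian travel is modelled.
- Per-unit accessibility is *not* monotone in the travel threshold — a
  wider radius exposes a green space to more competing demand, which can
  lower individual `A_k` — so only the accessible *count* is asserted to
  grow with the scope; the Gini decline with scope is an empirical property
  of clustered supply, not a theorem.
- Equity here is spatial only: no demographic subgroups, green-space
  quality, or demand heterogeneity.
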