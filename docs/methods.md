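# Methods notes

## Coordinate and data contracts

All geometry is planar, in meters. The package never reprojects; GeoJSON is
used purely as an encoding, and loaders refuse files whose coordinates all
fall inside longitude/latitude ranges, since metric buffer distances would
be meaningless there. Network topology is recovered by snapping edge
endpoints at 1e-6 m, the only topology repair performed.

Walkability is an edge attribute derived from a road-class deny-list
(default `{limited_access_highway, highway_ramp}`), reflecting the rule that
pedestrians may not traverse limited-access facilities. The deny-list is a
load-time parameter.

## Service areas

The reach computation seeds Dijkstra from a mid-edge origin (the snapped
home), so both directions along the host edge are explored. Because edges
have no interior junctions, the network distance to an interior point at
offset *s* on edge *(u, v)* of length *L* is `min(d(u)+s, d(v)+L−s)` (plus
the direct distance on the origin's own edge), which makes per-edge reached
intervals *exact* rather than discretized. Overlapping partial reaches of
one edge are merged into maximal intervals so no length is double-counted
and no geometry double-buffered. Loops and parallel edges are supported;
iteration is in edge-id order everywhere, so outputs are bit-stable.

Snapping uses Euclidean nearest-point over walkable edges with ties broken
by lowest edge id then lowest offset. There is no maximum snap distance —
participants far from any road are snapped anyway with a logged warning
(threshold 500 m); exclusion policy is left to the caller.

## Buffer constructions

*Sausage*: Minkowski sum of the reached segments with a disk of radius
`trim`, dissolved. *Detailed* and *detailed-trimmed* polygons originally
come from proprietary GIS software whose algorithm is unpublished, so this
package defines documented surrogates: dilate the reached lines by a closing
radius *R*, erode by *R − trim*. Algebraically this is a morphological
closing of the sausage polygon by a disk of radius *R − trim*, so the result
always contains the sausage, and closings by nested disks are nested —
giving the containment chain sausage ⊆ detailed-trimmed ⊆ detailed by
construction. The detailed variant additionally fills all interior rings
(enclosed blocks become neighborhood), the detailed-trimmed variant keeps
them.

Default closing radii are specified relative to the trim: `trim + 25 m`
(detailed-trimmed) and `trim + 275 m` (detailed). At the reference 25 m trim
these equal 50 m and 300 m. Making them trim-relative keeps every trim
admissible (a fixed 50 m radius would be smaller than a 75 m trim and the
erosion step would be ill-posed) and preserves the qualitative area ordering
at both packaged trims. The radii reproduce the *ordering* of the three
methods' areas on block-structured cities, not any particular magnitude;
they are configuration parameters.

All dilations/erosions discretize circles at 64 segments (shapely
`quad_segs=16`), fixed so areas are deterministic. Because a discretized
erosion can undercut the exact sausage by a sliver, the surrogate result is
explicitly unioned with the sausage polygon to restore the mathematical
containment guarantee.

## Built-environment measures

* Polygon features (parcels, parks) are assigned by *any-intersection* and
  contribute their full area and unit count — a fringe parcel counts like a
  central one. A clipped mode is deliberately not the default.
* Net residential density divides units by *residential parcel* area, not
  buffer area; an empty denominator yields 0 with a flag.
* An intersection is a walkable-network node of degree ≥ 3 (threshold
  configurable); density denominators for intersection/transit/recreation
  densities are the buffer area in km². Whether such densities should
  instead divide by land area is ambiguous in the literature; buffer area is
  used here and flagged.
* Land-use mix is normalized entropy over a fixed k = 4 categories
  (residential, retail, civic, recreational); parcels of class `other` are
  excluded from the shares, and the ln k denominator uses the configured k
  regardless of how many categories are present, so missing categories keep
  LUM < 1. Both choices are configurable.
* Point features are snapped to the network before counting by default
  (both modes exist), since destinations sit back from centerlines and a
  25 m trim would otherwise systematically miss them.
* The walkability index standardizes its three components across the
  analysis sample separately per (method, trim) with sample (ddof = 1)
  standard deviations; a zero-variance component is an error, not a silent 0.
* Park areas are stored in m²; an acre conversion (1 acre = 4046.8564224 m²)
  is provided at the reporting layer.

## Synthetic cities

The generator is the package's study-conditions module, not a test
convenience. A city is an (m × n) grid of blocks (default 12 × 12 at 120 m)
whose interior street segments are independently removed with probability
`edge_prune_prob` (default 0.15) — one parameter spans the low- to
high-connectivity contrast — plus a small limited-access fraction (0.05).
Pruning retries until the walkable part is connected. Parcels tile block
interiors (2 × 2 per block, 10 m street margin) with categories drawn from
fixed shares (residential 0.55, retail 0.15, civic 0.10, recreational 0.10,
other 0.10) and Poisson unit counts (mean 20 per residential parcel);
transit stops (0.5/km of street) and private recreation (0.3/km) are placed
along streets with a 2–30 m perpendicular offset so snapping matters; parks
occupy random blocks (p = 0.06).

Cohorts place homes 5–40 m off random street segments, form spatially
contiguous clusters by a rectangular partition of the extent, and assign
SES and walkability strata by median splits of a noisy linear SES field and
of "true walkability". True walkability is measured in a *fixed circular
800 m window* — deliberately none of the three network buffers — so no
method is privileged by construction. Outcomes follow a latent Gaussian
model: intercept + β·z(true walkability) + covariate terms + cluster
intercept N(0, 0.5²) + N(0, 1), mapped to each outcome's support
(days/week: rounded, clamped to 0–7; minutes/week: exponential link). βs
default to 0.30 for transport walking, 0.10 for leisure, −0.15 for sitting,
echoing the usual pattern that utilitarian walking responds most to
walkability. An `identity` family bypasses the support mapping for
diagnostics and parameter-recovery tests.

What the generator does *not* emulate: empirical questionnaire response
distributions (zero-inflation, digit preference), multi-city heterogeneity,
pedestrian-only paths, irregular street geometry, or correlated land-use
clustering. Passing tests therefore demonstrate internal statistical and
geometric correctness of the machinery under a known model, not
transferability of any effect estimate to real cohorts.

## Statistical choices

* The value-level *t* test is **paired** (BEM vectors are
  participant-matched); degenerate cases are flagged (`identical`: all
  differences zero, p = 1; `degenerate`: constant non-zero difference,
  p = 0) rather than raised.
* Association models are linear mixed models fitted by maximum likelihood
  (statsmodels `MixedLM`) with a Gaussian error family for all five
  outcomes — day counts are modeled on their raw 0–7 scale. This is a
  documented simplification; count and skewed-minutes families are out of
  scope. The response is internally scaled to unit variance for optimizer
  conditioning and coefficients are scaled back, which leaves p values
  unchanged. The default BEM term is linear (coefficient-level comparison
  requires it); a fixed-df cubic regression-spline term is available for
  shape diagnostics, reporting an omnibus Wald p for the basis.
* The coefficient z test treats the two estimates as independent. Shared
  participants make them positively correlated, so the test is conservative
  for detecting method differences; no correction is applied.
* α = 0.05 throughout, with no multiple-testing correction — agreement
  tabulation is descriptive, mirroring how such comparisons are reported.
* The pipeline's default configuration runs the 25 m trim and the two
  method pairs anchored at sausage (vs detailed-trimmed, vs detailed); the
  75 m trim and all-pairs comparisons are behind flags.

## Problem sizes and determinism

Packaged analyses run at desk scale by choice: the demo city has 200
participants in 15 clusters, simulation-based calibration checks use 200
recovery and 1000 type-I replicates at n = 1000 with 50 clusters, and the
z-test null uses 2000 replicates at n = 200. Every random quantity flows
from a single integer seed through `numpy.random.default_rng`; re-running
any configuration reproduces outputs byte-for-byte, and the run manifest
records a config hash (excluding the output directory) plus output
checksums to make this checkable.

## Known limitations

* The detailed/detailed-trimmed surrogates match the proprietary
  constructions qualitatively (ordering, hole behavior), not numerically;
  published mean-area gaps cannot be reproduced bit-for-bit and are not
  targets.
* Gaussian mixed models on bounded/skewed outcomes are approximate; Wald
  type-I error in simulation is slightly conservative (~4%).
* Snapped point counting assumes destinations are accessed from their
  nearest network point, which can mis-assign points near network fringes.
* Grid cities have no curved streets, so polyline generality (supported by
  the geometry code) is exercised only lightly by the generator.
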