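# Methods

## The decay model and its fit

Infestation is modeled as `y = a · exp(−MD / b)` with `MD` the edge-to-edge
Euclidean distance (meters) from a current field to the **nearest**
previous-year host-crop field. Only the nearest site enters the regression;
the influence of multiple nearby sources is handled downstream by the risk
map's overlap escalation, not by the curve. `a` is percent infestation of a
non-rotated field; `b` is the e-folding scale — the distance over which the
prediction drops by 1/e. (`b` is sometimes loosely called an inflection
point; a pure exponential has none, and this package consistently treats it
as the e-folding scale.)

`fit_decay` minimizes Σ(yᵢ − a·exp(−mdᵢ/b))² with `scipy.optimize.least_squares`
(trust-region reflective), box constraints a ∈ (0, 100] (percent domain) and
b ∈ (0, 10⁶] m (geographic plausibility), and starting values a₀ = max(y),
b₀ = max(md)/2 — robust for decay-shaped data and overridable. Convergence
tolerances are 1e-12 (xtol/ftol/gtol) with a 10 000-evaluation cap; failure
raises with the last iterate in the message. Inputs are rejected as
degenerate when there are fewer than 3 observations, fewer than 2 distinct
distances, or no positive infestation at all (the green-pea situation — the
mean observed infestation there was so low that no curve is identifiable,
which is why green peas get a fixed buffer instead of a fit).

Reported statistics follow the standard nonlinear-regression conventions,
stated explicitly because the reference values print them without formulas:

* RMSE = √(SSE / (n − p)) with p = 2 parameters;
* covariance = s²(JᵀJ)⁻¹ from the final Jacobian, SEs its diagonal roots;
* R² against the mean-only model; adjusted R² = 1 − (1 − R²)(n − 1)/(n − p − 1);
* p-values from t = estimate/SE on n − 2 degrees of freedom (a perfect fit,
  SE = 0, reports p = 0). Stars: *** p < 0.001, ** p < 0.01, * p < 0.05.

## Buffer derivation

`derive_buffers` rounds to whole meters, half away from zero: inner =
round(b_all), middle = round(b_all + SE), outer = round(b_untreated + SE).
The insecticide-free fit feeds the outer buffer because treatment status of
previous-year sites is generally unknown (and undetectable from remote
sensing), so the untreated curve is the conservative planning case. With
the shipped reference estimates this gives 1261 / 1560 / 1825 m. The
ordering inner ≤ middle ≤ outer is data-dependent; a violation warns rather
than errors. Fitted distances that coincide (e.g. when the untreated subset
is too small to fit separately) are merged into fewer bands by
`scheme_from_distances`.

## Risk map construction

Each previous-year site is buffered at the scheme distances; band 0 is the
full innermost buffer **including the source polygon** (a non-rotated field
is the maximal-risk case), band i > 0 the ring buffer(dᵢ) − buffer(dᵢ₋₁).
Classes decrease outward and must be members of the escalation ladder
(default exponential 1, 2, 4, 8; linear or custom ladders are supported via
configuration).

Flattening overlays all per-source zones exactly: the union of zone
boundaries is noded and polygonized into atomic faces, each face is
classified from the zones covering its representative point, and faces are
dissolved by (class, band, escalated). By construction the output is flat
(pairwise disjoint interiors) and conserves the buffered area.

Escalation rules, chosen where the behavior was genuinely open:

* a region covered by k ≥ 2 **distinct sources** escalates exactly one
  ladder step (the literal reading of "next highest class"); a
  `per-source-step` mode escalating k − 1 steps is available;
* mixed-class overlaps escalate from the **maximum** covering class — risk
  is at least that of the worse source;
* rings of one source touch but never overlap, so same-source adjacency
  never escalates;
* escalation saturates at the ladder maximum (an unbounded class is
  meaningless for a fixed legend).

Buffer arcs are chordal approximations with 16 segments per quarter circle;
the maximum radial shortfall is r·(1 − cos(π/64)) ≈ 0.12 % of the radius
(≈ 2.2 m at 1825 m). All geometric tolerances in the tests are stated
relative to this. The pointwise oracle used to validate the overlay computes
exact per-source distances, so probe points falling inside that chordal
shell of a band circle are ambiguous by construction and excluded from
exact-match assertions.

## Queries

A query clips every zone to a disc around the candidate coordinates
(default radius: outermost scheme distance + 500 m, so the whole
contributing neighbourhood is visible). The class at the point is the
maximum class among covering zones — on-boundary ties resolve toward higher
risk, the conservative advice. "Directions of risk" are realized as
distance and bearing (degrees clockwise from north) to the centroid of each
previous-year site whose outermost buffer covers the point.

## Vector I/O

GeoJSON and ESRI Shapefile (polygon type 5, with SHX index and DBF
attribute table) are supported; the shapefile codec is implemented in the
package. DBF's 10-character field-name limit is handled by a fixed mapping
(`infestation_pct` → `INFEST_PCT`, `insecticide` → `INSECTICID`, …); unknown
attributes pass through. A projected meter-unit CRS is required — every
distance in the method is metric — and known degree-unit identifiers
(EPSG:4326, OGC:CRS84, …) are rejected unless explicitly allowed. No
reprojection is performed; supplying data in a suitable CRS (e.g. a UTM
zone) is the caller's responsibility. Shapefiles carry no machine-readable
CRS here, so the identifier is supplied at read time. Invalid geometries get
the standard zero-distance-buffer repair (which keeps the
dominant-orientation lobes of self-intersecting rings); unrepairable or
zero-area features are rejected with their id.

## Synthetic landscapes

The generator emulates the study inputs: per year, `n_fields` parcels —
randomly rotated rectangles (aspect 1–3) perturbed to convex quadrilaterals
and rescaled to a target area drawn uniformly from 1–50 ha — placed
uniformly in a 30 km-diameter region by rejection sampling so that
same-year parcels never overlap. Years are placed independently, so some
current fields land near or on previous-year fields by chance, exercising
all distance bands. Observations are drawn from the decay curve with
additive Gaussian noise floored at 0 and capped at 100 %; defaults are the
reference parameters a = 9.79, b = 1260.7 and noise sd 9.1 (the residual
scale of the reference fit). All randomness flows from a single seed.

What the generator does **not** emulate: real parcel shapes and road/field
structure, spatial autocorrelation of infestation, dispersal barriers
(forests, urban areas), year-to-year crop-rotation agronomy, and the true
error distribution of field counts (which is certainly not additive
Gaussian — see below). Passing tests therefore demonstrate the correctness
of the geometry and the estimation machinery, not predictive skill on real
landscapes.

### A note on the noise model

At the default noise scale (sd 9.1 against an intercept of 9.79 %) the
zero-flooring dominates the signal at large distances: the mean of
max(0, m + σZ) has a pedestal of ≈ 4 % where the curve itself predicts
< 1 %. Plain least squares on such data is structurally biased toward larger
decay scales, and the 2·SE coverage of b̂ in the suite's 100-replicate
recovery study is far below nominal — the corresponding acceptance test
documents this by failing. The estimator itself is well calibrated: in a
low-censoring regime (noise sd 0.5, distances within two e-folding scales)
the same study achieves ≈ 95 % coverage. Modeling the censoring explicitly
(a Tobit-type likelihood) would remove the bias but is outside the fitting
contract of this package.

## Problem sizes

The test suite and acceptance script run on deliberately small instances:
landscapes of 6–25 fields per year in 9–15 km regions (100 fields for the
area-range check), 10 seeded landscapes × 1000 probe points for the overlay
oracle, and 100 × 200-observation replicates for the recovery study. These
sizes fully exercise every code path; the algorithms are polynomial in the
number of fields (the overlay is the dominant cost) and handle
thousand-field regions comfortably.

## Known limitations

* No dispersal barriers or landscape resistance — distance is the only
  predictor, matching the method's scope.
* Previous-site infestation intensity is deliberately ignored: the mere
  existence of a previous host site is the input, which keeps the data
  requirement to one polygon layer per year.
* Field size is not a covariate (it was examined and found uninformative in
  the underlying study).
* Single-year memory: only the immediately preceding season's sites
  contribute risk; multi-year soil persistence of other pests would need
  additional bands.
* No reprojection; meter-unit planar coordinates are assumed throughout.
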