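# Methods

`routewalk` implements a pedestrian route-choice analysis: given a street
network with audited per-edge environment attributes and a cohort of
chosen walking routes (one per pedestrian, residence to first
destination), it asks which street-environment factors pull pedestrians
away from the two canonical baseline routes — the shortest-distance route
and the least-directional-change route.

## Model

Route choice is treated as random-utility maximisation.  A pedestrian
facing routes *j* with route-level attribute vectors *x_j* receives
utility

    U_j = β′ x_j + ε_j,      ε_j ~ i.i.d. Gumbel(0, 1),

and picks the route with the highest utility, which yields the
conditional-logit choice probability

    P(j) = exp(β′ x_j) / Σ_k exp(β′ x_k).

Only attribute *differences* between the routes in a chooser's set are
identified; there is no intercept, and the Gumbel scale fixes the units
of β.  The log-likelihood is globally concave; `clogit.fit_clogit` uses
Newton iteration with the analytic gradient and Hessian from β = 0, step
halving to guarantee ascent, convergence at gradient max-norm < 1e-8 (or
relative log-likelihood change < 1e-12), and standard errors from the
inverse observed information.  p values are two-sided normal.  If the
chosen alternatives are perfectly separable the likelihood has no finite
maximum; the fitter detects the coefficient divergence (‖β‖∞ > 50 on the
working scale) and raises a `SeparationError` rather than returning a
spurious estimate.  An optional `zscore` flag rescales attributes by
their pooled standard deviation for conditioning; results are reported
back in original units.

## Labeled alternatives

Instead of enumerating many candidate paths, the choice set is generated
by labeling: exactly one route per criterion.

* **Shortest distance** — minimum total length.
* **Least directional change** — minimum cumulative angular turn cost.
  Angular cost between two edges meeting at an intersection is θ/90,
  where θ ∈ [0°, 180°] is the deviation from straight-ahead continuation
  (straight 0, right angle 1, U-turn 2).  For curved streets the bearing
  at the intersection uses the polyline chord incident to the node.  Any
  positive monotone transform of θ would select the same routes; θ/90 is
  the conventional space-syntax weighting and keeps costs in [0, 2].

Both searches run on (node, incoming-edge) states so turn costs are
additive, with a deterministic lexicographic tie-break: secondary cost
first (turn cost for the distance route, length for the angular route),
then the smallest edge-id sequence.  Because edge lengths are strictly
positive and turn costs obey the triangle inequality at each
intersection (they are angles between headings), the canonical optimum
never repeats an edge, so the state search returns edge-simple routes
without an explicit exclusion list.  We deliberately realise the
least-angular route this way rather than by backtracking the
segment-graph depth map: a segment-graph path may chain two links at the
same intersection, which corresponds to entering and backing out of a
street without paying the physical U-turn; the primal state search
cannot produce that artefact.

`routing.angular_step_depth` exposes the classical segment-map
construction itself: street edges become segment nodes, node-sharing
edge pairs become links weighted by angular cost, and depth is the
cheapest cumulative cost from any origin-incident segment (multi-source
Dijkstra, origin segments at depth 0).

Origins and destinations live on intersections; snapping trip endpoints
into edge interiors is upstream of this package.  Networks are
undirected (pedestrians ignore one-way restrictions), planar-projected
metres, with at most one edge per node pair.

## Street-environment aggregation

Each edge carries the fifteen-attribute audit record (see
`environment.ATTRIBUTE_FIELDS`).  Route-level vectors are built as:

* length-weighted means for widths, D/H ratio, ordinal condition codes
  (on-street parking, sidewalk walkability, green spaces, street walls)
  and street-frontage proportions — Σ(value·length)/Σ(length);
* raw sums for the four street-furniture counts (traffic signals,
  garbage bins, streetlights, benches), with an opt-in per-100 m
  normalisation.

Treating ordinal condition codes as interval-scaled for the weighted
mean is a deliberate simplification: the audit's "functional condition"
variables are averaged exactly like the continuous ones, and the
resulting route value is a length-weighted condition score, not a
category.  Consumers who need strict ordinal treatment should recode
upstream.

## Overlap decomposition and exclusion

The overlap ratio of a chosen route against an alternative is the summed
length of shared edges divided by the chosen route's length (a
symmetric variant, dividing by the mean of the two lengths, is available
via `denominator="symmetric"`).  Sharing means identical edge ids — both
routes live on one network, so no geometric buffering is involved — and
full overlap is exact edge-set equality.  Trips that fully overlap an
alternative are excluded before fitting the model against that
alternative: for them, distance or direction alone explains the choice
and the attribute comparison is degenerate.

Partially overlapping trips are decomposed into maximal deviated
part-routes, each bounded by the divergence and reconvergence
intersections and paired with the alternative's sub-path between the
same two intersections.  For modelling, all deviated chosen edges of a
trip are pooled into one part-route observation (and likewise on the
alternative side): the estimation unit is the pedestrian, not the loop,
so a trip with two detours still contributes one observation.

## Pipeline

`run_pipeline` fits four models — {entire route, deviated part-route} ×
{shortest, least-angular alternative} — each a two-alternative
conditional logit of the chosen side against the alternative side on a
configurable attribute subset (named presets cover the four standard
comparisons).  Reports include full-overlap counts and integer-rounded
percentages (round half up), the overlap-share distribution at
configurable thresholds (default 0.6–1.0), and mean trip lengths overall
and by overlap group (no hypothesis test on the difference).  All output
files use fixed float formatting (3 decimals for coefficients, matching
choice-model table conventions) so identical inputs produce
byte-identical outputs.

A modelling caveat that matters for simulation studies: after excluding
full-overlap trips, every retained observation has, by construction, the
chosen route "beating" the alternative, so the post-exclusion models are
fitted on all-one outcomes.  This mirrors standard practice for
generated-alternative route-choice models and is estimable whenever no
direction of attribute space weakly separates the differences, but it is
*not* a consistent estimator of the generating coefficients when the
data were simulated from a discrete choice between exactly those two
alternatives — conditioning on the winner truncates the sample.
Parameter-recovery validation therefore estimates on the generation
choice set itself (both outcomes present, `synthetic.pairwise_design` +
`clogit.fit_clogit`), where the conditional-logit MLE is consistent; the
pipeline's post-exclusion models are validated for bookkeeping and
determinism, not recovery.

## Synthetic data generator

The generator emulates a compact, aging residential neighbourhood with
short utilitarian walking trips.  Defaults (all overridable in
`SyntheticConfig`):

* **Network**: 8×8 intersection grid; block lengths uniform on
  60–140 m (mean 100 m); node jitter N(0, 4 m) so turns spread around 0
  and 1 rather than being exactly rectilinear.
* **Attributes** per edge: sidewalk width lognormal(ln 2.0, 0.30) m,
  driveway width lognormal(ln 6.0, 0.30) m, D/H lognormal(ln 1.2,
  0.40); condition codes categorical (e.g. green spaces 40/40/20% for
  codes 1/2/3); counts Poisson with per-100 m rates (garbage bins 1.5,
  streetlights 3.0, benches 0.5, signals 0.3) scaled by edge length;
  frontage proportions Beta (shops Beta(1.2, 6), bus stops
  Beta(0.5, 15), …).
* **Trips**: 219 OD pairs (the cohort size the analysis is designed
  around) whose shortest-path length lies in [0.5, 2]× the 350 m trip
  scale; within that band candidates are accepted with a Gaussian
  weight centred on the scale (sd 30%), so the cohort mean sits near
  350 m instead of at the band's centre of mass.
* **Choices**: true coefficients β = (+1.0 green spaces, −0.5 sidewalk
  width) on the Gumbel scale; pairwise mode draws the utility-maximising
  route from the two labeled alternatives (when they coincide the common
  route is returned and the trip is a full-overlap case).  Choice-set
  mode adds random simple-path detours (shortest paths under perturbed
  edge weights) to demonstrate — not correct — the misspecification
  that arises when the true choice set is larger than the estimated one.

All randomness flows through one seed; each stage (layout, attributes,
OD sampling, choice noise, detours) uses an independent child stream
keyed by stage name, so outputs are reproducible stage by stage.

What the generator does **not** emulate: GPS measurement error and
map-matching artefacts, free-form chosen routes that differ from *both*
labeled alternatives, irregular (non-grid) street topology, spatial
autocorrelation of environment attributes along corridors, and
heterogeneity of preferences across pedestrians.  Passing tests
therefore demonstrate the correctness of the machinery and the
estimator's calibration under the stated model — not that the model is
adequate for any particular real street network.

## Numerical choices and degenerate inputs

* Log-likelihoods use log-sum-exp stabilisation and `math.fsum`
  accumulation, so the null value on n paired observations is exactly
  −n ln 2.
* Overlap ratio returns exactly 1.0 for identical edge sets, independent
  of float summation order.
* Percentages round half up to integers.
* Node snapping on GeoJSON load uses a 1e-6 m tolerance; declared edge
  lengths must match polyline arc length to 1e-6 relative.
* Empty routes, misaligned OD pairs, missing attribute rows, parallel
  edges, self-loops and unreachable destinations all raise typed errors
  naming the offending id.
* Trips whose deviated edge set is empty on either side (possible only
  for non-simple chosen routes) are skipped in part-route models with a
  count in the model notice; a configurable minimum deviated length
  (default 0 m) can additionally drop trivial detours.

## Problem sizes used in validation

The validation suite runs at deliberately compact sizes: routing
correctness on ~50 random networks of ≤ 20 nodes against exhaustive
enumeration, likelihood identities at a few hundred observations,
recovery at n = 500 trips with 200-replication Wald calibration,
decomposition on 1,000 OD pairs, and full pipeline runs on cohorts of
120–219 trips.  These sizes give stable Monte-Carlo checks while keeping
the whole suite fast; all of them scale linearly in code if larger
studies are needed.

## Known limitations

* Ordinal-as-interval aggregation (above).
* The two audit facility categories "life facilities" and "leisure
  facilities" have overlapping definitions in the source audit tool;
  both are kept as distinct columns and the user is responsible for not
  double-loading a model with collinear pairs.
* No path-size or overlap correction for correlated alternatives: models
  are fitted pairwise (chosen vs one alternative), so utilities are
  interpreted per comparison, and the four models are not a joint model
  of a three-route choice set.
* No length/detour-factor constraint on the least-angular route: on
  pathological networks it can be much longer than the shortest route.
* No clustered or robust standard errors; one observation per pedestrian
  is assumed independent.
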