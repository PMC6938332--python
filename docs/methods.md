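# Methods

This note records the models, conventions and numerical choices behind
`condorcircuit`, in the order the pipeline runs them.

## Occurrence filtering

Telemetry records carry `bird_id, timestamp, x, y, speed_mps, proofed` in a
single shared projected CRS (metres). The flight filter keeps records with
`proofed == 1` and speed **strictly** between 2.78 and 30.0 m/s — a fix at
exactly 2.78 m/s is treated as stationary and dropped. Offshore points are
removed via a land/ocean mask supplied by the caller (any mask resolution is
accepted; the package does not define "offshore" beyond the mask). Points
within each site's exclusion radius (default 5 km — release sites see
artificially inflated movement from baiting and pen attraction; a former
release site used for trapping is modelled as just another site entry) are
removed by Euclidean distance, boundary inclusive. Daily thinning keeps one
uniformly random record per bird per calendar day; the day boundary defaults
to UTC and is configurable, since real deployments rarely record the local
timezone. All filters are set operations, so the speed and zone filters
commute; thinning is seeded and deterministic regardless of input order.

Background data: the convex hull of the filtered flight points is buffered
by 10 km, clipped to land, and 10,000 points (default) are drawn uniformly
by rejection sampling over the hull's bounding box, excluding the site
exclusion zones. Rejection sampling is exact, simple and reproducible under
a seed; the loop aborts with a diagnostic if the acceptance rate collapses
(e.g. an all-ocean mask).

## Conductance model

The habitat model for birds in flight is a Gibbs distribution over the
background cells,

    p(x) ∝ exp( Σ_j λ_j f_j(x) ),

with one linear and one quadratic feature per covariate, each rescaled to
[0, 1] using background minima/maxima (the rescaling constants are stored in
the model so it can be projected to novel regions). Fitting maximises the
L1-regularised mean log-likelihood of the presences by sequential coordinate
descent: one exact bounded 1-D minimisation per feature per pass (with an
explicit test of the λ_j = 0 kink), capped at 5,000 single-feature updates.
The regularisation weight per feature is
`beta_multiplier · sd(f at presences) / √m` (floored at 1e-6), with
`beta_multiplier = 1.0` by default and exposed in the settings; the
regularised training gain is reported relative to the uniform background
model, is non-negative, and is non-decreasing across updates (each update is
an exact 1-D ascent). Early convergence (a full pass improving the gain by
less than 1e-7) is recorded on the model, not raised. Duplicate presences
are retained.

Projection clamps raw covariates to their training range, so predictions
outside the range equal the boundary prediction. The logistic output is
`c·p / (1 + c·p)` with `c = exp(H)`, `H` the entropy of the fitted
background distribution; its mean over the training background sits near
0.5 for typical fits and it is used directly as conductance — no non-linear
transform is applied, because the presences are in-flight, moving birds.

Evaluation uses random 5-fold cross-validation of the presences: per fold,
the regularised training gain, the rank-based AUC of withheld presences
against the background, and AIC = 2K − 2 lnL with K the number of nonzero
lambdas and lnL the summed log raw probability of **all** presences under
the fold's background-renormalised model (the convention commonly used to
compare presence-background models when the likelihood itself is defined
only relative to the background). The per-fold baseline of the gain is the
uniform background model. The candidate with the lowest mean AIC wins; ties
go to fewer covariates. Percent contribution attributes each positive gain
increment to the covariate whose feature was updated and normalises to 100.

Collinearity screening computes pairwise Spearman correlations of covariate
values at the movement points and, for |r_s| > 0.70, drops the
lower-priority covariate (priority = the caller's stated biological
ordering, defaulting to stack order). A covariate constant at the points has
undefined r_s; it is reported and retained.

Derived covariates: focal statistics (mean, median, and density — summed
value × cell area, e.g. habitat km² within the window) use circular windows
of cells whose centres fall within the radius; windows shrink at grid edges
and never wrap; nodata cells are excluded, and an empty window yields
nodata. Terrain ruggedness is the ratio of 3-D to planar surface area in the
focal window, with the per-cell surface triangulated as eight triangles
joining the cell centre to the midpoints toward its eight neighbours — the
planar projections of those triangles tile the cell exactly, so flat terrain
gives exactly 1 and an inclined plane gives 1/cos θ. Slope is Horn's 3×3
finite difference in degrees with replicated edge rows/columns.

## Circuit engine

Land cells become nodes; 8-neighbour edges carry the mean of the two cell
conductances, divided by √2 on diagonals (the average-conductance lattice
convention; the choice is a convention, not an estimate, and is shared with
the linkage stage's move costs). Before graph construction the conductance
surface is filled so current can flow everywhere: ocean cells take the
minimum in-study conductance (soaring birds avoid open water), terrestrial
cells outside the study area take the in-study median (a neutral constant
for flow, not a movement estimate).

One solve per (source, ground) pair: the ground is a direct 0-V tie (an
optional per-ground resistance shifts voltages without changing currents for
single-pair solves), the source injects a configured current (default 1 A),
and the reduced Laplacian system is solved by sparse LU factorisation that
is computed once per connected component and reused across the ring of
grounds — the contract is the solution, not the solver. Per-cell current is
half the sum of absolute incident edge currents, with source and ground
cells reporting the full injection, so a pass-through cell in a series chain
reports the through-current. Ground-ring geometry: points every 10 km along
the boundary of the union of 350-km site buffers, starting from the
easternmost point; the node count is ceil(perimeter/spacing), which is 220
for a single site. The direction-neutral map is the unweighted mean over all
pairs, ×1,000 to milliamps. A post-hoc attractant overlay solves
source-to-destination pairs for named high-use cells, averages them in mA,
and takes the cellwise maximum with the ring map.

## Calibration

Current values are extracted at movement points within 300 km of a release
site (current near the ground ring is biased by the ring itself). The
continuous Boyce index uses moving windows of width 0.1 × the map range
centred at 101 evenly spaced values (the conventions of the R package that
popularised the index); P/E per window is the point fraction over the cell
fraction, zero-expectation windows are skipped, ties take average ranks, and
a constant map yields an explicitly undefined (NaN) index with a diagnostic
rather than 0. A disjoint-bin mode exists in which the
expectation-weighted mean of P/E is exactly 1, used for invariant checking.
The expected distribution is taken from land cells within the evaluation
limit, **excluding cells whose area intersects a site exclusion zone**
(centre distance ≤ radius + cell half-diagonal): the filtered points cannot
fall there, and because the source cell and its immediate neighbours carry a
1/d current spike, leaving them in the expected distribution forces zero
P/E in every top window regardless of model quality. The reverse cumulative
curve reports the fraction of point values at or above each 1-mA threshold,
starting at exactly 1 and ending one bin above the maximum.

The index is exactly invariant under affine transforms of the map (windows
scale with the range); under general monotone transforms the fixed-width
windows change membership, so exact invariance is not guaranteed and is not
claimed.

## Linkage

Resistance is 1/conductance (zero conductance must be masked or floored
upstream). Core patches binarise the nesting-suitability raster at ≥ 0.04,
label 8-connected components, and drop patches under 10 km². Cost-weighted
distance runs multi-source Dijkstra from all patch cells with move cost =
mean of the two cells' resistances × centre distance in cell-size km (×√2
diagonal). Candidate pairs come from cost-weighted allocation adjacency
(each cell assigned to its CWD-nearest patch, ties to the lower patch id;
regions sharing an 8-neighbour boundary are candidates). Each link follows
the least-cost path through the cell minimising CWD_a + CWD_b, backtracked
along both predecessor grids; a link whose interior cells lie inside a third
patch is dropped, as is a pair with no finite path (both logged). Entry
ties are broken deterministically by Dijkstra's fixed node ordering.

## Synthetic data

The generator emulates the statistical regime the analysis assumes, not its
physics. Covariate fields are Gaussian-smoothed white noise standardised to
zero mean and unit variance, with the kernel width set so the empirical
spatial correlation falls to 0.5 at lag = `autocorr_range`; an ocean strip
occupies the west edge. Truth conductance is the inverse-logit of a linear +
quadratic function of the covariates. Telemetry is per-cell multinomial:
fix locations are drawn with probability ∝ conductance × exp(−d/decay) over
land cells outside the site exclusion zone (plus a half-cell-diagonal margin
so jittered coordinates stay outside), with uniform jitter inside the cell;
there is no within-day movement autocorrelation, which is irrelevant
downstream because daily thinning keeps one point per bird-day. Disjoint
salted categories — unproofed fixes, sub-window and super-window speeds,
offshore points, and a cluster inside the exclusion zone — are injected with
exact counts so each filter's removal count is checkable record-for-record.

The scaled synthetic study used by the end-to-end checks runs on a 96×96
grid of 2-km cells with an 80-km ground ring (10-km spacing), a 65-km
evaluation limit and a 20-km decay length. The decay-to-evaluation-radius
ratio (~0.3) matches the regime of strongly site-concentrated movement the
method assumes; with decay comparable to the region size the movement field
is near-uniform and a distance-structured current map cannot (and should
not) appear calibrated. What passing tests show is that the pipeline
recovers a known generating structure under these assumptions; they say
nothing about autocorrelated real trajectories, seasonal or meteorological
structure, or social attraction, none of which the generator emulates.

## Numerical conventions and edge cases

- Grids: row 0 at the north edge, cell-centre coordinates, NaN nodata in
  memory, −9999 in ASCII grid files; all stages require one shared projected
  CRS and refuse to reproject.
- Circuit solves: direct sparse LU (the lattice sizes used here are far
  below the regime where an iterative solver would pay off); disconnected
  source/ground pairs raise an error naming the two components.
- Degenerate inputs raise rather than guess: negative speeds, all-zero
  conductance, collinear hulls, empty study areas, constant maps (Boyce),
  single-cell DEMs.
- Seeds: every stochastic step takes an explicit seed; the pipeline derives
  stage seeds from the config seed, and reruns are bit-identical on CSV/JSON
  outputs and within 1e-12 on grids.

## Known limitations

Conductance is isotropic and static — no wind fields, no seasonal or
time-varying surfaces, no behavioural states. The model class is linear +
quadratic features only (by design, to avoid overfitting when projecting to
novel regions). The linkage stage maps least-cost paths, not corridor
widths or within-corridor pinch points. Movement is modelled at the
population level; individual-based simulation is out of scope.
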