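# Methods

## Surface model

The interpolant is a tensor-product Chebyshev polynomial
z(x, y) = Σ_ij a_ij T_i(x′) T_j(y′), fitted by ordinary least squares to
the station values. Chebyshev polynomials of the first kind are used purely
as a well-conditioned basis for polynomial least squares on a rectangle:
the fitted function space is identical to the monomial tensor space of the
same orders (a property the test suite checks against an independent
monomial-basis fit), but the design matrix stays numerically benign at
orders where a raw Vandermonde matrix would be hopeless.

Reference mapping. Physical coordinates are mapped affinely onto
[−1, 1]²; the reference rectangle defaults to the bounding box of the
fitting stations (optional fractional padding, default 0). In
cross-validation and twin-experiment pipelines the box is derived from the
full station set or the known study domain rather than the per-fold
training subset, so held-out points and grid nodes never leave the
reference square — Chebyshev polynomials grow like cosh(m·arccosh t)
outside [−1, 1], and at order 10 even a few percent of overshoot is
ruinous. Evaluation at points slightly outside the square remains defined
and finite.

Solver. `scipy.linalg.lstsq` (SVD, LAPACK gelsd) with a relative
singular-value cutoff of 1e−10. The fit demands N ≥ (s+1)(k+1) and raises
otherwise; a design that is rank deficient despite sufficient N (e.g.
degenerate station geometry) warns and returns the minimum-norm solution.
The results object retains residuals, rank, singular values and the
condition number for diagnostics.

Coefficient layout. `coeffs[i, j]` multiplies T_i(lon′)·T_j(lat′); the
design-matrix column for (i, j) sits at flat index i·(k+1)+j (longitude-
order major, the `numpy.polynomial.chebyshev.chebvander2d` convention).
Serialized surfaces (plain JSON) carry orders, domain and the coefficient
matrix and round-trip losslessly.

Negative values. A polynomial surface can dip below zero where the field
is near zero; raw values are always used for error metrics, and clipping
at zero is a presentation-only flag.

Geometry. All coordinates are planar degrees (plate carrée). The method
parameters that carry length units — influence radius, radius step,
variogram range — are specified in degrees, so no great-circle metric is
introduced anywhere; at mid-latitudes this stretches the east–west axis
relative to ground distance, which is a property of the parameterization,
not an implementation choice.

## Comparators

Cressman objective analysis: single-pass weighted mean with kernel
w(d) = (R²−d²)/(R²+d²) for d < R, zero otherwise. The radius is adaptive
per grid point: start at r0 = 4°, grow in 0.1° steps until at least five
stations lie strictly inside (d < R; a station at exactly d = R would get
zero weight anyway, so the strictness is observationally irrelevant). A
hard cap (default: the diagonal of the station bounding box) turns
pathological coverage into an explicit error naming the offending point
rather than an endless radius search. No successive-correction iterations
are applied.

Ordinary kriging: global (all stations in every system), with a fixed
spherical semivariogram — γ(h) = nugget + sill·(1.5 h/a − 0.5 (h/a)³) up
to the range a, constant beyond, γ(0) = 0. Defaults a = 10°, sill = 1,
nugget = 0. The (N+1)-row system with the unbiasedness row is LU-factorized
once per station set and solved against all query points at once. With
nugget 0 the predictor honours the data exactly at stations. Kriging
weights — hence estimates — are invariant to rescaling the sill (only the
kriging variance scales), so the sill's units never affect the
interpolated field; a moment-estimator variogram fit is available but off
by default, keeping the fixed a-priori variogram as the reference
behaviour. Duplicate station coordinates are rejected at data construction,
which is what would otherwise make the system singular.

## Evaluation protocol

Metrics: MAE and RMSE (RMSE ≥ MAE always; asserted on every output), plus
an error-composition histogram of |error| over [0,5), [5,10), [10,15),
[15,20), [20,∞) μg·m⁻³ (lower-inclusive bins, proportions summing to 1).
Twin-experiment runs score estimates against the prescribed truth at all
grid nodes; practical-style runs score at held-out stations.

Cross-validation: 8 folds, each holding out 15 stations. "Well
distributed" is operationalized as spatial stratification: seeded k-means
with k = 15 on (lon, lat), one station drawn per cluster per fold. When
every cluster holds at least 8 stations the validation sets are disjoint
across folds (each cluster contributes a distinct member per fold); with
fewer, the plan falls back to with-replacement sampling across folds and
logs it. Plans are deterministic given the seed. The across-fold average
is the arithmetic mean of the fold MAEs.

Order search: cross-validated MAE for every (s, k) in {1..max_order}²
(default cap 10 — beyond that the coefficient count outruns what a
~200-station network can estimate and validation errors explode).
Infeasible cells are reported as missing, not +∞, so the MAE surface can
be inspected honestly. Ties at the argmin break toward parsimony: smallest
s + k, then smallest s.

## Synthetic twin experiments

The generator prescribes Gaussian-blob truth fields over a study box that
approximates central/southern China (lon 97–123°, lat 18–38°,
config-overridable). Two presets encode the two canonical contamination
geometries: IE1 — heavy centre in the northwest quadrant, clean centre in
the southeast; IE2 — heavy centre in the southeast, clean centre in the
southwest. Defaults (background 70 μg·m⁻³; amplitudes +60 / −55 for IE1
and +60 / −50 for IE2; widths 5°; centres at quadrant midpoints) were
chosen so field values span roughly 10–130 μg·m⁻³, the range of typical
daily PM2.5 maps, with the heavy/clean structure at the quadrant scale.
Station networks are placed by seeded jittered-grid sampling (225 stations
by default) and observation noise is i.i.d. Gaussian, default sd 0.

What the surrogates do not emulate: the spatial heterogeneity of a real
city network (jittered-grid placement is space-filling and nearly uniform,
with none of the dense-east/sparse-west clustering of actual monitoring
networks), multi-scale structure beyond two Gaussian centres, anisotropy,
and any temporal dimension. Passing twin-experiment tests therefore
demonstrates correctness of the machinery and the qualitative behaviour of
the methods on smooth bimodal fields — not performance claims for any real
observing day. One consequence is measurable here: with uniform coverage
and sd-5 observation noise, nugget-0 kriging reproduces the noise at and
near stations (a grid-MAE floor around 2.6 μg·m⁻³ under the default
conditions) while Cressman's 4°-radius averaging suppresses noise
strongly, so Cressman can out-score kriging on fields this smooth even
though it is much the weaker method on fields with real small-scale
detail. The Chebyshev surface fit is the most accurate of the three under
noise in these conditions, and in hold-out cross-validation on noisy
networks the ordering surface fit < kriging < Cressman does emerge (see
`scripts/acceptance.py` output).

## Numerical choices and limitations

* SVD cutoff 1e−10; condition numbers are logged, and instances used in
  equivalence tests are restricted to condition < 1e8.
* Grid node counts are floor((extent/spacing) + 1e−9) + 1, so an exactly
  commensurate spacing includes both boundaries.
* Fold construction, station sampling and noise all flow from explicit
  integer seeds via `numpy.random.default_rng`; reruns are bitwise
  reproducible.
* The CLI is a thin layer over the library; every run logs its seed and a
  hash of the effective configuration.
* No spherical-geometry basis, no regularized fits, no universal kriging,
  no anisotropic or non-spherical variograms, no multi-pass Cressman.
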