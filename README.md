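# opfgrid

Spatial interpolation of scattered air-pollutant observations (daily PM2.5
city averages, μg·m⁻³) onto regular longitude/latitude grids. The package
is built around **orthogonal polynomial fitting (OPF)**: least-squares
fitting of a tensor-product Chebyshev surface to the station data. Two
classical interpolators are included as comparators — **Cressman objective
analysis** with an adaptive influence radius and global **ordinary kriging**
with a spherical semivariogram — together with the twin-experiment
simulator and cross-validation protocol used to score all three.

It is aimed at air-quality and exposure-assessment work where station
networks are sparse (a few hundred city values over a subcontinental
domain) and a smooth, full-coverage concentration field is needed as input
to health-impact or trend analyses.

## The model

Station coordinates are mapped affinely onto the reference square
[−1, 1]². The fitted surface is

    z(x, y) = Σ_{i=0}^{s} Σ_{j=0}^{k} a_ij · T_i(x′) · T_j(y′)

where T_m(t) = cos(m·arccos t) is the Chebyshev polynomial of the first
kind, (s, k) are the polynomial orders in the longitude and latitude
directions, and the coefficients a_ij minimise the sum of squared
residuals at the N stations (rank-revealing SVD least squares; the fit
requires N ≥ (s+1)(k+1)). Orders are selected by 8-fold hold-out
cross-validation: each fold holds out 15 spatially well-distributed
stations (one per k-means cluster), the surface is fitted to the rest, and
the validation MAE is averaged over folds for every (s, k) in {1..10}².

Comparators, parameterized as is conventional for degree-based networks:
Cressman weights w = (R²−d²)/(R²+d²) with the radius R grown from 4° in
0.1° steps until at least five stations fall inside; ordinary kriging with
a fixed spherical semivariogram (range 10°, sill 1, nugget 0), solved as
the usual (N+1)-row constrained system with a Lagrange multiplier.

## Worked example

```python
import opfgrid as og

field = og.ie1_preset()                      # synthetic truth field
stations = og.sample_stations(field, n=225, seed=1)

model = og.ChebyshevOPF(stations, s=5, k=5, domain=field.domain)
res = model.fit()
print(res.summary())

grid = og.GridSpec(field.domain, d_lon=0.25, d_lat=0.25)
est = res.predict_grid(grid)
truth = og.truth_on_grid(field, grid)
print(f"grid MAE vs truth: {og.mae(est, truth):.4f} ug/m3")
```

prints

```
Chebyshev orthogonal polynomial surface fit
===============================================
Stations:            225
Orders (s, k):       (5, 5)
Coefficients:        36
Design rank:         36
Condition number:    18
Domain lon:          [97.000, 123.000] deg E
Domain lat:          [18.000, 38.000] deg N
Residual MAE:        0.7328 ug/m3
Residual RMSE:       0.8764 ug/m3
grid MAE vs truth: 0.8061 ug/m3
```

The residual MAE/RMSE summarise misfit at the 225 fitting stations; the
grid MAE scores the reconstruction against the known truth field at all
8505 grid nodes — the twin-experiment measure of interpolation skill.

The same workflow is available from the shell:

```sh
opfgrid simulate --preset ie1 --n 225 --seed 1 --noise-sd 5 \
    --out-stations stations.csv --out-truth truth.csv
opfgrid fit --stations stations.csv --method opf --s 5 --k 5 --out grid.csv
opfgrid cv --stations stations.csv --seed 1 --out folds.csv
opfgrid order-search --stations stations.csv --seed 1 --out mae_matrix.csv
opfgrid compare --stations stations.csv --truth truth.csv
```

## File formats

* stations CSV — header `id,lon,lat,value` (any order, case-insensitive);
  lon/lat in degrees, value in μg·m⁻³. Rows with a missing or non-numeric
  value are dropped (logged); duplicate coordinates are an error.
* grid CSV — long format `lon,lat,value`, longitude varying fastest;
  missing values are empty fields.
* surface JSON — `{s, k, domain: {lon_min, lon_max, lat_min, lat_max},
  coeffs: [[...]]}`, losslessly round-trippable.
* fold table CSV — `fold,method,mae,rmse,n` (plus method parameters);
  order-search matrix CSV — s as rows, k as columns.
* config YAML — dotted keys such as `opf.s`, `cressman.r0`,
  `kriging.range`, `cv.n_folds`; unknown keys are rejected.

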