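"""Cressman objective analysis and ordinary kriging contracts."""

import numpy as np
import pytest

import opfgrid as og
from opfgrid.errors import (DuplicateStationError, InvalidLagError,
                            InvalidRadiusError, NoNeighborsError)

from conftest import random_stations


# ---------------------------------------------------------------- Cressman

@pytest.mark.parametrize(
    "p1,p2,expected",
    [((110, 30), (110, 30), 0.0),
     ((110, 30), (113, 34), 5.0),
     ((100, 20), (101, 20), 1.0)],
)
def test_degree_distance(p1, p2, expected):
    assert og.euclidean_degree_distance(p1, p2) == pytest.approx(expected)
    assert og.euclidean_degree_distance(p2, p1) == pytest.approx(expected)


@pytest.mark.parametrize(
    "d,R,expected",
    [(0.0, 4.0, 1.0), (4.0, 4.0, 0.0), (2.0, 4.0, 0.6), (5.0, 4.0, 0.0)],
)
def test_cressman_weight_values(d, R, expected):
    assert og.cressman_weight(d, R) == pytest.approx(expected)


def test_cressman_weight_monotone_and_bounded():
    d = np.linspace(0, 5, 200)
    w = og.cressman_weight(d, 4.0)
    assert np.all(w >= 0) and np.all(w <= 1)
    assert np.all(np.diff(w[d < 4.0]) < 0)
    with pytest.raises(InvalidRadiusError):
        og.cressman_weight(1.0, 0.0)


def test_cressman_constant_field(rng, unit_domain):
    stations = random_stations(rng, 12, unit_domain,
                               values=np.full(12, 33.0))
    est, _ = og.cressman_interpolate(stations, [0.4, 0.8], [0.5, 0.2],
                                     og.CressmanParams(r0=2.0))
    np.testing.assert_allclose(est, 33.0, atol=1e-12)


def test_cressman_hand_computed_oracle():
    """Six stations at known distances, radius fixed large."""
    lons = np.array([0.0, 1.0, 2.0, 0.0, -1.5, 0.5])
    lats = np.array([0.5, 0.0, 1.0, -2.0, 0.0, 0.5])
    vals = np.array([10.0, 20.0, 30.0, 40.0, 50.0, 60.0])
    st = og.StationSet(ids=list("abcdef"), lons=lons, lats=lats, values=vals)
    R = 10.0
    d = np.hypot(lons, lats)
    w = (R * R - d * d) / (R * R + d * d)
    expected = float(np.sum(w * vals) / np.sum(w))
    est, radii = og.cressman_interpolate(
        st, [0.0], [0.0], og.CressmanParams(r0=R, min_neighbors=5, r_max=20.0)
    )
    assert est[0] == pytest.approx(expected, abs=1e-12)
    assert radii[0] == pytest.approx(R)


def test_cressman_envelope_property(rng, unit_domain):
    """Estimates are convex combinations of in-range station values."""
    stations = random_stations(rng, 40, unit_domain)
    params = og.CressmanParams(r0=0.3, r_step=0.05, min_neighbors=5)
    qlon = rng.random(25)
    qlat = rng.random(25)
    est, radii = og.cressman_interpolate(stations, qlon, qlat, params)
    for e, x, y, R in zip(est, qlon, qlat, radii):
        d = np.hypot(stations.lons - x, stations.lats - y)
        in_range = stations.values[d < R]
        assert len(in_range) >= 5
        assert in_range.min() - 1e-12 <= e <= in_range.max() + 1e-12


def test_cressman_adaptive_radius_grows_on_ladder():
    """Five stations just outside r0: the radius steps up until they fit."""
    lons = 5.03 * np.cos(np.linspace(0, np.pi, 5))
    lats = 5.03 * np.sin(np.linspace(0, np.pi, 5))
    st = og.StationSet(ids=list("abcde"), lons=lons, lats=lats,
                       values=np.arange(5.0))
    est, radii = og.cressman_interpolate(
        st, [0.0], [0.0], og.CressmanParams(r0=4.0, r_step=0.1, r_max=30.0)
    )
    # smallest radius on the 4.0 + m*0.1 ladder strictly above 5.03
    assert radii[0] == pytest.approx(5.1)
    assert np.isfinite(est[0])


def test_cressman_no_neighbors_error_names_point():
    st = og.StationSet(ids=list("abcde"), lons=[10, 11, 12, 10, 11],
                       lats=[10, 10, 10, 11, 11], values=np.ones(5))
    res = og.Cressman(st, og.CressmanParams(r0=1.0, r_max=2.0)).fit()
    with pytest.raises(NoNeighborsError, match="lon=0.0"):
        res.predict([0.0], [0.0])


def test_cressman_too_few_stations_is_global_error(unit_domain, rng):
    stations = random_stations(rng, 3, unit_domain)
    with pytest.raises(ValueError, match="min_neighbors"):
        og.Cressman(stations, og.CressmanParams(min_neighbors=5))


def test_cressman_permutation_invariance(rng, unit_domain):
    stations = random_stations(rng, 30, unit_domain)
    shuffled = stations.subset(rng.permutation(30))
    params = og.CressmanParams(r0=0.4, min_neighbors=4)
    q = (rng.random(10), rng.random(10))
    a, _ = og.cressman_interpolate(stations, *q, params)
    b, _ = og.cressman_interpolate(shuffled, *q, params)
    np.testing.assert_allclose(a, b, atol=1e-12)


# ----------------------------------------------------------------- kriging

@pytest.mark.parametrize(
    "h,expected",
    [(0.0, 0.0), (10.0, 1.0), (5.0, 0.6875), (25.0, 1.0)],
)
def test_spherical_semivariogram_values(h, expected):
    model = og.VariogramModel(range_a=10.0, sill=1.0, nugget=0.0)
    assert og.spherical_semivariogram(h, model) == pytest.approx(expected)


def test_semivariogram_nondecreasing_and_lag_error():
    model = og.VariogramModel(range_a=10.0, sill=2.0, nugget=0.5)
    h = np.linspace(0.0, 15.0, 400)
    g = og.spherical_semivariogram(h, model)
    assert np.all(np.diff(g) >= -1e-12)
    assert g[0] == 0.0
    assert g[-1] == pytest.approx(2.5)
    with pytest.raises(InvalidLagError):
        og.spherical_semivariogram(-0.1, model)


def test_kriging_constant_field(rng, unit_domain):
    stations = random_stations(rng, 15, unit_domain,
                               values=np.full(15, 77.0))
    est = og.ordinary_kriging(stations, rng.random(9), rng.random(9),
                              og.VariogramModel(range_a=2.0))
    np.testing.assert_allclose(est, 77.0, atol=1e-8)


def test_kriging_weights_sum_to_one(rng, unit_domain):
    stations = random_stations(rng, 30, unit_domain)
    res = og.OrdinaryKriging(stations, og.VariogramModel(range_a=1.5)).fit()
    _, w = res.predict(rng.random(40), rng.random(40), return_weights=True)
    np.testing.assert_allclose(w.sum(axis=0), 1.0, atol=1e-10)


def test_kriging_exact_interpolation_at_stations(rng, unit_domain):
    stations = random_stations(rng, 20, unit_domain)
    est = og.ordinary_kriging(stations, stations.lons, stations.lats,
                              og.VariogramModel(range_a=1.5, nugget=0.0))
    np.testing.assert_allclose(est, stations.values, atol=1e-8)


def test_kriging_dense_solver_oracle():
    """Five stations on a line vs an independently assembled dense solve."""
    lons = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
    lats = np.zeros(5)
    vals = np.array([3.0, 5.0, 4.0, 8.0, 7.0])
    st = og.StationSet(ids=list("abcde"), lons=lons, lats=lats, values=vals)
    model = og.VariogramModel(range_a=3.0, sill=2.0)
    q = (np.array([1.6]), np.array([0.4]))

    def gamma(h):
        r = np.minimum(h / 3.0, 1.0)
        return np.where(h == 0, 0.0, 2.0 * (1.5 * r - 0.5 * r ** 3))

    n = 5
    A = np.ones((n + 1, n + 1))
    A[n, n] = 0.0
    dist = np.hypot(lons[:, None] - lons[None, :], lats[:, None] - lats[None, :])
    A[:n, :n] = gamma(dist)
    b = np.ones(n + 1)
    b[:n] = gamma(np.hypot(lons - q[0][0], lats - q[1][0]))
    w = np.linalg.solve(A, b)[:n]
    expected = float(w @ vals)

    est = og.ordinary_kriging(st, *q, model)
    assert est[0] == pytest.approx(expected, abs=1e-8)


def test_kriging_sill_invariance(rng, unit_domain):
    """Rescaling the sill changes variances, never estimates."""
    stations = random_stations(rng, 25, unit_domain)
    q = (rng.random(30), rng.random(30))
    base, var1 = og.ordinary_kriging(
        stations, *q, og.VariogramModel(range_a=1.2, sill=1.0),
        return_variance=True)
    scaled, var9 = og.ordinary_kriging(
        stations, *q, og.VariogramModel(range_a=1.2, sill=9.0),
        return_variance=True)
    np.testing.assert_allclose(base, scaled, atol=1e-8)
    np.testing.assert_allclose(var9, 9.0 * var1, rtol=1e-8)


def test_kriging_input_errors(rng, unit_domain):
    with pytest.raises(ValueError, match="at least 2"):
        og.OrdinaryKriging(random_stations(rng, 1, unit_domain))
    with pytest.raises(DuplicateStationError):
        og.StationSet(ids=["a", "b"], lons=[1.0, 1.0], lats=[2.0, 2.0],
                      values=[5.0, 6.0])


def test_kriging_permutation_invariance(rng, unit_domain):
    stations = random_stations(rng, 25, unit_domain)
    shuffled = stations.subset(rng.permutation(25))
    q = (rng.random(12), rng.random(12))
    a = og.ordinary_kriging(stations, *q)
    b = og.ordinary_kriging(shuffled, *q)
    np.testing.assert_allclose(a, b, atol=1e-8)
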