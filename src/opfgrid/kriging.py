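"""Ordinary kriging with a spherical semivariogram.

The semivariogram is fixed a priori (range 10°, sill 1, nugget 0 by
default) rather than fitted to the data; an optional moment-estimator fit
is provided but off by default. Kriging is global: every station enters
every system, which is appropriate for networks of a few hundred stations.

For each query point x0 the ordinary-kriging weights solve the (N+1)-row
system

    [ Γ  1 ] [ w ]   [ γ₀ ]
    [ 1ᵀ 0 ] [ μ ] = [ 1  ],

with Γ_ab = γ(|x_a − x_b|), γ₀_a = γ(|x_a − x0|), and μ the Lagrange
multiplier enforcing the unbiasedness constraint Σw = 1. The estimate is
Σ w_a z_a and the kriging variance is wᵀγ₀ + μ. With a zero nugget the
predictor interpolates the data exactly at station locations. Estimates
are invariant to rescaling the sill (only the variance scales), which is
why the sill's units never matter to the interpolated field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist

from .domain import StationSet
from .errors import InvalidLagError, SingularKrigingError

__all__ = ["VariogramModel", "spherical_semivariogram", "OrdinaryKriging",
           "KrigingResults", "ordinary_kriging", "fit_empirical_variogram"]


@dataclass(frozen=True)
class VariogramModel:
    """Spherical semivariogram parameters.

    range_a : distance at which the sill is reached, degrees (default 10).
    sill : partial sill (variance scale), default 1.
    nugget : discontinuity at the origin, default 0 (exact interpolation).
    """

    model: str = "spherical"
    range_a: float = 10.0
    sill: float = 1.0
    nugget: float = 0.0

    def __post_init__(self) -> None:
        if self.model != "spherical":
            raise ValueError("only the spherical model is supported")
        if self.range_a <= 0:
            raise ValueError(f"range_a must be > 0, got {self.range_a}")
        if self.sill <= 0:
            raise ValueError(f"sill must be > 0, got {self.sill}")
        if self.nugget < 0:
            raise ValueError(f"nugget must be >= 0, got {self.nugget}")


def spherical_semivariogram(h, model: VariogramModel | None = None):
    """γ(h) for the spherical model; γ(0) = 0 by convention.

    For 0 < h <= a: γ = nugget + sill·(1.5·h/a − 0.5·(h/a)³);
    for h > a: γ = nugget + sill.
    """
    model = model or VariogramModel()
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise InvalidLagError("lag distances must be >= 0")
    r = np.minimum(h / model.range_a, 1.0)
    g = model.nugget + model.sill * (1.5 * r - 0.5 * r ** 3)
    g = np.where(h == 0.0, 0.0, g)
    return g if g.ndim else float(g)


class OrdinaryKriging:
    """Global ordinary-kriging model over a station set."""

    def __init__(self, stations: StationSet, variogram: VariogramModel | None = None):
        if stations.n < 2:
            raise ValueError(f"kriging needs at least 2 stations, got {stations.n}")
        self.stations = stations
        self.variogram = variogram or VariogramModel()

    def fit(self) -> "KrigingResults":
        """Assemble and factorize the (N+1) x (N+1) kriging system.

        Raises
        ------
        SingularKrigingError
            If the system matrix is singular (duplicate station coordinates
            are rejected earlier, at StationSet construction).
        """
        st = self.stations
        n = st.n
        D = cdist(st.coords(), st.coords())
        A = np.empty((n + 1, n + 1))
        A[:n, :n] = spherical_semivariogram(D, self.variogram)
        A[:n, n] = 1.0
        A[n, :n] = 1.0
        A[n, n] = 0.0
        try:
            lu, piv = scipy.linalg.lu_factor(A)
        except (scipy.linalg.LinAlgError, ValueError) as exc:
            raise SingularKrigingError(f"singular kriging system: {exc}") from exc
        if not np.all(np.isfinite(lu)) or np.any(np.abs(np.diag(lu)) < 1e-300):
            raise SingularKrigingError("singular kriging system")
        return KrigingResults(self, lu, piv)


class KrigingResults:
    """Prediction interface for a factorized ordinary-kriging system."""

    def __init__(self, model: OrdinaryKriging, lu, piv):
        self.model = model
        self._lu = lu
        self._piv = piv

    def predict(self, lons, lats, return_variance: bool = False,
                return_weights: bool = False):
        """Kriged estimates at query points (optionally with variance).

        All right-hand sides are solved against the one factorization, so
        predicting on a full grid costs one triangular solve per point.
        """
        st = self.model.stations
        n = st.n
        lons = np.atleast_1d(np.asarray(lons, dtype=float))
        lats = np.atleast_1d(np.asarray(lats, dtype=float))
        pts = np.column_stack([lons, lats])
        g0 = spherical_semivariogram(cdist(st.coords(), pts),
                                     self.model.variogram)
        rhs = np.vstack([g0, np.ones((1, pts.shape[0]))])
        sol = scipy.linalg.lu_solve((self._lu, self._piv), rhs)
        w = sol[:n]
        mu = sol[n]
        est = w.T @ st.values
        out = [est]
        if return_variance:
            out.append(np.einsum("ij,ij->j", w, g0) + mu)
        if return_weights:
            out.append(w)
        return est if len(out) == 1 else tuple(out)


def ordinary_kriging(stations: StationSet, lons, lats,
                     variogram: VariogramModel | None = None,
                     return_variance: bool = False):
    """Functional wrapper: one-shot ordinary kriging at query points."""
    res = OrdinaryKriging(stations, variogram).fit()
    return res.predict(lons, lats, return_variance=return_variance)


def fit_empirical_variogram(stations: StationSet, n_bins: int = 15,
                            max_lag: float | None = None) -> VariogramModel:
    """Moment-estimator (Matheron) fit of a spherical variogram.

    Optional helper, never used by default — the default workflow keeps the
    fixed a-priori variogram. Bins squared half-differences by lag and fits
    (range, sill, nugget) by bounded least squares.
    """
    st = stations
    D = cdist(st.coords(), st.coords())
    iu = np.triu_indices(st.n, k=1)
    h = D[iu]
    sq = 0.5 * (st.values[:, None] - st.values[None, :])[iu] ** 2
    if max_lag is None:
        max_lag = float(h.max()) / 2.0
    edges = np.linspace(0.0, max_lag, n_bins + 1)
    centers, gammas = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (h > lo) & (h <= hi)
        if mask.sum() >= 5:
            centers.append(0.5 * (lo + hi))
            gammas.append(float(sq[mask].mean()))
    centers = np.asarray(centers)
    gammas = np.asarray(gammas)
    if len(centers) < 3:
        raise ValueError("too few populated lag bins to fit a variogram")

    def residual(p):
        a, sill, nug = p
        m = VariogramModel(range_a=a, sill=sill, nugget=nug)
        return spherical_semivariogram(np.maximum(centers, 1e-12), m) - gammas

    p0 = [max_lag / 2.0, float(gammas.max()), 0.0]
    fit = least_squares(residual, p0,
                        bounds=([1e-6, 1e-12, 0.0], [np.inf, np.inf, np.inf]))
    a, sill, nug = fit.x
    return VariogramModel(range_a=float(a), sill=float(sill), nugget=float(nug))
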