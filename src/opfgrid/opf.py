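"""Orthogonal polynomial fitting (OPF) of scattered pollutant observations.

The model is a tensor-product Chebyshev polynomial surface

    z(lon, lat) = Σ_{i=0}^{s} Σ_{j=0}^{k} a_ij · T_i(x') · T_j(y'),

where (x', y') are the station coordinates mapped affinely onto the
reference square [−1, 1]² over a rectangular domain, and T_m is the
Chebyshev polynomial of the first kind of order m. The coefficients a_ij
are the ordinary-least-squares minimiser of the squared residuals at the
stations, solved by SVD-based rank-revealing least squares.

Workflow mirrors the usual three steps: fit the coefficients from
monitoring data, choose the orders (see :mod:`opfgrid.evaluation` for the
cross-validated order search), then evaluate the surface on a target grid.

Typical use::

    model = ChebyshevOPF(stations, s=5, k=5)
    res = model.fit()
    field = res.predict_grid(grid)
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from numpy.polynomial import chebyshev as ncheb

from .chebyshev import build_design_matrix, map_to_reference
from .domain import DomainBox, GridSpec, StationSet
from .errors import UnderdeterminedFitError

__all__ = ["ChebyshevSurface", "ChebyshevOPF", "OPFResults",
           "fit_surface", "evaluate_surface"]

logger = logging.getLogger(__name__)

#: Relative singular-value cutoff for the rank-revealing least squares.
SVD_RCOND = 1e-10

#: Default policy cap on polynomial orders. Overridable per call; beyond
#: about 10 the amount of data behind ~200-station networks cannot support
#: the coefficient count and fits degrade sharply.
DEFAULT_MAX_ORDER = 10


@dataclass
class ChebyshevSurface:
    """A fitted tensor-Chebyshev surface: orders, reference box, coefficients.

    ``coeffs[i, j]`` multiplies T_i(x')·T_j(y') with i the longitude order
    and j the latitude order; shape is exactly (s+1, k+1), row-major.
    """

    s: int
    k: int
    domain: DomainBox
    coeffs: np.ndarray

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.shape != (self.s + 1, self.k + 1):
            raise ValueError(
                f"coeffs shape {self.coeffs.shape} does not match orders "
                f"(s={self.s}, k={self.k})"
            )
        if not np.all(np.isfinite(self.coeffs)):
            raise ValueError("non-finite surface coefficients")

    def evaluate(self, lons, lats, clip_negative: bool = False) -> np.ndarray:
        """Evaluate the surface at points; vectorized.

        ``clip_negative`` floors the output at 0 for presentation only —
        error metrics are always computed on raw values.
        """
        lons = np.asarray(lons, dtype=float)
        lats = np.asarray(lats, dtype=float)
        if lons.shape != lats.shape:
            raise ValueError("lons and lats must have the same shape")
        x = map_to_reference(lons, self.domain.lon_min, self.domain.lon_max)
        y = map_to_reference(lats, self.domain.lat_min, self.domain.lat_max)
        z = ncheb.chebval2d(x, y, self.coeffs)
        if clip_negative:
            z = np.maximum(z, 0.0)
        return z

    def evaluate_grid(self, grid: GridSpec, clip_negative: bool = False) -> np.ndarray:
        glon, glat = grid.points()
        return self.evaluate(glon, glat, clip_negative=clip_negative)

    # -- serialization: plain JSON document, lossless round trip ------------

    def to_dict(self) -> dict:
        return {"s": self.s, "k": self.k, "domain": self.domain.to_dict(),
                "coeffs": self.coeffs.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "ChebyshevSurface":
        return cls(s=int(d["s"]), k=int(d["k"]),
                   domain=DomainBox.from_dict(d["domain"]),
                   coeffs=np.asarray(d["coeffs"], dtype=float))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, text: str) -> "ChebyshevSurface":
        return cls.from_dict(json.loads(text))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "ChebyshevSurface":
        with open(path) as fh:
            return cls.from_json(fh.read())


class ChebyshevOPF:
    """Least-squares Chebyshev surface model for a scattered station set.

    Parameters
    ----------
    stations : StationSet
        Observations to fit.
    s, k : int
        Polynomial orders in the longitude and latitude directions.
    domain : DomainBox, optional
        Reference rectangle mapped onto [−1, 1]². Defaults to the bounding
        box of the stations, padded by ``pad_fraction``.
    pad_fraction : float
        Fractional padding applied when the domain is derived from the
        stations. Ignored when ``domain`` is given.

    The fit requires ``stations.n >= (s+1)·(k+1)``: with fewer observations
    than coefficients the system is underdetermined and the model refuses to
    fit rather than return one of infinitely many surfaces.
    """

    def __init__(self, stations: StationSet, s: int, k: int,
                 domain: DomainBox | None = None, pad_fraction: float = 0.0):
        if s < 0 or k < 0:
            raise ValueError(f"orders must be >= 0, got s={s}, k={k}")
        self.stations = stations
        self.s = int(s)
        self.k = int(k)
        self.domain = domain if domain is not None else stations.bounding_box(pad_fraction)

    @classmethod
    def from_dataframe(cls, df, s: int, k: int, **kwargs) -> "ChebyshevOPF":
        """Build the model from a DataFrame with id/lon/lat/value columns."""
        return cls(StationSet.from_dataframe(df), s, k, **kwargs)

    @property
    def n_coeffs(self) -> int:
        return (self.s + 1) * (self.k + 1)

    def fit(self) -> "OPFResults":
        """Solve the least-squares system and return the fitted results.

        Raises
        ------
        UnderdeterminedFitError
            If ``stations.n < (s+1)(k+1)``.

        A design that is rank deficient beyond the 1e−10 relative
        singular-value cutoff triggers a warning and returns the
        minimum-norm solution.
        """
        n = self.stations.n
        if n < self.n_coeffs:
            raise UnderdeterminedFitError(
                f"fitting orders (s={self.s}, k={self.k}) needs at least "
                f"{self.n_coeffs} stations, got {n}"
            )
        A = build_design_matrix(self.stations, self.s, self.k, self.domain)
        z = self.stations.values
        coef, _, rank, sv = scipy.linalg.lstsq(A, z, cond=SVD_RCOND,
                                               lapack_driver="gelsd")
        if rank < self.n_coeffs:
            warnings.warn(
                f"rank-deficient OPF design (rank {rank} < {self.n_coeffs}); "
                "returning the minimum-norm least-squares solution",
                stacklevel=2,
            )
            logger.warning("rank-deficient fit: rank=%d p=%d", rank, self.n_coeffs)
        surface = ChebyshevSurface(
            s=self.s, k=self.k, domain=self.domain,
            coeffs=coef.reshape(self.s + 1, self.k + 1),
        )
        fitted = A @ coef
        cond = float(sv[0] / sv[-1]) if sv is not None and sv[-1] > 0 else np.inf
        logger.debug("OPF fit: n=%d p=%d rank=%d cond=%.3g", n, self.n_coeffs,
                     rank, cond)
        return OPFResults(self, surface, fitted, z - fitted, rank, sv, cond)


class OPFResults:
    """Results of a Chebyshev OPF fit.

    Attributes
    ----------
    surface : ChebyshevSurface
        The fitted surface (orders, domain, coefficient matrix).
    fittedvalues : ndarray
        Surface evaluations at the fitting stations.
    resid : ndarray
        Observed minus fitted, μg·m⁻³.
    rank : int
        Numerical rank of the design at the 1e−10 cutoff.
    singular_values : ndarray
        Singular values of the design matrix.
    condition_number : float
        Ratio of extreme singular values — a conditioning diagnostic.
    """

    def __init__(self, model, surface, fittedvalues, resid, rank,
                 singular_values, condition_number):
        self.model = model
        self.surface = surface
        self.fittedvalues = np.asarray(fittedvalues)
        self.resid = np.asarray(resid)
        self.rank = int(rank)
        self.singular_values = singular_values
        self.condition_number = condition_number

    @property
    def params(self) -> np.ndarray:
        """Coefficient matrix a_ij, shape (s+1, k+1)."""
        return self.surface.coeffs

    @property
    def nobs(self) -> int:
        return self.model.stations.n

    @property
    def df_resid(self) -> int:
        return self.nobs - self.rank

    def predict(self, lons, lats, clip_negative: bool = False) -> np.ndarray:
        return self.surface.evaluate(lons, lats, clip_negative=clip_negative)

    def predict_grid(self, grid: GridSpec, clip_negative: bool = False) -> np.ndarray:
        return self.surface.evaluate_grid(grid, clip_negative=clip_negative)

    def resid_mae(self) -> float:
        return float(np.mean(np.abs(self.resid)))

    def resid_rmse(self) -> float:
        return float(np.sqrt(np.mean(self.resid ** 2)))

    def summary(self) -> str:
        """Plain-text summary of the fit."""
        m = self.model
        d = self.surface.domain
        lines = [
            "Chebyshev orthogonal polynomial surface fit",
            "=" * 47,
            f"Stations:            {self.nobs}",
            f"Orders (s, k):       ({m.s}, {m.k})",
            f"Coefficients:        {m.n_coeffs}",
            f"Design rank:         {self.rank}",
            f"Condition number:    {self.condition_number:.3g}",
            f"Domain lon:          [{d.lon_min:.3f}, {d.lon_max:.3f}] deg E",
            f"Domain lat:          [{d.lat_min:.3f}, {d.lat_max:.3f}] deg N",
            f"Residual MAE:        {self.resid_mae():.4f} ug/m3",
            f"Residual RMSE:       {self.resid_rmse():.4f} ug/m3",
        ]
        return "\n".join(lines)

    def plot_surface(self, grid: GridSpec, ax=None, **imshow_kwargs):
        """Quick-look image of the fitted field (requires matplotlib)."""
        import matplotlib.pyplot as plt  # deferred: plotting is optional

        z = self.predict_grid(grid).reshape(grid.n_lat, grid.n_lon)
        if ax is None:
            _, ax = plt.subplots()
        d = grid.domain
        im = ax.imshow(z, origin="lower", aspect="auto",
                       extent=(d.lon_min, d.lon_max, d.lat_min, d.lat_max),
                       **imshow_kwargs)
        ax.set_xlabel("longitude (deg E)")
        ax.set_ylabel("latitude (deg N)")
        ax.figure.colorbar(im, ax=ax, label="concentration (ug/m3)")
        return ax


def fit_surface(stations: StationSet, s: int, k: int,
                domain: DomainBox | None = None) -> ChebyshevSurface:
    """Functional wrapper: fit and return just the surface."""
    return ChebyshevOPF(stations, s, k, domain=domain).fit().surface


def evaluate_surface(surface: ChebyshevSurface, lons, lats,
                     clip_negative: bool = False) -> np.ndarray:
    """Functional wrapper around :meth:`ChebyshevSurface.evaluate`."""
    return surface.evaluate(lons, lats, clip_negative=clip_negative)
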