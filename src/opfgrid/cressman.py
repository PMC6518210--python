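"""Cressman objective analysis with an adaptive influence radius.

Each grid point is estimated as a distance-weighted mean of the stations
inside an influence radius R, using the classical Cressman kernel

    w(d) = (R² − d²) / (R² + d²)   for d < R,   w = 0 otherwise.

The radius is adaptive: it starts at ``r0`` (default 4°) and grows in
``r_step`` increments (default 0.1°) until at least ``min_neighbors``
stations (default 5) lie strictly inside it. This is a single weighted pass
— no successive-correction iterations. Distances are planar degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .domain import StationSet
from .errors import InvalidRadiusError, NoNeighborsError

__all__ = ["CressmanParams", "cressman_weight", "euclidean_degree_distance",
           "Cressman", "CressmanResults", "cressman_interpolate"]


@dataclass(frozen=True)
class CressmanParams:
    """Adaptive-radius parameters.

    r0 : initial influence radius, degrees (default 4).
    r_step : radius increment when too few neighbours, degrees (default 0.1).
    min_neighbors : minimum station count inside the radius (default 5).
    r_max : hard cap on radius growth; ``None`` means the diagonal of the
        station bounding box, which guarantees termination on any input
        where enough stations exist at all.
    """

    r0: float = 4.0
    r_step: float = 0.1
    min_neighbors: int = 5
    r_max: float | None = None

    def __post_init__(self) -> None:
        if self.r0 <= 0:
            raise InvalidRadiusError(f"r0 must be > 0, got {self.r0}")
        if self.r_step <= 0:
            raise ValueError(f"r_step must be > 0, got {self.r_step}")
        if self.min_neighbors < 1:
            raise ValueError("min_neighbors must be >= 1")
        if self.r_max is not None and self.r_max < self.r0:
            raise ValueError("r_max must be >= r0")


def euclidean_degree_distance(p1, p2) -> float:
    """Planar distance in degrees between two (lon, lat) points."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    return float(np.hypot(p1[0] - p2[0], p1[1] - p2[1]))


def cressman_weight(d, R: float):
    """Cressman kernel (R² − d²)/(R² + d²), zero at and beyond the radius."""
    if R <= 0:
        raise InvalidRadiusError(f"influence radius must be > 0, got {R}")
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be >= 0")
    w = np.where(d < R, (R * R - d * d) / (R * R + d * d), 0.0)
    return w if w.ndim else float(w)


class Cressman:
    """Cressman analysis model over a station set."""

    def __init__(self, stations: StationSet, params: CressmanParams | None = None):
        self.stations = stations
        self.params = params or CressmanParams()
        if stations.n < self.params.min_neighbors:
            raise ValueError(
                f"need at least min_neighbors={self.params.min_neighbors} "
                f"stations, got {stations.n}"
            )

    def fit(self) -> "CressmanResults":
        """Precompute station arrays; Cressman has no free parameters."""
        r_max = self.params.r_max
        if r_max is None:
            r_max = self.stations.bounding_box().diagonal
            r_max = max(r_max, self.params.r0)
        return CressmanResults(self, r_max)


class CressmanResults:
    """Prediction interface for a Cressman analysis."""

    def __init__(self, model: Cressman, r_max: float):
        self.model = model
        self.r_max = r_max

    def predict(self, lons, lats, return_radius: bool = False):
        """Estimate values at query points.

        Returns the estimates, and with ``return_radius=True`` also the
        final influence radius used at each point.

        Raises
        ------
        NoNeighborsError
            If for some point the radius would have to exceed ``r_max`` to
            admit ``min_neighbors`` stations; the offending point is named.
        """
        p = self.model.params
        st = self.model.stations
        lons = np.atleast_1d(np.asarray(lons, dtype=float))
        lats = np.atleast_1d(np.asarray(lats, dtype=float))
        pts = np.column_stack([lons, lats])
        d = cdist(pts, st.coords())

        # Smallest admissible radius per point: the least R in the ladder
        # {r0 + m*r_step} with strictly more than min_neighbors-1 stations
        # at d < R, i.e. R strictly above the min_neighbors-th distance.
        kth = np.partition(d, p.min_neighbors - 1, axis=1)[:, p.min_neighbors - 1]
        m = np.maximum(np.ceil((kth - p.r0) / p.r_step), 0.0)
        R = p.r0 + m * p.r_step
        bump = R <= kth
        R[bump] += p.r_step
        over = R > self.r_max + 1e-12
        if np.any(over):
            i = int(np.flatnonzero(over)[0])
            raise NoNeighborsError(
                f"point (lon={lons[i]}, lat={lats[i]}): influence radius "
                f"would exceed cap {self.r_max} deg before admitting "
                f"{p.min_neighbors} stations"
            )

        Rc = R[:, None]
        w = np.where(d < Rc, (Rc ** 2 - d ** 2) / (Rc ** 2 + d ** 2), 0.0)
        est = (w @ st.values) / w.sum(axis=1)
        if return_radius:
            return est, R
        return est


def cressman_interpolate(stations: StationSet, lons, lats,
                         params: CressmanParams | None = None
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Functional wrapper: returns (estimates, per-point final radius)."""
    return Cressman(stations, params).fit().predict(lons, lats,
                                                    return_radius=True)
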