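"""Spatial containers: scattered station sets, domain boxes and regular grids.

Coordinates are planar longitude/latitude degrees throughout (plate carrée):
the interpolation parameters this package implements — influence radii,
variogram ranges — are specified in degrees, so no great-circle metric is
used anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DuplicateStationError, InvalidDomainError

__all__ = ["DomainBox", "StationSet", "GridSpec"]


@dataclass(frozen=True)
class DomainBox:
    """Axis-aligned lon/lat rectangle, the reference frame for fitting.

    Parameters
    ----------
    lon_min, lon_max : float
        Western and eastern bounds, degrees east. ``lon_min < lon_max``.
    lat_min, lat_max : float
        Southern and northern bounds, degrees north. ``lat_min < lat_max``.
    """

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float

    def __post_init__(self) -> None:
        if not (self.lon_min < self.lon_max):
            raise InvalidDomainError(
                f"lon_min ({self.lon_min}) must be < lon_max ({self.lon_max})"
            )
        if not (self.lat_min < self.lat_max):
            raise InvalidDomainError(
                f"lat_min ({self.lat_min}) must be < lat_max ({self.lat_max})"
            )

    @property
    def width(self) -> float:
        return self.lon_max - self.lon_min

    @property
    def height(self) -> float:
        return self.lat_max - self.lat_min

    @property
    def diagonal(self) -> float:
        """Planar-degree length of the box diagonal."""
        return float(np.hypot(self.width, self.height))

    def padded(self, fraction: float) -> "DomainBox":
        """Return a box expanded by ``fraction`` of each side length."""
        dx = fraction * self.width
        dy = fraction * self.height
        return DomainBox(
            self.lon_min - dx, self.lon_max + dx, self.lat_min - dy, self.lat_max + dy
        )

    def contains(self, lons, lats) -> np.ndarray:
        lons = np.asarray(lons, dtype=float)
        lats = np.asarray(lats, dtype=float)
        return (
            (lons >= self.lon_min)
            & (lons <= self.lon_max)
            & (lats >= self.lat_min)
            & (lats <= self.lat_max)
        )

    def to_dict(self) -> dict:
        return {
            "lon_min": self.lon_min,
            "lon_max": self.lon_max,
            "lat_min": self.lat_min,
            "lat_max": self.lat_max,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DomainBox":
        return cls(
            float(d["lon_min"]), float(d["lon_max"]),
            float(d["lat_min"]), float(d["lat_max"]),
        )


@dataclass
class StationSet:
    """Scattered observations: one pollutant value per station/city.

    Parameters
    ----------
    ids : sequence of str
        Opaque station/city labels.
    lons, lats : array-like of float
        Coordinates in degrees east / degrees north.
    values : array-like of float
        Observed concentrations, μg·m⁻³.

    Invariants enforced at construction: all four sequences share length
    ``n >= 1``, coordinates and values are finite, and no two stations share
    the exact same (lon, lat) pair — duplicates are an input error, not a
    condition silently tolerated downstream.
    """

    ids: list = field(default_factory=list)
    lons: np.ndarray = field(default_factory=lambda: np.empty(0))
    lats: np.ndarray = field(default_factory=lambda: np.empty(0))
    values: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.lons = np.asarray(self.lons, dtype=float)
        self.lats = np.asarray(self.lats, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if n < 1:
            raise ValueError("a StationSet needs at least one station")
        if not (self.lons.shape == self.lats.shape == self.values.shape == (n,)):
            raise ValueError(
                "ids, lons, lats and values must all have the same length"
            )
        for name, arr in (("lons", self.lons), ("lats", self.lats),
                          ("values", self.values)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite entries in {name}")
        coords = set(zip(self.lons.tolist(), self.lats.tolist()))
        if len(coords) != n:
            raise DuplicateStationError(
                "duplicate (lon, lat) coordinates among stations"
            )

    @property
    def n(self) -> int:
        return len(self.ids)

    def coords(self) -> np.ndarray:
        """(n, 2) array of [lon, lat] rows."""
        return np.column_stack([self.lons, self.lats])

    def bounding_box(self, pad_fraction: float = 0.0) -> DomainBox:
        """Bounding box of the stations, optionally padded.

        Degenerate (collinear along an axis) sets get a tiny symmetric pad so
        the box is always a valid rectangle.
        """
        lon_lo, lon_hi = float(self.lons.min()), float(self.lons.max())
        lat_lo, lat_hi = float(self.lats.min()), float(self.lats.max())
        if lon_hi - lon_lo <= 0:
            lon_lo, lon_hi = lon_lo - 0.5, lon_hi + 0.5
        if lat_hi - lat_lo <= 0:
            lat_lo, lat_hi = lat_lo - 0.5, lat_hi + 0.5
        box = DomainBox(lon_lo, lon_hi, lat_lo, lat_hi)
        return box.padded(pad_fraction) if pad_fraction else box

    def subset(self, indices) -> "StationSet":
        idx = np.asarray(indices, dtype=int)
        return StationSet(
            ids=[self.ids[i] for i in idx],
            lons=self.lons[idx],
            lats=self.lats[idx],
            values=self.values[idx],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": self.ids, "lon": self.lons, "lat": self.lats,
             "value": self.values}
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "StationSet":
        return cls(
            ids=list(df["id"]),
            lons=df["lon"].to_numpy(dtype=float),
            lats=df["lat"].to_numpy(dtype=float),
            values=df["value"].to_numpy(dtype=float),
        )


@dataclass(frozen=True)
class GridSpec:
    """Regular lon/lat grid: a domain box plus per-axis node spacing."""

    domain: DomainBox
    d_lon: float = 0.25
    d_lat: float = 0.25

    def __post_init__(self) -> None:
        if self.d_lon <= 0 or self.d_lat <= 0:
            raise InvalidDomainError("grid spacings must be positive")
        if self.n_lon < 2 or self.n_lat < 2:
            raise InvalidDomainError(
                "grid must have at least 2 nodes per axis; "
                f"got {self.n_lon} x {self.n_lat}"
            )

    @property
    def n_lon(self) -> int:
        return int(np.floor(self.domain.width / self.d_lon + 1e-9)) + 1

    @property
    def n_lat(self) -> int:
        return int(np.floor(self.domain.height / self.d_lat + 1e-9)) + 1

    @property
    def n_nodes(self) -> int:
        return self.n_lon * self.n_lat

    def lon_nodes(self) -> np.ndarray:
        return self.domain.lon_min + self.d_lon * np.arange(self.n_lon)

    def lat_nodes(self) -> np.ndarray:
        return self.domain.lat_min + self.d_lat * np.arange(self.n_lat)

    def points(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened node coordinates with longitude varying fastest."""
        lat2d, lon2d = np.meshgrid(self.lat_nodes(), self.lon_nodes(),
                                   indexing="ij")
        return lon2d.ravel(), lat2d.ravel()
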