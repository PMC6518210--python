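"""Synthetic twin-experiment fields and station networks.

A twin experiment prescribes a known truth field, samples it at a station
network (optionally with observation noise), reconstructs the field from
the samples, and scores the reconstruction against the truth. The truth
fields here are smooth Gaussian-blob surfaces over a lon/lat box with a
background level and a small number of contamination centres:

    z(p) = background + Σ_c amplitude_c · exp(−d(p, c)² / (2·width_c²)),

with d the planar-degree distance. Two presets mimic the two canonical
pollution geometries used in regional PM2.5 twin experiments over central
and southern China:

* ``ie1_preset`` — a heavy-contamination centre in the northwest quadrant
  and a slight-contamination (clean) centre in the southeast, the most
  common wintertime pattern;
* ``ie2_preset`` — heavy centre in the southeast, clean centre in the
  southwest, typical of spring/autumn.

Default magnitudes make the fields span roughly 10–130 μg·m⁻³, the range
of typical daily PM2.5 maps; they are surrogates with the right geometry,
not reproductions of any particular observed day.

Station networks are placed by seeded jittered-grid sampling: the domain
is divided into roughly-square cells, a subset of cells is drawn, and one
station is placed uniformly at random inside each chosen cell. This gives
the irregular-but-space-filling coverage of a national city network while
guaranteeing no duplicate coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .domain import DomainBox, GridSpec, StationSet

__all__ = ["BlobField", "ie1_preset", "ie2_preset", "sample_stations",
           "DEFAULT_DOMAIN", "truth_on_grid"]

#: Study-zone box approximating central/southern China; gives the
#: degree-scaled method parameters (4 deg radius, 10 deg range) sensible reach.
DEFAULT_DOMAIN = DomainBox(97.0, 123.0, 18.0, 38.0)


@dataclass
class BlobField:
    """Smooth truth field: background plus Gaussian contamination centres.

    ``centers`` is a list of (lon, lat, amplitude, width) tuples; amplitude
    is in μg·m⁻³ and may be negative (a clean region), width is the Gaussian
    standard deviation in degrees.
    """

    background: float
    centers: list = field(default_factory=list)
    domain: DomainBox = DEFAULT_DOMAIN

    def __post_init__(self) -> None:
        for c in self.centers:
            if len(c) != 4:
                raise ValueError("each center is (lon, lat, amplitude, width)")
            if c[3] <= 0:
                raise ValueError(f"center width must be > 0, got {c[3]}")

    def evaluate(self, lons, lats) -> np.ndarray:
        lons = np.asarray(lons, dtype=float)
        lats = np.asarray(lats, dtype=float)
        z = np.full(np.broadcast(lons, lats).shape, float(self.background))
        for clon, clat, amp, width in self.centers:
            d2 = (lons - clon) ** 2 + (lats - clat) ** 2
            z = z + amp * np.exp(-d2 / (2.0 * width * width))
        return z


def evaluate_field(field_: BlobField, lons, lats) -> np.ndarray:
    """Functional alias for :meth:`BlobField.evaluate`."""
    return field_.evaluate(lons, lats)


def _quadrant_points(domain: DomainBox):
    """Midpoints of the four quadrants of a domain box."""
    lon_q1 = domain.lon_min + 0.25 * domain.width
    lon_q3 = domain.lon_min + 0.75 * domain.width
    lat_q1 = domain.lat_min + 0.25 * domain.height
    lat_q3 = domain.lat_min + 0.75 * domain.height
    return {"nw": (lon_q1, lat_q3), "ne": (lon_q3, lat_q3),
            "sw": (lon_q1, lat_q1), "se": (lon_q3, lat_q1)}


def ie1_preset(domain: DomainBox = DEFAULT_DOMAIN, background: float = 70.0,
               heavy_amplitude: float = 60.0, slight_amplitude: float = -55.0,
               width: float = 5.0) -> BlobField:
    """First twin-experiment geometry: heavy NW centre, clean SE centre."""
    q = _quadrant_points(domain)
    return BlobField(
        background=background,
        centers=[(*q["nw"], heavy_amplitude, width),
                 (*q["se"], slight_amplitude, width)],
        domain=domain,
    )


def ie2_preset(domain: DomainBox = DEFAULT_DOMAIN, background: float = 70.0,
               heavy_amplitude: float = 60.0, slight_amplitude: float = -50.0,
               width: float = 5.0) -> BlobField:
    """Second twin-experiment geometry: heavy SE centre, clean SW centre."""
    q = _quadrant_points(domain)
    return BlobField(
        background=background,
        centers=[(*q["se"], heavy_amplitude, width),
                 (*q["sw"], slight_amplitude, width)],
        domain=domain,
    )


def sample_stations(field_: BlobField, n: int = 225, seed: int = 0,
                    noise_sd: float = 0.0) -> StationSet:
    """Sample a synthetic station network from a truth field.

    Jittered-grid placement: the domain is split into cells whose count and
    aspect roughly match the domain, ``n`` distinct cells are drawn, and one
    station lands uniformly inside each — deterministic given ``seed``.
    Values are the field evaluated at the stations plus i.i.d. Gaussian
    noise of standard deviation ``noise_sd`` (default 0: perfect twins).
    """
    if n < 1:
        raise ValueError("need n >= 1 stations")
    rng = np.random.default_rng(seed)
    dom = field_.domain
    nx = max(1, math.ceil(math.sqrt(n * dom.width / dom.height)))
    ny = max(1, math.ceil(n / nx))
    cells = rng.choice(nx * ny, size=n, replace=False)
    ix = cells % nx
    iy = cells // nx
    # jitter kept off cell edges so distinct cells can never collide
    u = rng.uniform(0.05, 0.95, size=n)
    v = rng.uniform(0.05, 0.95, size=n)
    lons = dom.lon_min + (ix + u) * dom.width / nx
    lats = dom.lat_min + (iy + v) * dom.height / ny
    values = field_.evaluate(lons, lats)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=n)
    ids = [f"S{i + 1:03d}" for i in range(n)]
    return StationSet(ids=ids, lons=lons, lats=lats, values=values)


def truth_on_grid(field_: BlobField, grid: GridSpec) -> np.ndarray:
    """Evaluate the truth field at all grid nodes (lon fastest)."""
    glon, glat = grid.points()
    return field_.evaluate(glon, glat)
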