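"""CSV input/output for station sets and gridded fields.

Formats (documented column-exactly in the README):

* stations CSV — header with columns id, lon, lat, value (any order,
  case-insensitive); one row per station/city.
* grid CSV — long format lon, lat, value with longitude varying fastest;
  missing values are written as empty fields and read back as NaN.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .domain import GridSpec, StationSet
from .errors import EmptyInputError, SchemaError

__all__ = ["read_stations_csv", "write_stations_csv", "write_grid_csv",
           "read_grid_csv"]

logger = logging.getLogger(__name__)

_REQUIRED = ("id", "lon", "lat", "value")


def read_stations_csv(path) -> StationSet:
    """Parse a stations CSV into a StationSet.

    Rows whose value is missing or non-numeric are dropped and counted in
    the log. Missing required columns raise :class:`SchemaError`; duplicate
    coordinates raise at StationSet construction; zero usable rows raise
    :class:`EmptyInputError`.
    """
    df = pd.read_csv(path)
    rename = {c: c.strip().lower() for c in df.columns}
    df = df.rename(columns=rename)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    for col in ("lon", "lat", "value"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    usable = df[["lon", "lat", "value"]].notna().all(axis=1)
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.info("%s: dropped %d row(s) with missing/non-numeric fields",
                    path, n_dropped)
    df = df[usable]
    if df.empty:
        raise EmptyInputError(f"{path}: no usable station rows")
    return StationSet.from_dataframe(df)


def write_stations_csv(stations: StationSet, path) -> None:
    stations.to_dataframe().to_csv(path, index=False)


def write_grid_csv(grid: GridSpec, values, path) -> None:
    """Write gridded values as long-format lon,lat,value (lon fastest)."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size != grid.n_nodes:
        raise ValueError(
            f"values length {values.size} does not match grid "
            f"({grid.n_lat} x {grid.n_lon} = {grid.n_nodes} nodes)"
        )
    glon, glat = grid.points()
    pd.DataFrame({"lon": glon, "lat": glat, "value": values}).to_csv(
        path, index=False
    )


def read_grid_csv(path) -> pd.DataFrame:
    """Read a long-format grid CSV; empty value fields come back as NaN."""
    df = pd.read_csv(path)
    rename = {c: c.strip().lower() for c in df.columns}
    df = df.rename(columns=rename)
    missing = [c for c in ("lon", "lat", "value") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df[["lon", "lat", "value"]]
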