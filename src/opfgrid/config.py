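"""Run configuration: YAML files with dotted keys, validated on load.

Recognised keys (grouped by section)::

    opf.s, opf.k, opf.max_order
    cressman.r0, cressman.r_step, cressman.min_neighbors, cressman.r_max
    kriging.range, kriging.sill, kriging.nugget
    cv.n_folds, cv.holdout_size, cv.seed
    grid.d_lon, grid.d_lat
    domain.lon_min, domain.lon_max, domain.lat_min, domain.lat_max
    seed

Unknown keys are rejected with a message naming them — a silent typo in a
parameter name must never alter an analysis.
"""

from __future__ import annotations

import hashlib
import json

import yaml

from .errors import ConfigError

__all__ = ["KNOWN_KEYS", "load_config", "flatten", "config_hash"]

_INT_KEYS = {"opf.s", "opf.k", "opf.max_order", "cressman.min_neighbors",
             "cv.n_folds", "cv.holdout_size", "cv.seed", "seed"}
_FLOAT_KEYS = {"cressman.r0", "cressman.r_step", "cressman.r_max",
               "kriging.range", "kriging.sill", "kriging.nugget",
               "grid.d_lon", "grid.d_lat", "domain.lon_min",
               "domain.lon_max", "domain.lat_min", "domain.lat_max"}
KNOWN_KEYS = _INT_KEYS | _FLOAT_KEYS


def flatten(nested: dict, prefix: str = "") -> dict:
    """Flatten a nested mapping into dotted keys."""
    out = {}
    for key, val in nested.items():
        dotted = f"{prefix}{key}"
        if isinstance(val, dict):
            out.update(flatten(val, prefix=f"{dotted}."))
        else:
            out[dotted] = val
    return out


def load_config(path) -> dict:
    """Load and validate a YAML config; returns a flat dotted-key dict."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    flat = flatten(raw)
    unknown = sorted(set(flat) - KNOWN_KEYS)
    if unknown:
        raise ConfigError(f"{path}: unknown config key(s): {unknown}")
    out = {}
    for key, val in flat.items():
        try:
            out[key] = int(val) if key in _INT_KEYS else float(val)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"{path}: bad value for {key}: {val!r}") from exc
    return out


def config_hash(config: dict) -> str:
    """Short stable hash of a flat config dict, for provenance logging."""
    blob = json.dumps(config, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
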