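"""Tensor-product Chebyshev basis machinery.

Chebyshev polynomials of the first kind, T_m(t) = cos(m·arccos t) on
[−1, 1], are evaluated through :mod:`numpy.polynomial.chebyshev`, which uses
the stable three-term recurrence T_m = 2·t·T_{m−1} − T_{m−2}. Physical
longitude/latitude coordinates are mapped affinely onto the reference square
[−1, 1]² before any basis evaluation; points slightly outside the reference
interval are permitted (the recurrence extends T_m off [−1, 1]), which is
what allows evaluating a fitted surface at padded grid nodes.

Column convention for the tensor design matrix: the column for basis
function T_i(x')·T_j(y') (i = longitude order, j = latitude order) sits at
flat index ``i·(k+1) + j`` — longitude-order major, matching
:func:`numpy.polynomial.chebyshev.chebvander2d` and the row-major layout of
the (s+1)×(k+1) coefficient matrix ``a[i, j]``.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial import chebyshev as ncheb

from .domain import DomainBox
from .errors import InvalidDomainError, InvalidOrderError

__all__ = [
    "map_to_reference",
    "chebyshev_basis",
    "build_design_matrix",
    "design_matrix_from_points",
]


def map_to_reference(coord, lo: float, hi: float) -> np.ndarray:
    """Affine map of physical coordinates onto the reference interval [−1, 1].

    ``t = 2·(coord − lo)/(hi − lo) − 1``, so ``coord = lo → −1`` and
    ``coord = hi → +1``. Values outside [lo, hi] map outside [−1, 1]; that is
    intentional (evaluation at padded points).

    Raises
    ------
    InvalidDomainError
        If ``lo >= hi``.
    """
    if not lo < hi:
        raise InvalidDomainError(f"need lo < hi, got lo={lo}, hi={hi}")
    coord = np.asarray(coord, dtype=float)
    return 2.0 * (coord - lo) / (hi - lo) - 1.0


def chebyshev_basis(t, n_max: int) -> np.ndarray:
    """Evaluate [T_0(t), …, T_{n_max}(t)] for first-kind Chebyshev polynomials.

    Parameters
    ----------
    t : scalar or array of reference coordinates
        Values slightly outside [−1, 1] are allowed.
    n_max : int
        Highest order, ``>= 0``.

    Returns
    -------
    ndarray of shape ``t.shape + (n_max + 1,)``.
    """
    if n_max < 0:
        raise InvalidOrderError(f"n_max must be >= 0, got {n_max}")
    t = np.asarray(t, dtype=float)
    basis = ncheb.chebvander(t, n_max)
    return basis[0] if t.ndim == 0 else basis


def design_matrix_from_points(
    lons, lats, s: int, k: int, domain: DomainBox
) -> np.ndarray:
    """Tensor Chebyshev design matrix for arbitrary evaluation points.

    Row r holds T_i(x'_r)·T_j(y'_r) at flat column index ``i·(k+1) + j``
    (see module docstring); the first column is identically 1.
    """
    if s < 0 or k < 0:
        raise InvalidOrderError(f"orders must be >= 0, got s={s}, k={k}")
    x = map_to_reference(lons, domain.lon_min, domain.lon_max)
    y = map_to_reference(lats, domain.lat_min, domain.lat_max)
    return ncheb.chebvander2d(x, y, [s, k])


def build_design_matrix(stations, s: int, k: int, domain: DomainBox) -> np.ndarray:
    """Design matrix with one row per station (N × (s+1)(k+1))."""
    return design_matrix_from_points(stations.lons, stations.lats, s, k, domain)
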