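"""Natural cubic spline and Fourier basis construction.

Natural cubic splines are built from the truncated-power representation
(the same construction as R's ``ns``, up to a non-singular column
transform): with knots ``k_1 < ... < k_K`` (boundary knots included) the
basis spans all cubic splines that are linear beyond the boundary knots,
and has ``K - 1`` columns (intercept excluded).
"""

from __future__ import annotations

import numpy as np


def _pos_cube(u: np.ndarray) -> np.ndarray:
    return np.where(u > 0.0, u, 0.0) ** 3


def natural_cubic_basis(
    x: np.ndarray,
    interior_knots: np.ndarray,
    boundary_knots: tuple[float, float],
) -> np.ndarray:
    """Natural cubic spline basis, linear outside the boundary knots.

    Parameters
    ----------
    x : array of evaluation points.
    interior_knots : strictly inside ``boundary_knots`` (may be empty).
    boundary_knots : (lo, hi) with lo < hi.

    Returns
    -------
    (len(x), n_interior + 1) design matrix without an intercept column.
    """
    x = np.asarray(x, dtype=float)
    lo, hi = float(boundary_knots[0]), float(boundary_knots[1])
    if not lo < hi:
        raise ValueError("boundary knots must satisfy lo < hi")
    interior = np.sort(np.asarray(interior_knots, dtype=float))
    if interior.size and (interior[0] <= lo or interior[-1] >= hi):
        raise ValueError("interior knots must lie strictly inside the boundary knots")
    knots = np.concatenate([[lo], interior, [hi]])
    K = len(knots)

    def d(j: int) -> np.ndarray:
        return (_pos_cube(x - knots[j]) - _pos_cube(x - knots[K - 1])) / (
            knots[K - 1] - knots[j]
        )

    cols = [x]
    for j in range(K - 2):
        cols.append(d(j) - d(K - 2))
    return np.column_stack(cols)


def natural_spline_df(x: np.ndarray, df: int) -> tuple[np.ndarray, dict]:
    """Natural-spline basis with a given df over observed data.

    ``df`` columns: ``df - 1`` interior knots at equally spaced quantiles of
    ``x`` (median for df=2), boundary knots at the 1st/99th percentiles.
    Returns the basis and the knot placement so the basis can be
    re-evaluated on a prediction grid.
    """
    x = np.asarray(x, dtype=float)
    if df < 1:
        raise ValueError("df must be >= 1")
    lo, hi = np.percentile(x, [1.0, 99.0])
    if df == 1:
        interior = np.array([])
    else:
        probs = np.linspace(0, 100, df + 1)[1:-1]
        interior = np.percentile(x, probs)
        interior = interior[(interior > lo) & (interior < hi)]
    spec = {"interior_knots": interior, "boundary_knots": (lo, hi)}
    return natural_cubic_basis(x, interior, (lo, hi)), spec


def fourier_basis(t_days: np.ndarray, harmonics: int, period: float = 365.25) -> np.ndarray:
    """Sin/cos pairs of the yearly cycle: 2*harmonics columns."""
    t_days = np.asarray(t_days, dtype=float)
    cols = []
    for h in range(1, harmonics + 1):
        w = 2.0 * np.pi * h * t_days / period
        cols.append(np.sin(w))
        cols.append(np.cos(w))
    if not cols:
        return np.empty((len(t_days), 0))
    return np.column_stack(cols)
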