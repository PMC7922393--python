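"""Natural cubic regression spline basis with linear tails.

This is the classical restricted cubic spline construction used by R's
``splines::ns``: a cubic B-spline basis on the augmented knot sequence is
projected onto the subspace whose second derivative vanishes at the boundary
knots, leaving ``n_interior_knots + 1`` columns (no intercept).  Beyond the
boundary knots the basis continues linearly (first-order Taylor expansion at
the boundary, which is exact for a natural spline), so the fitted
exposure-response extrapolates linearly to exposures outside the calibration
range -- the relevant behavior for hotter future temperatures.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import BSpline


class NaturalSpline:
    """Natural cubic spline basis defined by interior and boundary knots.

    Parameters
    ----------
    knots : interior knots (may be empty for a single linear column).
    boundary_knots : pair (lo, hi) bracketing the interior knots.
    """

    def __init__(self, knots, boundary_knots):
        self.knots = np.sort(np.asarray(knots, dtype=float))
        lo, hi = map(float, boundary_knots)
        if hi <= lo:
            raise ValueError("boundary knots must satisfy lo < hi")
        if self.knots.size and (self.knots[0] <= lo or self.knots[-1] >= hi):
            raise ValueError("interior knots must lie strictly inside the boundary knots")
        self.boundary_knots = (lo, hi)
        self.t = np.concatenate([[lo] * 4, self.knots, [hi] * 4])
        self._ncoef = len(self.knots) + 4
        # natural constraint: second derivative zero at both boundaries
        const = self._raw(np.array(self.boundary_knots), deriv=2)[:, 1:]
        q, _ = np.linalg.qr(const.T, mode="complete")
        self._proj = q[:, 2:]

    @classmethod
    def from_data(cls, x, df: int) -> "NaturalSpline":
        """Knots at equally spaced quantiles of x (df-1 interior knots),
        boundary knots at the data range -- the standard df parametrization."""
        x = np.asarray(x, dtype=float)
        x = x[np.isfinite(x)]
        if df < 1:
            raise ValueError("df must be >= 1")
        n_interior = df - 1
        probs = np.linspace(0, 1, n_interior + 2)[1:-1]
        knots = np.quantile(x, probs) if n_interior else np.array([])
        return cls(knots, (x.min(), x.max()))

    @property
    def df(self) -> int:
        return self._ncoef - 3

    def _raw(self, x, deriv: int = 0) -> np.ndarray:
        b = BSpline(self.t, np.eye(self._ncoef), 3, extrapolate=True)
        if deriv:
            b = b.derivative(deriv)
        return np.atleast_2d(b(np.atleast_1d(np.asarray(x, dtype=float))))

    def basis(self, x) -> np.ndarray:
        """Design matrix, shape (len(x), df); linear beyond the boundary knots."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        lo, hi = self.boundary_knots
        h = self._raw(np.clip(x, lo, hi))
        below = x < lo
        above = x > hi
        if below.any():
            v = self._raw([lo])
            d = self._raw([lo], deriv=1)
            h[below] = v + (x[below] - lo)[:, None] * d
        if above.any():
            v = self._raw([hi])
            d = self._raw([hi], deriv=1)
            h[above] = v + (x[above] - hi)[:, None] * d
        return h[:, 1:] @ self._proj

    def __call__(self, x) -> np.ndarray:
        return self.basis(x)
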