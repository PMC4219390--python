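"""Restricted cubic splines with linear tails.

The basis underlies both the longitudinal trajectory (spline of measurement
time) and the flexible parametric survival model (spline of log time for the
log cumulative hazard). A restricted cubic spline with knots
``k_min < k_2 < ... < k_{K-1} < k_max`` spans ``df = K - 1`` columns: the
first column is ``x`` itself and, for each interior knot ``k_j``,

    v_j(x) = [ (x-k_j)_+^3 - lam_j (x-k_min)_+^3
               - (1-lam_j)(x-k_max)_+^3 ] / (k_max - k_min)^2

with ``lam_j = (k_max - k_j)/(k_max - k_min)``.  The combination of truncated
cubes cancels the quadratic and cubic growth beyond both boundary knots, so
any fitted function is exactly linear outside ``[k_min, k_max]``.  Division by
the squared boundary span keeps the columns on a scale comparable to ``x``;
no orthogonalisation is applied, so coefficients are interpretable directly
in this parameterisation (and are parameterisation-dependent).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["KnotSet", "KnotDegeneracyError", "place_knots", "rcs_basis", "rcs_derivative"]


class KnotDegeneracyError(ValueError):
    """Raised when requested degrees of freedom exceed what the data support."""


@dataclass(frozen=True)
class KnotSet:
    """Knot locations for a restricted cubic spline.

    Parameters
    ----------
    interior : tuple of float
        Interior knots, strictly increasing, strictly inside the boundary.
    boundary : (float, float)
        Boundary knots bracketing all interior knots; the fitted function is
        linear beyond them.

    The number of basis columns is ``df = len(interior) + 1`` (total knots
    minus one).  ``df = 1`` means no interior knots: a pure linear term.
    """

    interior: tuple[float, ...]
    boundary: tuple[float, float]

    def __post_init__(self) -> None:
        interior = tuple(float(k) for k in self.interior)
        boundary = (float(self.boundary[0]), float(self.boundary[1]))
        object.__setattr__(self, "interior", interior)
        object.__setattr__(self, "boundary", boundary)
        knots = self.all_knots
        if np.any(np.diff(knots) <= 0):
            raise KnotDegeneracyError(f"knots must be strictly increasing, got {knots}")

    @property
    def df(self) -> int:
        return len(self.interior) + 1

    @property
    def all_knots(self) -> np.ndarray:
        return np.array([self.boundary[0], *self.interior, self.boundary[1]])

    def to_dict(self) -> dict:
        return {"interior": list(self.interior), "boundary": list(self.boundary)}

    @classmethod
    def from_dict(cls, d: dict) -> "KnotSet":
        return cls(interior=tuple(d["interior"]), boundary=tuple(d["boundary"]))


def place_knots(values, df: int, scale: str = "identity") -> KnotSet:
    """Place boundary knots at the data extremes and interior knots at
    equally spaced centiles.

    Parameters
    ----------
    values : array-like
        Observed values on the original axis (e.g. measurement times, or
        event times when ``scale='log'``).
    df : int
        Number of basis columns; ``df - 1`` interior knots are placed at the
        ``i/df`` centiles (linear-interpolation quantiles), ``i = 1..df-1``.
    scale : {'identity', 'log'}
        Axis transformation applied before knot placement.

    Raises
    ------
    KnotDegeneracyError
        If the (transformed) values cannot support ``df + 1`` strictly
        increasing knots.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("values must be non-empty")
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    if scale == "log":
        if np.any(x <= 0):
            raise ValueError("log scale requires strictly positive values")
        x = np.log(x)
    elif scale != "identity":
        raise ValueError(f"unknown scale {scale!r}")

    distinct = np.unique(x)
    if distinct.size < df + 1:
        raise KnotDegeneracyError(
            f"df={df} needs at least {df + 1} distinct values, got {distinct.size}"
        )
    boundary = (float(x.min()), float(x.max()))
    if df == 1:
        return KnotSet(interior=(), boundary=boundary)
    probs = np.arange(1, df) / df
    interior = np.quantile(x, probs)  # linear-interpolation quantiles
    return KnotSet(interior=tuple(interior), boundary=boundary)


def _truncated_cube(u: np.ndarray) -> np.ndarray:
    return np.where(u > 0, u, 0.0) ** 3


def _truncated_square(u: np.ndarray) -> np.ndarray:
    return np.where(u > 0, u, 0.0) ** 2


def rcs_basis(x, knots: KnotSet) -> np.ndarray:
    """Evaluate the restricted cubic spline basis.

    Returns an ``(len(x), knots.df)`` matrix whose first column is ``x``;
    evaluation beyond the boundary knots is permitted and linear.
    """
    x = np.asarray(x, dtype=float).ravel()
    out = np.empty((x.size, knots.df))
    out[:, 0] = x
    kmin, kmax = knots.boundary
    span2 = (kmax - kmin) ** 2
    for j, kj in enumerate(knots.interior, start=1):
        lam = (kmax - kj) / (kmax - kmin)
        out[:, j] = (
            _truncated_cube(x - kj)
            - lam * _truncated_cube(x - kmin)
            - (1.0 - lam) * _truncated_cube(x - kmax)
        ) / span2
    return out


def rcs_derivative(x, knots: KnotSet) -> np.ndarray:
    """Element-wise derivative of :func:`rcs_basis` with respect to ``x``."""
    x = np.asarray(x, dtype=float).ravel()
    out = np.empty((x.size, knots.df))
    out[:, 0] = 1.0
    kmin, kmax = knots.boundary
    span2 = (kmax - kmin) ** 2
    for j, kj in enumerate(knots.interior, start=1):
        lam = (kmax - kj) / (kmax - kmin)
        out[:, j] = (
            3.0
            * (
                _truncated_square(x - kj)
                - lam * _truncated_square(x - kmin)
                - (1.0 - lam) * _truncated_square(x - kmax)
            )
            / span2
        )
    return out
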