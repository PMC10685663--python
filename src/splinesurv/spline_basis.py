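"""M-spline hazard basis construction and evaluation.

An M-spline basis of degree ``d`` on ``m`` internal knots consists of
``n = m + d + 1`` non-negative polynomial pieces that each integrate to one
over the boundary interval.  A convex combination of M-splines, multiplied by
a positive scale, is a valid hazard function; the integrated (I-spline) basis
gives the matching cumulative hazard.  The basis here is modified so the last
term is held constant beyond the upper boundary knot, which makes the implied
hazard flat (and the cumulative hazard linear) in the extrapolation region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "KnotSet",
    "BasisMatrix",
    "default_knots",
    "mspline_eval",
    "ispline_eval",
    "constant_hazard_coefs",
]


@dataclass(frozen=True)
class KnotSet:
    """Knot sequence and polynomial degree defining an M-spline basis.

    Parameters
    ----------
    internal_knots : tuple of float
        Ordered knots strictly inside ``(lower_boundary, upper_boundary)``.
    upper_boundary : float
        Right boundary knot; the basis is constant beyond it.
    lower_boundary : float, default 0
        Left boundary knot.
    degree : int, default 3
        Polynomial degree of each piece (3 = cubic).
    """

    internal_knots: tuple[float, ...]
    upper_boundary: float
    lower_boundary: float = 0.0
    degree: int = 3

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "internal_knots", tuple(float(k) for k in self.internal_knots)
        )
        ik = np.asarray(self.internal_knots, dtype=float)
        if self.degree < 0:
            raise ValueError("degree must be non-negative")
        if self.lower_boundary < 0:
            raise ValueError("all knots must be >= 0")
        if not self.lower_boundary < self.upper_boundary:
            raise ValueError("lower_boundary must be below upper_boundary")
        if ik.size:
            if np.any(np.diff(ik) < 0):
                raise ValueError("internal knots must be ordered")
            if ik[0] <= self.lower_boundary or ik[-1] >= self.upper_boundary:
                raise ValueError(
                    "internal knots must lie strictly between the boundaries"
                )

    @property
    def n_basis(self) -> int:
        """Number of basis functions, ``internal + degree + 1``."""
        return len(self.internal_knots) + self.degree + 1

    @property
    def order(self) -> int:
        return self.degree + 1

    @property
    def knot_vector(self) -> np.ndarray:
        """Full knot vector with boundary knots repeated to multiplicity order."""
        return np.concatenate(
            [
                np.repeat(self.lower_boundary, self.order),
                self.internal_knots,
                np.repeat(self.upper_boundary, self.order),
            ]
        )

    def to_dict(self) -> dict:
        return {
            "internal_knots": list(self.internal_knots),
            "lower_boundary": self.lower_boundary,
            "upper_boundary": self.upper_boundary,
            "degree": self.degree,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KnotSet":
        return cls(
            internal_knots=tuple(d["internal_knots"]),
            lower_boundary=float(d.get("lower_boundary", 0.0)),
            upper_boundary=float(d["upper_boundary"]),
            degree=int(d.get("degree", 3)),
        )


@dataclass(frozen=True)
class BasisMatrix:
    """Evaluated basis: ``values[i, j]`` is basis term j at ``times[i]``."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


def default_knots(
    uncensored_times: Sequence[float],
    n_basis: int = 10,
    upper_boundary: float | None = None,
    extra_knots: Sequence[float] = (),
    degree: int = 3,
) -> KnotSet:
    """Place knots at quantiles of the uncensored event times.

    ``n_basis - degree - 1`` internal knots are placed at equally-spaced
    quantiles (linear interpolation) of the event times.  The upper boundary
    defaults to the final event time; supplying ``upper_boundary`` or
    ``extra_knots`` (e.g. to span late external data) raises it to their
    maximum, with the remaining extra knots appended as internal knots.
    """
    times = np.asarray(uncensored_times, dtype=float)
    if times.size == 0:
        raise ValueError("no events: cannot place knots without uncensored times")
    if np.any(times < 0):
        raise ValueError("event times must be non-negative")
    n_internal = n_basis - degree - 1
    if n_internal < 1:
        raise ValueError("n_basis must be at least degree + 2")
    extra = np.asarray(sorted(extra_knots), dtype=float)
    tmax = times.max()
    if extra.size and extra.min() <= tmax:
        raise ValueError("extra_knots must all exceed the largest event time")
    upper = tmax
    if upper_boundary is not None:
        upper = max(upper, float(upper_boundary))
    if extra.size:
        upper = max(upper, extra.max())

    probs = np.arange(1, n_internal + 1) / (n_internal + 1)
    internal = np.quantile(times, probs)  # linear-interpolation quantiles
    internal = np.concatenate([internal, extra[extra < upper]])
    internal = internal[(internal > 0) & (internal < upper)]
    internal.sort()
    distinct = np.unique(internal)
    if distinct.size < internal.size:
        warnings.warn(
            "duplicate knots collapsed: requested %d internal knots, kept %d"
            % (internal.size, distinct.size),
            stacklevel=2,
        )
        internal = distinct
    return KnotSet(
        internal_knots=tuple(internal),
        lower_boundary=0.0,
        upper_boundary=float(upper),
        degree=degree,
    )


@lru_cache(maxsize=128)
def _basis_splines(knots: KnotSet) -> tuple:
    """Per-term BSpline objects, their antiderivatives, and M-spline scales."""
    tvec = knots.knot_vector
    k = knots.degree
    n = knots.n_basis
    spans = tvec[knots.order : knots.order + n] - tvec[:n]
    scale = knots.order / spans  # M_i = order * B_i / (t_{i+order} - t_i)
    bsplines = []
    antiderivs = []
    for i in range(n):
        c = np.zeros(n)
        c[i] = 1.0
        b = BSpline(tvec, c, k, extrapolate=False)
        bsplines.append(b)
        antiderivs.append(b.antiderivative())
    return tuple(bsplines), tuple(antiderivs), scale


def mspline_eval(knots: KnotSet, times: Sequence[float]) -> BasisMatrix:
    """Evaluate the M-spline basis ``b_i(t)`` at the given times.

    Entries are non-negative; at the left boundary only the first term is
    nonzero, and for ``t`` past the upper boundary every column is zero except
    the last, which keeps its boundary value (constant hazard extension).
    """
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    bsplines, _, scale = _basis_splines(knots)
    tc1 = np.atleast_1d(np.clip(t, knots.lower_boundary, knots.upper_boundary))
    vals = np.empty((tc1.size, knots.n_basis))
    for i, b in enumerate(bsplines):
        vals[:, i] = b(tc1)
    np.nan_to_num(vals, copy=False)
    vals *= scale
    # clipping t to the boundary already yields (0, ..., 0, b_n(upper)) there
    np.clip(vals, 0.0, None, out=vals)
    return BasisMatrix(times=np.atleast_1d(t), values=vals)


def ispline_eval(knots: KnotSet, times: Sequence[float]) -> BasisMatrix:
    """Evaluate the integrated basis ``I_i(t) = ∫₀ᵗ b_i(s) ds``.

    Columns are non-decreasing; past the upper boundary every column is at its
    full integral except the last, which grows linearly with slope equal to
    the last M-spline's boundary value.
    """
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    bsplines, antiderivs, scale = _basis_splines(knots)
    L, U = knots.lower_boundary, knots.upper_boundary
    tc1 = np.atleast_1d(np.clip(t, L, U))
    n = knots.n_basis
    vals = np.empty((tc1.size, n))
    for i, a in enumerate(antiderivs):
        vals[:, i] = a(tc1) - a(np.array([L]))
    np.nan_to_num(vals, copy=False)
    vals *= scale
    # linear continuation of the last (constant-tail) basis term
    over = np.atleast_1d(t) - U
    over = np.clip(over, 0.0, None)
    if np.any(over > 0):
        slope = float(bsplines[-1](np.array([U]))[0]) * scale[-1]
        vals[:, -1] += slope * over
    np.clip(vals, 0.0, None, out=vals)
    return BasisMatrix(times=np.atleast_1d(t), values=vals)


def constant_hazard_coefs(knots: KnotSet) -> tuple[np.ndarray, float]:
    """Coefficients making the spline hazard constant in time.

    Because the underlying B-splines sum to one everywhere inside the
    boundary, weighting each M-spline by its knot span gives a flat function.
    Returns ``(p, c)`` with ``p >= 0``, ``sum(p) = 1`` and
    ``sum_i p_i b_i(t) = c`` for all t in the boundary interval, so a hazard
    of level ``lam`` needs scale ``eta = lam / c``.
    """
    tvec = knots.knot_vector
    n = knots.n_basis
    spans = tvec[knots.order : knots.order + n] - tvec[:n]
    p = spans / spans.sum()
    c = knots.order / spans.sum()
    return p, float(c)
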