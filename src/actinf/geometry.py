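"""Information geometry of categorical beliefs.

A belief over ``n`` discrete states is a point on the (n-1)-simplex.  The
Fisher information metric makes the simplex a Riemannian manifold; under the
component-wise square-root embedding ``s -> sqrt(s)`` the simplex maps onto
the positive orthant of the unit sphere, isometrically up to a factor of two.
Geodesics are therefore great-circle arcs, and the geodesic (Fisher-Rao)
distance between beliefs ``a`` and ``b`` is ``2 * arccos(sqrt(a) . sqrt(b))``.

Two finite-separation distances are provided:

``chord``
    ``2 * ||sqrt(a) - sqrt(b)||_2`` -- the straight-line distance in the
    sphere embedding.  This is the default used for accumulating the
    information length of belief trajectories; it agrees with the metric
    (the Hessian of the KL divergence) to second order in ``b - a``.
``arc``
    ``2 * arccos(sqrt(a) . sqrt(b))`` -- the exact geodesic length.

The chord never exceeds the arc, and their ratio tends to one as the points
approach each other, so for the small per-iterate steps produced by
gradient-based belief updating the two accumulate nearly identical lengths.

Metric quantities diverge at the simplex boundary, so beliefs are floored at
``FLOOR`` and renormalised before geometric operations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "FLOOR",
    "BoundaryWarning",
    "InfoPath",
    "as_belief",
    "floor_beliefs",
    "softmax",
    "inverse_fisher_metric",
    "information_distance",
    "path_information_length",
    "geodesic_distance",
    "geodesic_path",
]

#: Probability floor applied before logarithms, square roots and divisions.
FLOOR = 1e-16


class BoundaryWarning(UserWarning):
    """A belief lies on the simplex boundary, where the Fisher metric degenerates."""


def as_belief(p: Sequence[float] | np.ndarray, *, atol: float = 1e-10) -> np.ndarray:
    """Validate and return ``p`` as a belief vector (1-D, >= 0, sums to one)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size < 2:
        raise ValueError(f"belief must be a 1-D vector with n >= 2, got shape {p.shape}")
    if not np.all(np.isfinite(p)):
        raise ValueError("belief contains non-finite components")
    if np.any(p < -atol):
        raise ValueError(f"belief has negative components (min {p.min():.3e})")
    total = float(p.sum())
    if abs(total - 1.0) > atol:
        raise ValueError(f"belief components sum to {total!r}, expected 1")
    return np.clip(p, 0.0, None)


def floor_beliefs(p: np.ndarray, floor: float = FLOOR) -> np.ndarray:
    """Clip components at ``floor`` and renormalise, returning an interior point."""
    q = np.clip(np.asarray(p, dtype=float), floor, None)
    return q / q.sum()


def softmax(v: Sequence[float] | np.ndarray) -> np.ndarray:
    """Shift-invariant softmax: ``exp(v) / sum(exp(v))``.

    The maximum is subtracted before exponentiation, so adding a constant to
    every component leaves the output unchanged and no overflow can occur.
    Raises ``ValueError`` on NaN/inf input.
    """
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("softmax requires finite input")
    z = np.exp(v - v.max())
    return z / z.sum()


def inverse_fisher_metric(s: np.ndarray) -> np.ndarray:
    """Inverse Fisher metric at ``s``: the diagonal matrix ``diag(s)``.

    Its action on a gradient is the elementwise product ``s * u``.  Warns at
    boundary points (zero components), where the metric itself is singular;
    floor beliefs first for a well-defined inverse.
    """
    s = as_belief(s)
    if np.any(s <= 0.0):
        warnings.warn(
            "belief has zero components; the Fisher metric is singular at the "
            "boundary -- floor beliefs before metric operations",
            BoundaryWarning,
            stacklevel=2,
        )
    return np.diag(s)


def information_distance(a: np.ndarray, b: np.ndarray, kind: str = "chord") -> float:
    """Fisher information distance between beliefs ``a`` and ``b``.

    Parameters
    ----------
    a, b
        Belief vectors of equal dimension.
    kind
        ``"chord"`` (default) for ``2 * ||sqrt(a) - sqrt(b)||``, or ``"arc"``
        for the geodesic length ``2 * arccos(sqrt(a) . sqrt(b))``.
    """
    a = as_belief(a)
    b = as_belief(b)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    ra, rb = np.sqrt(a), np.sqrt(b)
    if kind == "chord":
        return 2.0 * float(np.linalg.norm(ra - rb))
    if kind == "arc":
        return 2.0 * float(np.arccos(np.clip(np.dot(ra, rb), -1.0, 1.0)))
    raise ValueError(f"unknown distance kind {kind!r}")


def geodesic_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Exact Fisher-Rao geodesic distance, ``2 * arccos(sqrt(a) . sqrt(b))``."""
    return information_distance(a, b, kind="arc")


@dataclass(frozen=True)
class InfoPath:
    """A belief trajectory with its per-step and cumulative information lengths.

    ``total_length`` always equals ``step_distances.sum()``;
    ``len(step_distances) == len(points) - 1``.
    """

    points: tuple[np.ndarray, ...]
    step_distances: np.ndarray
    total_length: float

    def __post_init__(self) -> None:
        if len(self.step_distances) != len(self.points) - 1:
            raise ValueError("need one step distance per consecutive pair of points")
        if abs(float(self.step_distances.sum()) - self.total_length) > 1e-10:
            raise ValueError("total_length must equal the sum of step distances")

    @property
    def cumulative(self) -> np.ndarray:
        """Cumulative length after each point (starts at 0)."""
        return np.concatenate([[0.0], np.cumsum(self.step_distances)])


def path_information_length(
    points: Sequence[np.ndarray], kind: str = "chord"
) -> InfoPath:
    """Accumulate the information distance between consecutive beliefs.

    A single-point path has zero length.
    """
    pts = tuple(as_belief(p) for p in points)
    if len(pts) == 0:
        raise ValueError("path needs at least one point")
    steps = np.array(
        [information_distance(pts[i], pts[i + 1], kind=kind) for i in range(len(pts) - 1)]
    )
    return InfoPath(points=pts, step_distances=steps, total_length=float(steps.sum()))


def geodesic_path(a: np.ndarray, b: np.ndarray, k: int = 64) -> list[np.ndarray]:
    """Discretised Fisher-Rao geodesic from ``a`` to ``b`` in ``k`` steps.

    Maps both beliefs to the positive orthant of the unit sphere by
    component-wise square root, interpolates along the great circle through
    the images (``k + 1`` points including both endpoints, which are returned
    exactly), and squares back to the simplex.  Antipodal degeneracy cannot
    occur on the positive orthant.
    """
    a = floor_beliefs(as_belief(a))
    b = floor_beliefs(as_belief(b))
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    if k < 1:
        raise ValueError("k must be >= 1")
    x, y = np.sqrt(a), np.sqrt(b)
    omega = float(np.arccos(np.clip(np.dot(x, y), -1.0, 1.0)))
    ts = np.linspace(0.0, 1.0, k + 1)
    if omega < 1e-12:
        pts = [a.copy() for _ in ts]
    else:
        sin_om = np.sin(omega)
        pts = []
        for t in ts:
            u = (np.sin((1.0 - t) * omega) * x + np.sin(t * omega) * y) / sin_om
            u = u / np.linalg.norm(u)
            pts.append(u * u)
    pts[0] = a
    pts[-1] = b
    return pts
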