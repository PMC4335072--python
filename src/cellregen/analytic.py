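"""Closed-form results used as independent oracles.

Two pieces: restoring a single removed off-lattice cell from the remembered
distances to the remaining cells (circle intersection / multilateration
with exact distances), and the steady-state solution of the nonlinear
diffusion problem (a(u) u')' - b u = 0 with a(u) = u**-k, which yields the
power-law decay used by the polynomial signal kernel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InvalidArgumentError

__all__ = [
    "Point",
    "DiffusionSolution",
    "circle_intersection",
    "restore_single_cell",
    "diffusion_solution",
    "ode_residual",
]

Point = tuple[float, float]

_TOL = 1e-9  # relative tolerance for tangency / agreement classification


def circle_intersection(
    center_a: Point, r_a: float, center_b: Point, r_b: float, tol: float = _TOL
) -> list[Point]:
    """Intersection points of two circles (0, 1 or 2 points).

    Tangency is classified with a relative tolerance: if the configuration
    is within ``tol`` of tangent, the single touching point is returned.
    """
    if r_a <= 0 or r_b <= 0:
        raise InvalidArgumentError("circle radii must be positive")
    ax, ay = center_a
    bx, by = center_b
    d = math.hypot(bx - ax, by - ay)
    if d == 0:
        raise InvalidArgumentError("circle centers must be distinct")
    scale = max(d, r_a, r_b)
    # point on line AB closest to the intersection chord
    h = (d * d + r_a * r_a - r_b * r_b) / (2 * d)
    disc = r_a * r_a - h * h
    ux, uy = (bx - ax) / d, (by - ay) / d
    px, py = ax + h * ux, ay + h * uy
    thresh = tol * scale * scale
    if disc > thresh:
        s = math.sqrt(disc)
        return [(px - s * uy, py + s * ux), (px + s * uy, py - s * ux)]
    if disc >= -thresh:
        return [(px, py)]
    return []


def restore_single_cell(
    controls: Sequence[Point], old_distances: Sequence[float], tol: float = _TOL
) -> list[Point]:
    """Candidate positions of a removed cell from remembered distances.

    With two control cells the remembered distances define two circles,
    giving 0, 1 or 2 candidate positions.  With three or more controls the
    candidates of the first circle pair are filtered by agreement with the
    remaining distance constraints, which generically leaves the unique
    original position.  An empty list means the distances are inconsistent
    (no common intersection); it is a result, not an error.
    """
    if len(controls) < 2:
        raise InvalidArgumentError("at least two control cells are required")
    if len(controls) != len(old_distances):
        raise InvalidArgumentError("one distance per control cell is required")
    if any(d <= 0 for d in old_distances):
        raise InvalidArgumentError("remembered distances must be positive")
    if len(set(controls)) != len(controls):
        raise InvalidArgumentError("control cells must occupy distinct positions")

    candidates = circle_intersection(
        controls[0], old_distances[0], controls[1], old_distances[1], tol
    )
    if len(controls) == 2:
        return candidates
    result = []
    for px, py in candidates:
        scale = max(max(old_distances), 1.0)
        if all(
            abs(math.hypot(px - cx, py - cy) - d) <= tol * scale
            for (cx, cy), d in zip(controls[2:], old_distances[2:])
        ):
            result.append((px, py))
    return result


@dataclass(frozen=True)
class DiffusionSolution:
    """u(x) = (1 + c x)**(-2/k) with c = (k/2) * sqrt(2 b / (2 - k)).

    Steady-state of (u**-k u')' - b u = 0 on x >= 0 with u(0) = 1, decaying
    at infinity with power-law rate 2/k.  Valid for 0 < k < 2, b > 0.
    """

    k: float
    b: float
    c: float

    def __call__(self, x):
        return (1.0 + self.c * np.asarray(x, dtype=float)) ** (-2.0 / self.k)

    def derivative(self, x):
        """Exact u'(x) of the closed form."""
        x = np.asarray(x, dtype=float)
        return -(2.0 * self.c / self.k) * (1.0 + self.c * x) ** (-2.0 / self.k - 1.0)

    def flux(self, x):
        """a(u) u' = -(2c/k) (1 + c x)**(1 - 2/k)."""
        x = np.asarray(x, dtype=float)
        return -(2.0 * self.c / self.k) * (1.0 + self.c * x) ** (1.0 - 2.0 / self.k)

    def flux_derivative(self, x):
        """(a(u) u')' with exact derivatives of the closed form."""
        x = np.asarray(x, dtype=float)
        coeff = -(2.0 * self.c**2 / self.k) * (1.0 - 2.0 / self.k)
        return coeff * (1.0 + self.c * x) ** (-2.0 / self.k)


def diffusion_solution(k: float, b: float) -> DiffusionSolution:
    """Construct the closed-form decaying solution for 0 < k < 2, b > 0."""
    if not 0 < k < 2:
        raise InvalidArgumentError(f"a decaying solution requires 0 < k < 2, got k={k}")
    if not b > 0:
        raise InvalidArgumentError(f"consumption rate must be positive, got b={b}")
    c = (k / 2.0) * math.sqrt(2.0 * b / (2.0 - k))
    return DiffusionSolution(k=k, b=b, c=c)


def ode_residual(solution: DiffusionSolution, x_grid) -> float:
    """max |(a(u) u')' - b u| over the grid, using exact derivatives."""
    x = np.asarray(x_grid, dtype=float)
    if x.size == 0 or np.any(x <= 0) or not np.all(np.isfinite(x)):
        raise InvalidArgumentError("x grid must be finite and strictly positive")
    residual = solution.flux_derivative(x) - solution.b * solution(x)
    return float(np.max(np.abs(residual)))
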