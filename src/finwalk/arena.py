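"""Bounded arena geometry: rounded-corner square tank and wall projections.

The experimental tank is a square of side ``L`` (cm) centred at the origin;
the simulation arena rounds its corners with quarter-circle arcs of radius
``R_c`` so that a point-like walker does not face competing perpendicular
repulsion at the vertices.  The resulting region is convex (Minkowski sum
of a smaller square and a disk), so a ray cast from any interior point
crosses the boundary exactly once.

``project_collision`` gives the projected wall collision of an agent: the
distance ``d_W`` along its heading to the boundary, time ``t_W = d_W/u``,
and the signed incidence angle ``phi_W`` between the outward boundary
normal at the hit point and the heading, anticlockwise positive.  With this
sign, a turn in the direction of sgn(phi_W) steers away from the wall,
which is what makes the repulsion term in the walker model repulsive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["Arena", "WallProjection", "wall_corrected_turning"]

_EPS = 1e-12


@dataclass
class WallProjection:
    """Projected wall collision for an agent at a given state.

    d_w : distance to the boundary along the heading (cm).
    t_w : time to collision, d_w / speed (inf for a stationary agent).
    phi_w : signed angle (rad, [-pi, pi)) from the outward boundary normal
        at the hit point to the heading; 0 means head-on.
    hit_point : boundary intersection (x, y) in cm.
    """

    d_w: float
    t_w: float
    phi_w: float
    hit_point: tuple[float, float]


@dataclass
class Arena:
    """Square arena of side ``side`` with corners rounded at radius ``corner_radius``."""

    side: float = 120.0
    corner_radius: float = 10.0

    def __post_init__(self):
        if self.side <= 0:
            raise ValueError("side must be positive")
        if not (0.0 <= self.corner_radius <= self.side / 2):
            raise ValueError("corner_radius must be in [0, side/2]")

    @property
    def half(self) -> float:
        return self.side / 2.0

    def contains(self, x, y) -> np.ndarray | bool:
        """True where (x, y) lies inside the rounded square (boundary inclusive).

        Accepts scalars or arrays.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        h = self.half
        rc = self.corner_radius
        inside_square = (np.abs(x) <= h) & (np.abs(y) <= h)
        in_corner = (np.abs(x) > h - rc) & (np.abs(y) > h - rc)
        cx = np.sign(x) * (h - rc)
        cy = np.sign(y) * (h - rc)
        in_arc = np.hypot(x - cx, y - cy) <= rc
        out = inside_square & (~in_corner | in_arc)
        return bool(out) if out.ndim == 0 else out

    def boundary_distance(self, x: float, y: float) -> float:
        """Shortest distance from an interior point to the boundary (cm)."""
        h = self.half
        rc = self.corner_radius
        if abs(x) > h - rc and abs(y) > h - rc:
            cx = math.copysign(h - rc, x)
            cy = math.copysign(h - rc, y)
            return rc - math.hypot(x - cx, y - cy)
        return h - max(abs(x), abs(y))

    def sample_position(self, rng: np.random.Generator) -> tuple[float, float]:
        """Uniform random point inside the arena (rejection from the square)."""
        h = self.half
        while True:
            x, y = rng.uniform(-h, h, size=2)
            if self.contains(x, y):
                return float(x), float(y)

    def project_collision(self, x: float, y: float, phi: float, u: float) -> WallProjection:
        """Projected collision of a ray from (x, y) along heading ``phi``.

        Raises if the start point is outside the arena.  ``u`` only enters
        through ``t_w = d_w / u`` (inf when u == 0).
        """
        if not self.contains(x, y):
            raise ValueError(f"point ({x}, {y}) outside arena")
        dx, dy = math.cos(phi), math.sin(phi)
        h = self.half
        rc = self.corner_radius
        flat = h - rc
        best_t = math.inf
        best_normal = (0.0, 0.0)
        # flat walls: (wall coordinate, normal)
        for wx, wy, nx, ny in (
            (h, None, 1.0, 0.0),
            (-h, None, -1.0, 0.0),
            (None, h, 0.0, 1.0),
            (None, -h, 0.0, -1.0),
        ):
            if wx is not None:
                if abs(dx) < _EPS:
                    continue
                t = (wx - x) / dx
                if t <= _EPS or t >= best_t:
                    continue
                hy = y + t * dy
                if abs(hy) <= flat + _EPS:
                    best_t, best_normal = t, (nx, ny)
            else:
                if abs(dy) < _EPS:
                    continue
                t = (wy - y) / dy
                if t <= _EPS or t >= best_t:
                    continue
                hx = x + t * dx
                if abs(hx) <= flat + _EPS:
                    best_t, best_normal = t, (nx, ny)
        # corner arcs: quarter circles centred at (+-flat, +-flat)
        if rc > 0:
            for sx in (1.0, -1.0):
                for sy in (1.0, -1.0):
                    cx, cy = sx * flat, sy * flat
                    ox, oy = x - cx, y - cy
                    b = ox * dx + oy * dy
                    c = ox * ox + oy * oy - rc * rc
                    disc = b * b - c
                    if disc < 0:
                        continue
                    sq = math.sqrt(disc)
                    for t in (-b - sq, -b + sq):
                        if t <= _EPS or t >= best_t:
                            continue
                        hx, hy = x + t * dx, y + t * dy
                        # restrict to the quarter arc in this corner's quadrant
                        if (hx - cx) * sx >= -_EPS and (hy - cy) * sy >= -_EPS:
                            best_t = t
                            best_normal = ((hx - cx) / rc, (hy - cy) / rc)
        if not math.isfinite(best_t):
            raise RuntimeError("ray failed to hit the boundary (degenerate geometry)")
        mx, my = best_normal
        # signed angle from outward normal to ray direction, wrapped to [-pi, pi)
        phi_w = math.atan2(mx * dy - my * dx, mx * dx + my * dy)
        if phi_w >= math.pi:  # atan2 returns (-pi, pi]; map pi -> -pi
            phi_w = -math.pi
        t_w = best_t / u if u > 0 else math.inf
        return WallProjection(
            d_w=float(best_t),
            t_w=float(t_w),
            phi_w=float(phi_w),
            hit_point=(x + best_t * dx, y + best_t * dy),
        )


def wall_corrected_turning(omega, phi_w):
    """Wall-corrected turning speed: +|omega| for turns away from the wall.

    A turn is "away" when sgn(omega) == sgn(phi_w); otherwise the magnitude
    is negated.  In the head-on case phi_w == 0, sgn(0) matches no nonzero
    turn and the value is -|omega| (measure-zero edge case, fixed by
    convention).
    """
    omega = np.asarray(omega, dtype=float)
    phi_w = np.asarray(phi_w, dtype=float)
    out = np.where(np.sign(omega) == np.sign(phi_w), np.abs(omega), -np.abs(omega))
    return float(out) if out.ndim == 0 else out
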