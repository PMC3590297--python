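"""HyperBalls geometry: ray-cast spheres and bond hyperboloids.

Atoms are spheres; a bond is the surface of revolution

    rho^2 = a^2 + c * (x - x_w)^2        (local frame, x along the bond)

with waist radius a = (1 - s) * min(r_i, r_j) set by the shrink factor
s in [0, 1), and (c, x_w) solved so the curve is externally tangent to
both atom spheres. As s grows the waist tightens and the one-sheeted
hyperboloid pinches continuously toward a cone / two-sheet limit; at s = 0
with equal radii the bond degenerates to a tangent cylinder. Every surface
is stored as a symmetric 4x4 quadric (inside-negative sign convention) so
one ray-quadratic intersection routine serves both kinds.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import HyperviewError


class TangencyError(HyperviewError):
    """No external tangency exists (one sphere inside the other), or the
    Newton solve failed to converge."""


@dataclass
class Quadric:
    """Homogeneous quadric surface {p : p~^T Q p~ = 0}, Q symmetric.

    ``axis_frame`` is the 4x4 rigid world->local transform (x along the
    bond axis for hyperboloids); ``x_bounds`` is the local-frame clip slab.
    Spheres are unclipped (bounds infinite).
    """

    Q: np.ndarray  # (4, 4) symmetric, world coordinates
    kind: str  # "sphere" | "hyperboloid"
    axis_frame: np.ndarray = field(default_factory=lambda: np.eye(4))
    x_bounds: tuple[float, float] = (-np.inf, np.inf)
    color: tuple[float, float, float] = (0.8, 0.8, 0.8)
    # conservative world-space AABB of the primitive (its render envelope)
    aabb: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        if self.Q.shape != (4, 4) or not np.allclose(self.Q, self.Q.T, atol=1e-9):
            raise ValueError("Q must be a symmetric 4x4 matrix")
        if self.kind == "hyperboloid" and not self.x_bounds[0] < self.x_bounds[1]:
            raise ValueError("x_bounds must satisfy x_lo < x_hi")

    def evaluate(self, point: np.ndarray) -> float:
        """Signed quadric value at a world point (negative inside)."""
        p = np.append(np.asarray(point, dtype=float), 1.0)
        return float(p @ self.Q @ p)

    def in_slab(self, point: np.ndarray) -> bool:
        lo, hi = self.x_bounds
        if lo == -np.inf and hi == np.inf:
            return True
        local = self.axis_frame @ np.append(np.asarray(point, dtype=float), 1.0)
        return bool(lo - 1e-9 <= local[0] <= hi + 1e-9)


@dataclass
class BondGeometry:
    """Solved bond-surface parameters in the local frame (origin at atom i)."""

    shrink: float
    waist_radius: float  # a
    waist_center: float  # x_w
    curvature: float  # c >= 0
    tangent_i: float  # tangency abscissa on sphere i
    tangent_j: float  # tangency abscissa on sphere j
    axis_length: float  # D = |p_j - p_i|


def sphere_quadric(
    center: np.ndarray, radius: float, color: tuple[float, float, float] = (0.8, 0.8, 0.8)
) -> Quadric:
    """Quadric of the sphere |p - center|^2 - r^2 = 0.

    The recorded AABB (side 2r cube) is the primitive's screen-projection
    envelope for the renderer.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    c = np.asarray(center, dtype=float).reshape(3)
    Q = np.eye(4)
    Q[:3, 3] = -c
    Q[3, :3] = -c
    Q[3, 3] = float(c @ c - radius**2)
    return Quadric(
        Q=Q,
        kind="sphere",
        color=color,
        aabb=(c - radius, c + radius),
    )


def _local_frame(p_i: np.ndarray, p_j: np.ndarray) -> np.ndarray:
    """World->local rigid transform: origin at p_i, local x along the bond."""
    x = p_j - p_i
    d = np.linalg.norm(x)
    x = x / d
    helper = np.array([0.0, 0.0, 1.0]) if abs(x[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    y = np.cross(helper, x)
    y /= np.linalg.norm(y)
    z = np.cross(x, y)
    R = np.vstack([x, y, z])  # rows = local axes
    M = np.eye(4)
    M[:3, :3] = R
    M[:3, 3] = -R @ p_i
    return M


def _tangency_residuals(c: float, x_w: float, a: float, r_i: float, r_j: float, D: float):
    """Residuals of double tangency for the curve rho^2 = a^2 + c (x - x_w)^2.

    The tangency abscissa on a sphere centered at X with radius r follows
    from matching slopes: x_t - X = c (x_w - X) / (1 + c); substituting into
    both surface equations gives one residual per sphere.
    """
    x1 = c * x_w / (1.0 + c)
    x2 = (c * x_w + D) / (1.0 + c)
    f1 = a**2 + c * (x1 - x_w) ** 2 - (r_i**2 - x1**2)
    f2 = a**2 + c * (x2 - x_w) ** 2 - (r_j**2 - (x2 - D) ** 2)
    return np.array([f1, f2]), (x1, x2)


def bond_hyperboloid(
    p_i: np.ndarray,
    r_i: float,
    p_j: np.ndarray,
    r_j: float,
    shrink: float = 0.3,
    color: tuple[float, float, float] = (0.8, 0.8, 0.8),
    tol: float = 1e-10,
) -> tuple[Quadric, BondGeometry]:
    """Bond surface between two spheres at the given shrink factor.

    (c, x_w) are found by a damped 2-unknown Newton iteration on the two
    tangency residuals (finite-difference Jacobian, tolerance ``tol``).
    The quadric is clipped to the slab between the tangency abscissae; the
    spheres remain responsible for their own caps.
    """
    p_i = np.asarray(p_i, dtype=float).reshape(3)
    p_j = np.asarray(p_j, dtype=float).reshape(3)
    if r_i <= 0 or r_j <= 0:
        raise ValueError("radii must be positive")
    if not (0 <= shrink < 1):
        raise ValueError("shrink must be in [0, 1)")
    D = float(np.linalg.norm(p_j - p_i))
    if D < 1e-12:
        raise ValueError("bond endpoints coincide")
    if D + min(r_i, r_j) <= max(r_i, r_j):
        raise TangencyError(
            f"sphere of radius {min(r_i, r_j)} lies inside the other (D={D:.3g}); "
            "no external tangency exists"
        )
    a = (1.0 - shrink) * min(r_i, r_j)

    # Informed initial guess from the waist/tangency geometry: the slab
    # positions split the axis like sqrt(r^2 - a^2), which also tells the
    # branch — c > 0 (hyperboloid) for separated spheres, c < -1
    # (ellipsoidal barrel) under strong overlap, with the parabolic
    # transition u -> 1 degenerate in this parameterization.
    num = max(r_i**2 - a**2, 0.0)
    den = max(r_j**2 - a**2, 0.0)
    if num < 1e-14 and den < 1e-14:
        c0, xw0 = 0.0, 0.5 * D  # equal radii at shrink 0: tangent cylinder
    elif num < 1e-14:
        c0, xw0 = den / D**2 / max(1 - den / D**2, 1e-6), 0.0
    elif den < 1e-14:
        c0, xw0 = num / D**2 / max(1 - num / D**2, 1e-6), D
    else:
        beta = np.sqrt(num / den)
        xw0 = beta * D / (1.0 + beta)
        u0 = num / xw0**2
        if u0 >= 1.0 - 1e-9:
            raise TangencyError(
                f"spheres overlap too deeply for a hyperboloid bond at this "
                f"shrink (r_i={r_i}, r_j={r_j}, D={D}, shrink={shrink}); "
                "increase the shrink factor or shrink the radii"
            )
        c0 = u0 / (1.0 - u0)
    c, x_w = c0, xw0
    converged = False
    for _ in range(100):
        F, _xt = _tangency_residuals(c, x_w, a, r_i, r_j, D)
        if np.max(np.abs(F)) < tol:
            converged = True
            break
        J = np.empty((2, 2))
        hc = max(1e-8, 1e-8 * abs(c))
        hx = max(1e-8, 1e-8 * abs(x_w))
        J[:, 0] = (_tangency_residuals(c + hc, x_w, a, r_i, r_j, D)[0] - F) / hc
        J[:, 1] = (_tangency_residuals(c, x_w + hx, a, r_i, r_j, D)[0] - F) / hx
        try:
            delta = np.linalg.solve(J, -F)
        except np.linalg.LinAlgError as exc:
            raise TangencyError(f"singular Jacobian at c={c:.4g}, x_w={x_w:.4g}") from exc
        step = 1.0
        while c + step * delta[0] <= -0.999:
            step *= 0.5
        c += step * delta[0]
        x_w += step * delta[1]
    if not converged:
        F, _ = _tangency_residuals(c, x_w, a, r_i, r_j, D)
        raise TangencyError(
            f"Newton failed: residual {np.max(np.abs(F)):.3g} at c={c:.4g}, x_w={x_w:.4g} "
            f"(r_i={r_i}, r_j={r_j}, D={D}, shrink={shrink})"
        )

    _, (x1, x2) = _tangency_residuals(c, x_w, a, r_i, r_j, D)
    geom = BondGeometry(
        shrink=shrink,
        waist_radius=a,
        waist_center=float(x_w),
        curvature=float(c),
        tangent_i=float(x1),
        tangent_j=float(x2),
        axis_length=D,
    )

    # local quadric: y^2 + z^2 - c (x - x_w)^2 - a^2 = 0 (inside-negative)
    Ql = np.zeros((4, 4))
    Ql[0, 0] = -c
    Ql[1, 1] = 1.0
    Ql[2, 2] = 1.0
    Ql[0, 3] = Ql[3, 0] = c * x_w
    Ql[3, 3] = -c * x_w**2 - a**2
    M = _local_frame(p_i, p_j)
    Qw = M.T @ Ql @ M
    Qw = 0.5 * (Qw + Qw.T)

    rho_max = float(np.sqrt(a**2 + c * max((x1 - x_w) ** 2, (x2 - x_w) ** 2)))
    axis = (p_j - p_i) / D
    lo_pt = p_i + axis * x1
    hi_pt = p_i + axis * x2
    pad = rho_max
    aabb = (np.minimum(lo_pt, hi_pt) - pad, np.maximum(lo_pt, hi_pt) + pad)

    quad = Quadric(
        Q=Qw,
        kind="hyperboloid",
        axis_frame=M,
        x_bounds=(float(x1), float(x2)),
        color=color,
        aabb=aabb,
    )
    return quad, geom


@dataclass
class RayHit:
    t: float
    point: np.ndarray
    normal: np.ndarray


def intersect_ray(quadric: Quadric, origin: np.ndarray, direction: np.ndarray) -> RayHit | None:
    """Nearest positive ray-quadric intersection, or None on a miss.

    Substituting p = o + t d into p~^T Q p~ = 0 gives a quadratic in t;
    the smaller positive root wins unless the clip slab rejects it, in
    which case the far root is considered. The normal is the normalized
    spatial gradient 2 (Q p~) oriented toward the ray origin.
    """
    o = np.append(np.asarray(origin, dtype=float), 1.0)
    d = np.append(np.asarray(direction, dtype=float), 0.0)
    Q = quadric.Q
    A = float(d @ Q @ d)
    B = 2.0 * float(o @ Q @ d)
    C = float(o @ Q @ o)
    eps = 1e-12
    if abs(A) < eps:
        if abs(B) < eps:
            return None
        roots = [-C / B]
    else:
        disc = B * B - 4 * A * C
        if disc < 0:
            return None
        sq = np.sqrt(disc)
        roots = sorted([(-B - sq) / (2 * A), (-B + sq) / (2 * A)])
    for t in roots:
        if t <= eps:
            continue
        point = origin + t * np.asarray(direction, dtype=float)
        if not quadric.in_slab(point):
            continue
        grad = 2.0 * (Q @ np.append(point, 1.0))[:3]
        n = np.linalg.norm(grad)
        if n < 1e-300:
            continue
        normal = grad / n
        if float(normal @ np.asarray(direction, dtype=float)) > 0:
            normal = -normal
        return RayHit(t=float(t), point=point, normal=normal)
    return None
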