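"""Quadratic-midline cell coordinate system and the Cartesian <-> cellular transform.

A rod-shaped cell is described by six scalars: the coefficients ``a0, a1, a2``
of the midline polynomial ``p(x) = a0 + a1*x + a2*x**2``, the midline domain
endpoints ``xl < xr`` and the cell radius ``r``.  Every Cartesian point
``(xp, yp)`` (image convention: y runs down, the centre of the top-left pixel
is at (0.5, 0.5)) maps to cellular coordinates

* ``xc`` -- abscissa of the closest point on the midline, clamped to
  ``[xl, xr]`` so that pole points project onto the midline endpoints;
* ``lc`` -- arc length along the midline from ``xl`` to ``xc`` (longitudinal
  position, 0 at the left pole, cell length at the right pole);
* ``rc`` -- Euclidean distance from the point to ``(xc, p(xc))``;
* ``phi`` -- angle in degrees, 0 on the top side of the cell (``yp < p(xp)``,
  i.e. smaller image row), 180 on the bottom side, and running continuously
  0 -> 180 around each hemispherical pole cap.

All functions are vectorised over point arrays; scalars in, scalars out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CoordinateParameters",
    "CellularPoint",
    "closest_midline_point",
    "map_to_cellular",
    "map_to_cartesian",
    "arc_length",
    "cell_length",
    "coordinate_maps",
]

#: below this |a2| the midline is treated as exactly linear (the cubic's
#: leading coefficient 2*a2**2 would be numerically degenerate)
A2_LINEAR_THRESHOLD = 1e-10

_POLE_TOL = 1e-9


@dataclass(frozen=True)
class CoordinateParameters:
    """The six parameters defining one cell's coordinate system (units: px)."""

    a0: float
    a1: float
    a2: float
    xl: float
    xr: float
    r: float

    def __post_init__(self) -> None:
        vals = (self.a0, self.a1, self.a2, self.xl, self.xr, self.r)
        if not all(np.isfinite(vals)):
            raise ValueError(f"non-finite coordinate parameters: {vals}")
        if not self.xl < self.xr:
            raise ValueError(f"require xl < xr, got xl={self.xl}, xr={self.xr}")
        if not self.r > 0:
            raise ValueError(f"require r > 0, got r={self.r}")

    def p(self, x):
        """Midline value p(x) = a0 + a1*x + a2*x**2."""
        x = np.asarray(x, dtype=float)
        return self.a0 + self.a1 * x + self.a2 * x * x

    def p_prime(self, x):
        """Midline slope p'(x) = a1 + 2*a2*x."""
        x = np.asarray(x, dtype=float)
        return self.a1 + 2.0 * self.a2 * x

    def with_updates(self, **kwargs) -> "CoordinateParameters":
        d = {f: getattr(self, f) for f in ("a0", "a1", "a2", "xl", "xr", "r")}
        d.update(kwargs)
        return CoordinateParameters(**d)

    def to_array(self) -> np.ndarray:
        return np.array([self.a0, self.a1, self.a2, self.xl, self.xr, self.r])

    @classmethod
    def from_array(cls, arr) -> "CoordinateParameters":
        return cls(*(float(v) for v in arr))


@dataclass(frozen=True)
class CellularPoint:
    """Cellular coordinates of one Cartesian point."""

    xc: float
    lc: float
    rc: float
    phi: float


def _check_finite_points(xp, yp):
    xp = np.asarray(xp, dtype=float)
    yp = np.asarray(yp, dtype=float)
    if not (np.all(np.isfinite(xp)) and np.all(np.isfinite(yp))):
        raise ValueError("non-finite Cartesian coordinates")
    return xp, yp


def _cubic_real_candidates(a, b, c, d):
    """Real parts of the three roots of a*t^3 + b*t^2 + c*t + d = 0.

    ``a`` and ``b`` are scalars, ``c`` and ``d`` arrays (one cubic per point).
    Cardano's method in complex arithmetic; for the point-projection cubic the
    unconstrained minimiser is always a real stationary point, so it appears
    among the real parts and evaluating the distance at all three candidates
    and taking the arg-min is safe.
    """
    c = np.asarray(c, dtype=complex)
    d = np.asarray(d, dtype=complex)
    # depressed cubic t = s - b/(3a):  s^3 + p s + q = 0
    p = (3.0 * a * c - b * b) / (3.0 * a * a)
    q = (2.0 * b**3 - 9.0 * a * b * c + 27.0 * a * a * d) / (27.0 * a**3)
    delta = (q / 2.0) ** 2 + (p / 3.0) ** 3
    u3 = -q / 2.0 + np.sqrt(delta)
    # avoid the u = 0 singularity (p = q = 0): fall back to the other branch
    alt = -q / 2.0 - np.sqrt(delta)
    u3 = np.where(np.abs(u3) > np.abs(alt), u3, alt)
    u = u3 ** (1.0 / 3.0)
    tiny = np.abs(u) < 1e-300
    u = np.where(tiny, 1.0, u)  # placeholder; roots are 0 there anyway
    omega = np.exp(2j * np.pi / 3.0)
    roots = []
    for k in range(3):
        uk = u * omega**k
        s = uk - p / (3.0 * uk)
        s = np.where(tiny, 0.0, s)
        roots.append(s.real - b / (3.0 * a))
    return np.stack(roots, axis=0)


def closest_midline_point(params: CoordinateParameters, xp, yp):
    """Abscissa ``xc`` of the midline point closest to ``(xp, yp)``.

    The squared distance ``(x - xp)**2 + (p(x) - yp)**2`` is minimised over
    the whole real line by solving its stationarity condition -- the cubic
    ``2*a2**2*x^3 + 3*a1*a2*x^2 + (1 + a1^2 + 2*a2*(a0 - yp))*x
    + (a1*(a0 - yp) - xp) = 0`` -- in closed form, and the minimiser is then
    clamped to the midline domain ``[xl, xr]``.
    """
    xp, yp = _check_finite_points(xp, yp)
    scalar = xp.ndim == 0 and yp.ndim == 0
    xp, yp = np.atleast_1d(xp), np.atleast_1d(yp)
    xp, yp = np.broadcast_arrays(xp, yp)
    a0, a1, a2 = params.a0, params.a1, params.a2

    if abs(a2) < A2_LINEAR_THRESHOLD:
        # linear midline: the stationarity condition is linear in x
        x_star = (xp - a1 * (a0 - yp)) / (1.0 + a1 * a1)
    else:
        xf, yf = xp.ravel(), yp.ravel()
        A = 2.0 * a2 * a2
        B = 3.0 * a1 * a2
        C = 1.0 + a1 * a1 + 2.0 * a2 * (a0 - yf)
        D = a1 * (a0 - yf) - xf
        cand = _cubic_real_candidates(A, B, C, D)
        d2 = (cand - xf) ** 2 + (params.p(cand) - yf) ** 2
        x_star = cand[np.argmin(d2, axis=0), np.arange(cand.shape[1])].reshape(xp.shape)

    xc = np.clip(x_star, params.xl, params.xr)
    return float(xc.ravel()[0]) if scalar else xc


def arc_length(params: CoordinateParameters, x_start, x_end):
    """Arc length of the midline between two abscissae (closed form).

    With ``u = a1 + 2*a2*x`` the antiderivative of ``sqrt(1 + p'(x)**2)`` is
    ``(u*sqrt(1+u^2) + asinh(u)) / (4*a2)``; for ``a2 -> 0`` the integrand is
    constant and the chord formula is used instead.
    """
    x_start = np.asarray(x_start, dtype=float)
    x_end = np.asarray(x_end, dtype=float)
    if not (np.all(np.isfinite(x_start)) and np.all(np.isfinite(x_end))):
        raise ValueError("non-finite abscissae")
    a1, a2 = params.a1, params.a2
    dx = x_end - x_start
    # midpoint-slope chord: second-order accurate, error <= |dx|^3 * a2^2 / 6;
    # used where the closed form would cancel catastrophically (tiny a2*dx)
    u_mid = a1 + 2.0 * a2 * (x_start + 0.5 * dx)
    midpoint = dx * np.sqrt(1.0 + u_mid * u_mid)
    if abs(a2) < A2_LINEAR_THRESHOLD:
        return midpoint

    def F(x):
        u = a1 + 2.0 * a2 * x
        return (u * np.sqrt(1.0 + u * u) + np.arcsinh(u)) / (4.0 * a2)

    closed = F(x_end) - F(x_start)
    return np.where(np.abs(a2 * dx) < 1e-5, midpoint, closed)


def cell_length(params: CoordinateParameters) -> float:
    """Full midline length of the cell, ``arc_length(xl, xr)``."""
    return float(arc_length(params, params.xl, params.xr))


def _pole_frames(params, xc):
    """Unit top-normal and outward tangent of the midline at abscissae xc."""
    slope = params.p_prime(xc)
    s = np.sqrt(1.0 + slope * slope)
    # top side is smaller y (image y runs down), so the top normal has dy < 0
    nx, ny = slope / s, -1.0 / s
    tx, ty = 1.0 / s, slope / s
    return nx, ny, tx, ty


def map_to_cellular(params: CoordinateParameters, xp, yp):
    """Transform Cartesian point(s) to cellular coordinates.

    Returns ``(xc, lc, rc, phi)`` arrays (or a :class:`CellularPoint` for
    scalar input).  ``phi`` is 0 on the top side of the cell body, 180 on the
    bottom, and for pole points it is the angle between the top-oriented
    normal at the midline endpoint and the segment to the point, running
    continuously from 0 (top) to 180 (bottom) around each cap.  On the
    midline (``rc = 0``) the angle is undefined and fixed to 0.
    """
    xp, yp = _check_finite_points(xp, yp)
    scalar = xp.ndim == 0 and yp.ndim == 0
    xp, yp = np.broadcast_arrays(np.atleast_1d(xp), np.atleast_1d(yp))

    xc = closest_midline_point(params, xp, yp)
    xc = np.atleast_1d(xc)
    pc = params.p(xc)
    lc = arc_length(params, params.xl, xc)
    rc = np.hypot(xc - xp, pc - yp)

    phi = np.where(yp < params.p(xp), 0.0, 180.0)

    pole = (xc <= params.xl + _POLE_TOL) | (xc >= params.xr - _POLE_TOL)
    if np.any(pole):
        nx, ny, _, _ = _pole_frames(params, xc[pole])
        vx = xp[pole] - xc[pole]
        vy = yp[pole] - pc[pole]
        norm = np.hypot(vx, vy)
        safe = np.where(norm > 0, norm, 1.0)
        cosang = np.clip((nx * vx + ny * vy) / safe, -1.0, 1.0)
        phi_pole = np.degrees(np.arccos(cosang))
        phi_pole = np.where(norm > 0, phi_pole, 0.0)
        phi = phi.astype(float)
        phi[pole] = phi_pole

    phi = np.where(rc <= _POLE_TOL, 0.0, phi)

    if scalar:
        return CellularPoint(float(xc[0]), float(lc[0]), float(rc[0]), float(phi[0]))
    return xc, lc, rc, phi


def _invert_arc_length(params: CoordinateParameters, lc):
    """Abscissa xc with arc_length(xl, xc) = lc (vectorised safeguarded Newton).

    The arc length is strictly increasing with derivative >= 1, so Newton
    from the chord estimate converges; iterates are clipped to [xl, xr].
    """
    lc = np.asarray(lc, dtype=float)
    L = cell_length(params)
    x = params.xl + np.clip(lc / max(L, 1e-300), 0.0, 1.0) * (params.xr - params.xl)
    for _ in range(100):
        g = arc_length(params, params.xl, x) - lc
        slope = params.p_prime(x)
        step = g / np.sqrt(1.0 + slope * slope)
        x = np.clip(x - step, params.xl, params.xr)
        if np.max(np.abs(step)) < 1e-12:
            break
    return x


def map_to_cartesian(params: CoordinateParameters, lc, rc, phi):
    """Inverse transform: cellular coordinates back to Cartesian ``(xp, yp)``.

    ``lc`` is inverted to the midline abscissa through the monotone arc-length
    function; the point is then placed at distance ``rc`` along the direction
    selected by ``phi`` (the top/bottom normal on the cell body, the rotated
    endpoint normal on the pole caps).  Round trip with
    :func:`map_to_cellular` is the identity wherever ``rc > 0``.
    """
    lc = np.asarray(lc, dtype=float)
    rc = np.asarray(rc, dtype=float)
    phi = np.asarray(phi, dtype=float)
    scalar = lc.ndim == 0 and rc.ndim == 0 and phi.ndim == 0
    lc, rc, phi = np.broadcast_arrays(
        np.atleast_1d(lc), np.atleast_1d(rc), np.atleast_1d(phi)
    )
    L = cell_length(params)
    if np.any(lc < -1e-9) or np.any(lc > L + 1e-9):
        raise ValueError(f"lc outside [0, {L}]")
    if np.any(rc < 0):
        raise ValueError("rc must be >= 0")

    xc = _invert_arc_length(params, np.clip(lc, 0.0, L))
    pc = params.p(xc)
    nx, ny, tx, ty = _pole_frames(params, xc)

    left = xc <= params.xl + _POLE_TOL
    right = xc >= params.xr - _POLE_TOL
    # outward tangent: +t at the right pole, -t at the left pole, unused (0)
    # on the body where phi is 0 or 180 and the sine vanishes
    wsign = np.where(right, 1.0, np.where(left, -1.0, 0.0))
    ang = np.radians(phi)
    dx = np.cos(ang) * nx + np.sin(ang) * wsign * tx
    dy = np.cos(ang) * ny + np.sin(ang) * wsign * ty

    xp = xc + rc * dx
    yp = pc + rc * dy
    if scalar:
        return float(xp[0]), float(yp[0])
    return xp, yp


def pixel_centers(shape):
    """Cartesian coordinates of the pixel centres of an image of given shape.

    Pixel (row i, col j) has centre ``(j + 0.5, i + 0.5)``.
    """
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    return xx + 0.5, yy + 0.5


def coordinate_maps(params: CoordinateParameters, shape):
    """Per-pixel coordinate images ``(xc, lc, rc, phi)`` for a given shape."""
    rows, cols = int(shape[0]), int(shape[1])
    if rows <= 0 or cols <= 0:
        raise ValueError(f"shape must be positive, got {shape}")
    xx, yy = pixel_centers((rows, cols))
    xc, lc, rc, phi = map_to_cellular(params, xx.ravel(), yy.ravel())
    return (
        xc.reshape(rows, cols),
        lc.reshape(rows, cols),
        rc.reshape(rows, cols),
        phi.reshape(rows, cols),
    )


def radial_distance_map(params: CoordinateParameters, shape):
    """The ``rc`` plane of :func:`coordinate_maps` alone."""
    return coordinate_maps(params, shape)[2]


# -- perimeter parametrisation of the isodistance outline --------------------
#
# The closed outline at constant radial distance R is parametrised by a
# position s in [0, P) with P = 2*L + 2*pi*R (L = midline length): the top
# membrane segment runs s = lc from 0 to L, the right pole cap s = L +
# (phi/180)*pi*R, the bottom segment back from lc = L to 0, and the left pole
# cap closes the loop.  Zero is at (lc = 0, phi = 0, rc = R) and s increases
# clockwise in the image (y-down) convention.  For curved midlines the
# in-segment metric is the midline arc length, not the offset-curve length
# (the curvature correction ~ a2*R is neglected).


def perimeter_length(params: CoordinateParameters, radius=None) -> float:
    """Length of the closed isodistance outline, ``2*L + 2*pi*R``."""
    R = params.r if radius is None else float(radius)
    return 2.0 * cell_length(params) + 2.0 * np.pi * R


def perimeter_position(params: CoordinateParameters, lc, phi, radius=None):
    """Position along the outline of cellular points ``(lc, phi)`` (rc near R)."""
    R = params.r if radius is None else float(radius)
    lc = np.atleast_1d(np.asarray(lc, dtype=float))
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    lc, phi = np.broadcast_arrays(lc, phi)
    L = cell_length(params)
    half_cap = np.pi * R
    P = 2.0 * L + 2.0 * half_cap

    right_pole = lc >= L - _POLE_TOL
    left_pole = lc <= _POLE_TOL
    bottom = (~right_pole) & (~left_pole) & (phi >= 90.0)

    s = np.where(bottom, L + half_cap + (L - lc), lc)  # top or bottom body
    s = np.where(right_pole, L + phi / 180.0 * half_cap, s)
    s = np.where(left_pole & (phi > 0), 2.0 * L + half_cap
                 + (180.0 - phi) / 180.0 * half_cap, s)
    return np.mod(s, P)


def cellular_from_perimeter(params: CoordinateParameters, s, radius=None):
    """Inverse of :func:`perimeter_position`: outline position -> ``(lc, phi)``."""
    R = params.r if radius is None else float(radius)
    s = np.atleast_1d(np.asarray(s, dtype=float))
    L = cell_length(params)
    half_cap = np.pi * R
    P = 2.0 * L + 2.0 * half_cap
    s = np.mod(s, P)

    lc = np.empty_like(s)
    phi = np.empty_like(s)
    top = s < L
    rpole = (s >= L) & (s < L + half_cap)
    bot = (s >= L + half_cap) & (s < 2.0 * L + half_cap)
    lpole = s >= 2.0 * L + half_cap

    lc[top] = s[top]
    phi[top] = 0.0
    lc[rpole] = L
    phi[rpole] = (s[rpole] - L) / half_cap * 180.0
    lc[bot] = 2.0 * L + half_cap - s[bot]
    phi[bot] = 180.0
    lc[lpole] = 0.0
    phi[lpole] = 180.0 - (s[lpole] - 2.0 * L - half_cap) / half_cap * 180.0
    return lc, phi
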