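"""Helical-curve model and synthetic Cα-trace generation.

The curve model parametrizes a general helix by five quantities: radius
``r`` (Å), per-residue rise ``p`` (Å), per-residue turn angle ``t``
(degrees), an origin vector and a proper rotation matrix.  With identity
rotation and zero origin the canonical curve is

    point(u) = (r sin(u t), r cos(u t), u p)

so that consecutive integer values of the parameter ``u`` are one residue
apart.  A left-handed curve negates the angular argument.  The chord length
between consecutive residues obeys

    d^2 = p^2 + 4 r^2 sin^2(t / 2)

which is also the identity used to recover ``t`` from (r, p, d).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "HelicalCurve",
    "TraceFixtureSpec",
    "InvalidGeometryError",
    "curve_point",
    "curve_points",
    "turn_angle_from_rp",
    "chord_length",
    "generate_ideal_calphas",
    "mirror_coordinates",
    "closest_point_distance",
    "helix_in_coil_trace",
    "kinked_pair_trace",
]


class InvalidGeometryError(ValueError):
    """Raised when (r, p, d) admit no real turn angle (d <= p or arcsin > 1)."""


def _check_rotation(rotation: np.ndarray) -> np.ndarray:
    rotation = np.asarray(rotation, dtype=float)
    if rotation.shape != (3, 3):
        raise ValueError("rotation must be 3x3")
    if not np.allclose(rotation @ rotation.T, np.eye(3), atol=1e-9):
        raise ValueError("rotation must be orthonormal")
    if np.linalg.det(rotation) < 0:
        raise ValueError("rotation must be proper (det +1)")
    return rotation


@dataclass(frozen=True)
class HelicalCurve:
    """A five-parameter helical curve plus handedness.

    Parameters
    ----------
    radius : float
        Distance of the trace from the helix axis, Å. Must be positive.
    rise : float
        Axial advance per residue, Å. Non-negative.
    turn : float
        Rotation about the axis per residue, degrees, in (0, 360).
    origin : array-like of shape (3,)
        Curve origin r0, Å.
    rotation : array-like of shape (3, 3)
        Proper orthonormal matrix orienting the canonical curve; the helix
        axis is ``rotation @ (0, 0, 1)``.
    handedness : {"right", "left"}
    """

    radius: float
    rise: float
    turn: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    handedness: str = "right"

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.rise < 0:
            raise ValueError("rise must be >= 0")
        if not 0.0 < self.turn < 360.0:
            raise ValueError("turn angle must be in (0, 360) degrees")
        if self.handedness not in ("right", "left"):
            raise ValueError("handedness must be 'right' or 'left'")
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        object.__setattr__(self, "rotation", _check_rotation(self.rotation))

    @property
    def axis(self) -> np.ndarray:
        """Unit helix-axis direction."""
        return self.rotation @ np.array([0.0, 0.0, 1.0])


@dataclass(frozen=True)
class TraceFixtureSpec:
    """Recipe for a synthetic Cα trace: curve, length, noise level, seed."""

    curve: HelicalCurve
    n_residues: int
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise ValueError("n_residues must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def curve_point(curve: HelicalCurve, u: float) -> np.ndarray:
    """Evaluate the curve at residue-index parameter ``u`` (Å)."""
    return curve_points(curve, np.asarray([u], dtype=float))[0]


def curve_points(curve: HelicalCurve, u: np.ndarray) -> np.ndarray:
    """Vectorized :func:`curve_point` over an array of parameters."""
    u = np.asarray(u, dtype=float)
    theta = np.radians(curve.turn) * u
    if curve.handedness == "left":
        theta = -theta
    local = np.stack(
        [curve.radius * np.sin(theta), curve.radius * np.cos(theta), u * curve.rise],
        axis=-1,
    )
    return curve.origin + local @ curve.rotation.T


def chord_length(r: float, p: float, t_deg: float) -> float:
    """Consecutive-residue chord length d from (r, p, t)."""
    return math.sqrt(p * p + 4.0 * r * r * math.sin(math.radians(t_deg) / 2.0) ** 2)


def turn_angle_from_rp(r: float, p: float, d: float) -> float:
    """Turn angle t (degrees) from radius, rise and consecutive-Cα distance.

    Inverts the chord identity: t = 2 arcsin(0.5 sqrt(d^2 - p^2) / r).

    Raises
    ------
    InvalidGeometryError
        If ``d <= p`` or the arcsin argument exceeds 1; callers doing a grid
        scan skip such cells.
    """
    if d <= p:
        raise InvalidGeometryError(f"d={d} <= p={p}: no real turn angle")
    arg = 0.5 * math.sqrt(d * d - p * p) / r
    if arg > 1.0:
        raise InvalidGeometryError(f"arcsin argument {arg} > 1")
    return math.degrees(2.0 * math.asin(arg))


def generate_ideal_calphas(spec: TraceFixtureSpec) -> np.ndarray:
    """Generate an (n, 3) Cα trace on the curve, optionally noise-perturbed.

    Point k sits at ``curve_point(curve, k)`` plus isotropic Gaussian noise
    of standard deviation ``noise_sigma`` drawn from ``seed``.  Zero noise
    yields a deterministic, exactly on-curve trace.
    """
    pts = curve_points(spec.curve, np.arange(spec.n_residues, dtype=float))
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        pts = pts + rng.normal(0.0, spec.noise_sigma, size=pts.shape)
    return pts


def mirror_coordinates(points: np.ndarray) -> np.ndarray:
    """Invert the x component of every coordinate (flips handedness)."""
    points = np.asarray(points, dtype=float)
    out = points.copy()
    out[..., 0] = -out[..., 0]
    return out


def closest_point_distance(
    curve: HelicalCurve, point: np.ndarray, u_window: tuple[float, float]
) -> float:
    """Minimum distance from ``point`` to the curve over a parameter window.

    Bounded 1-D minimization to 1e-8 parameter tolerance; callers pass a
    window of ±1 residue around the expected index so the search cannot
    capture the next turn.
    """
    point = np.asarray(point, dtype=float)

    def objective(u: float) -> float:
        diff = curve_points(curve, np.asarray([u]))[0] - point
        return float(diff @ diff)

    res = minimize_scalar(
        objective, bounds=u_window, method="bounded", options={"xatol": 1e-8}
    )
    return math.sqrt(res.fun)


# ---------------------------------------------------------------------------
# Composite fixture layouts


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation taking unit vector a onto unit vector b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(a @ b)
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180 deg about any perpendicular axis
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        return 2.0 * np.outer(perp, perp) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _append_segment(
    base: np.ndarray, seg: np.ndarray, gap: float = 3.8
) -> np.ndarray:
    """Rigidly place ``seg`` so it continues from the end of ``base``.

    The segment's first bond direction is aligned with the base's last bond
    direction and its first point sits ``gap`` Å past the base's last point.
    """
    if len(base) < 2:
        raise ValueError("base must have >= 2 points")
    direction = base[-1] - base[-2]
    direction = direction / np.linalg.norm(direction)
    seg_dir = seg[1] - seg[0]
    rot = _rotation_between(seg_dir / np.linalg.norm(seg_dir), direction)
    seg = (seg - seg[0]) @ rot.T + base[-1] + gap * direction
    return np.vstack([base, seg])


def _strand_trace(n: int) -> np.ndarray:
    # Extended-strand geometry (radius 0.96 A, rise 3.34 A, turn 177.9 deg):
    # quadruples on it score far above every helix threshold.
    curve = HelicalCurve(radius=0.96, rise=3.34, turn=177.9)
    return generate_ideal_calphas(TraceFixtureSpec(curve=curve, n_residues=n))


def helix_in_coil_trace(
    curve: HelicalCurve, n_helix: int, n_flank: int = 6
) -> tuple[np.ndarray, tuple[int, int]]:
    """A planted helix flanked by extended-strand 'coil' on both sides.

    Returns the (n, 3) trace and the (start, end) residue indices (inclusive)
    of the planted helix within it.
    """
    helix = generate_ideal_calphas(TraceFixtureSpec(curve=curve, n_residues=n_helix))
    pts = _strand_trace(n_flank)
    pts = _append_segment(pts, helix)
    pts = _append_segment(pts, _strand_trace(n_flank))
    return pts, (n_flank, n_flank + n_helix - 1)


def kinked_pair_trace(
    curve: HelicalCurve, n_each: int, kink_deg: float
) -> np.ndarray:
    """Two ideal helices of ``n_each`` residues joined with a known
    inter-axis angle (degrees)."""
    first = generate_ideal_calphas(TraceFixtureSpec(curve=curve, n_residues=n_each))
    second = generate_ideal_calphas(TraceFixtureSpec(curve=curve, n_residues=n_each))
    axis = curve.axis
    # tilt the second helix axis by kink_deg about a perpendicular axis
    perp = np.cross(axis, [1.0, 0.0, 0.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(axis, [0.0, 1.0, 0.0])
    perp /= np.linalg.norm(perp)
    ang = math.radians(kink_deg)
    k = perp
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    rot = np.eye(3) + math.sin(ang) * kx + (1 - math.cos(ang)) * (kx @ kx)
    second = second @ rot.T
    new_axis = rot @ axis
    join = first[-1] + 3.8 * new_axis
    second = second - second[0] + join
    return np.vstack([first, second])
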