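"""Helical-curve fitting to sliding Cα quadruples.

For every window of four consecutive Cα atoms the fitter

1. computes initial (r, p, t) estimates by a direct geometric construction,
2. scans an exhaustive grid of (r, p) values around the estimates; for each
   cell the turn angle follows from the chord identity, the candidate curve's
   four index points are rigidly superposed onto the quadruple by SVD
   (Kabsch), and the cell with the smallest superposition RMSD wins,
3. reports the winning curve, its axis, and the closest-point RMSD Δ of the
   four atoms to the curve after superposition.

Per-residue quantities derived from the sliding fits: the axis angle ``a``
between consecutive fitted axes (zero along a perfect helix) and the pooled
seven-residue RMSD ``δ`` over the up-to-four quadruple curves covering a
residue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .helix_model import (
    HelicalCurve,
    InvalidGeometryError,
    closest_point_distance,
    mirror_coordinates,
)

__all__ = [
    "GridSpec",
    "QuadrupleFit",
    "ResidueProfile",
    "DegenerateQuadrupleError",
    "kabsch_superpose",
    "initial_estimates",
    "fit_quadruple",
    "axis_angle",
    "delta_rmsd",
    "profile_segment",
]


class DegenerateQuadrupleError(ValueError):
    """Quadruple is collinear or has coincident points; no helix fits it."""


@dataclass(frozen=True)
class GridSpec:
    """Half-widths and step of the exhaustive (r, p) search grid, Å."""

    d_r: float = 0.25
    d_p: float = 0.25
    step: float = 0.01

    def __post_init__(self) -> None:
        if not (0.0 < self.step <= self.d_r and self.step <= self.d_p):
            raise ValueError("require 0 < step <= d_r and step <= d_p")


@dataclass
class QuadrupleFit:
    """Best-fit helical curve for one sliding quadruple.

    ``delta`` is the closest-point RMSD of the four Cα atoms after
    superposition; ``point_distances`` holds the four individual
    closest-point distances (consumed by the seven-residue RMSD δ).
    The axis is a unit vector oriented with positive projection on the
    Cα_i → Cα_{i+3} displacement.
    """

    start_index: int
    valid: bool
    r: float = math.nan
    p: float = math.nan
    t: float = math.nan
    delta: float = math.inf
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axis: np.ndarray = field(default_factory=lambda: np.zeros(3))
    handedness: str = "right"
    pair_rmsd: float = math.inf  # index-paired superposition RMSD (objective)
    point_distances: np.ndarray | None = None

    @property
    def curve(self) -> HelicalCurve:
        if not self.valid:
            raise ValueError("invalid fit has no curve")
        return HelicalCurve(
            radius=self.r,
            rise=self.p,
            turn=self.t,
            origin=self.origin,
            rotation=self.rotation,
        )


@dataclass
class ResidueProfile:
    """Per-residue fit summary for one handedness.

    Undefined quantities (no quadruple starts at this residue, or a
    neighbouring fit failed) are stored as ``inf`` so that every
    ``< threshold`` test fails on them.
    """

    index: int
    a: float = math.inf
    delta: float = math.inf
    small_delta: float = math.inf
    fit: QuadrupleFit | None = None


def kabsch_superpose(
    model: np.ndarray, target: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``model`` onto ``target`` (Kabsch/SVD).

    Returns ``(rotation, translation, rmsd)`` with
    ``rotation @ model[i] + translation ~ target[i]`` minimizing the
    index-paired RMSD.  The rotation is proper (det +1); reflections are
    excluded.

    Raises
    ------
    DegenerateQuadrupleError
        If either point set is collinear or collapses to a point.
    """
    model = np.asarray(model, dtype=float)
    target = np.asarray(target, dtype=float)
    if model.shape != target.shape or model.ndim != 2 or model.shape[0] < 3:
        raise ValueError("need two equal (n>=3, 3) point sets")
    mc = model.mean(axis=0)
    tc = target.mean(axis=0)
    x = model - mc
    y = target - tc
    if _is_degenerate(x) or _is_degenerate(y):
        raise DegenerateQuadrupleError("collinear or coincident point set")
    h = x.T @ y
    u, s, vt = np.linalg.svd(h)
    d = 1.0 if np.linalg.det(vt.T @ u.T) > 0 else -1.0
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    diff = x @ rot.T - y
    rmsd = math.sqrt(float((diff * diff).sum()) / len(model))
    trans = tc - rot @ mc
    return rot, trans, rmsd


def _is_degenerate(centered: np.ndarray, tol: float = 1e-8) -> bool:
    # rank < 2 after centering: all points on a line (or a single point)
    s = np.linalg.svd(centered, compute_uv=False)
    return bool(s[1] < tol * max(1.0, s[0]))


def initial_estimates(quadruple: np.ndarray) -> tuple[float, float, float]:
    """Direct geometric (r, p, t) estimates for four consecutive Cα atoms.

    Construction: the two second-difference vectors of the trace,
    w1 = P2 - 2 P1 + P0 and w2 = P3 - 2 P2 + P1, are perpendicular to the
    helix axis for points exactly on a helix; the axis direction is their
    normalized cross product (oriented to give a non-negative rise).  The
    points projected onto the axis-normal plane lie on a circle, recovered
    by a linear least-squares (Kåsa) fit; the radius is the mean distance
    of the projections to the circle centre, the turn angle the mean
    angular step around it, and the rise the mean axial projection of the
    three bond vectors.  Exact on ideal quadruples.

    Raises
    ------
    DegenerateQuadrupleError
        For collinear or coincident quadruples.
    """
    q = np.asarray(quadruple, dtype=float)
    if q.shape != (4, 3):
        raise ValueError("quadruple must be (4, 3)")
    bonds = np.diff(q, axis=0)
    lengths = np.linalg.norm(bonds, axis=1)
    if np.any(lengths < 1e-9):
        raise DegenerateQuadrupleError("coincident consecutive points")
    w1 = q[2] - 2.0 * q[1] + q[0]
    w2 = q[3] - 2.0 * q[2] + q[1]
    axis = np.cross(w1, w2)
    norm = np.linalg.norm(axis)
    if norm < 1e-9 * max(1.0, np.linalg.norm(w1) * np.linalg.norm(w2)):
        raise DegenerateQuadrupleError("collinear quadruple")
    axis = axis / norm
    if float(bonds.sum(axis=0) @ axis) < 0.0:
        axis = -axis
    e1 = np.cross(axis, [1.0, 0.0, 0.0])
    if np.linalg.norm(e1) < 1e-6:
        e1 = np.cross(axis, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    proj = np.stack([q @ e1, q @ e2], axis=1)
    a_mat = np.hstack([2.0 * proj, np.ones((4, 1))])
    sol, *_ = np.linalg.lstsq(a_mat, (proj**2).sum(axis=1), rcond=None)
    rel = proj - sol[:2]
    radii = np.linalg.norm(rel, axis=1)
    if np.any(radii < 1e-9):
        raise DegenerateQuadrupleError("projection collapses onto the axis")
    r = float(radii.mean())
    steps = np.abs(np.diff(np.unwrap(np.arctan2(rel[:, 1], rel[:, 0]))))
    t = math.degrees(float(steps.mean()))
    if t < 1e-9 or t >= 360.0:
        raise DegenerateQuadrupleError("degenerate turn angle")
    p = float(np.mean(bonds @ axis))
    return r, max(p, 0.0), t


def _canonical_points(r: np.ndarray, p: np.ndarray, t_rad: np.ndarray) -> np.ndarray:
    """Canonical right-handed curve points at u = 0..3 for each grid cell.

    Shapes: inputs (G,), output (G, 4, 3).
    """
    u = np.arange(4.0)
    theta = t_rad[:, None] * u
    pts = np.empty((len(r), 4, 3))
    pts[:, :, 0] = r[:, None] * np.sin(theta)
    pts[:, :, 1] = r[:, None] * np.cos(theta)
    pts[:, :, 2] = p[:, None] * u
    return pts


def fit_quadruple(
    quadruple: np.ndarray,
    grid: GridSpec | None = None,
    start_index: int = 0,
    handedness: str = "right",
) -> QuadrupleFit:
    """Exhaustive grid-search best fit of a helical curve to one quadruple.

    Enumerates r and p on the grid centred at the initial estimates; per
    valid cell the turn angle comes from the chord identity using the mean
    of the three consecutive Cα distances, and the candidate curve's four
    index points are superposed onto the quadruple by Kabsch.  The cell
    minimizing the superposition RMSD wins (ties broken by scan order:
    ascending r, then p).  The reported Δ is the closest-point RMSD of the
    four atoms to the winning curve.

    Returns an invalid fit (``valid=False``) when the quadruple is
    degenerate or every grid cell violates ``d > p``.
    """
    grid = grid or GridSpec()
    q = np.asarray(quadruple, dtype=float)
    try:
        r_m, p_m, _ = initial_estimates(q)
    except DegenerateQuadrupleError:
        return QuadrupleFit(start_index=start_index, valid=False, handedness=handedness)

    d = float(np.linalg.norm(np.diff(q, axis=0), axis=1).mean())

    k_r = int(round(grid.d_r / grid.step))
    k_p = int(round(grid.d_p / grid.step))
    r_vals = r_m + grid.step * np.arange(-k_r, k_r + 1)
    p_vals = p_m + grid.step * np.arange(-k_p, k_p + 1)
    rr, pp = np.meshgrid(r_vals, p_vals, indexing="ij")  # scan order: r, then p
    rr = rr.ravel()
    pp = pp.ravel()

    valid = (rr > 1e-6) & (pp >= 0.0) & (d > pp)
    with np.errstate(invalid="ignore"):
        arg = np.where(valid, 0.5 * np.sqrt(np.maximum(d * d - pp * pp, 0.0)) / rr, 2.0)
    valid &= arg <= 1.0
    if not valid.any():
        return QuadrupleFit(start_index=start_index, valid=False, handedness=handedness)

    rr = rr[valid]
    pp = pp[valid]
    t_rad = 2.0 * np.arcsin(arg[valid])

    cand = _canonical_points(rr, pp, t_rad)  # (G, 4, 3)
    cand_c = cand - cand.mean(axis=1, keepdims=True)
    tc = q.mean(axis=0)
    y = q - tc
    h = np.einsum("gij,ik->gjk", cand_c, y)  # (G, 3, 3) cross-covariance
    s = np.linalg.svd(h, compute_uv=False)
    sign = np.where(np.linalg.det(h) < 0.0, -1.0, 1.0)
    e0 = (cand_c * cand_c).sum(axis=(1, 2)) + float((y * y).sum())
    msd = np.maximum(e0 - 2.0 * (s[:, 0] + s[:, 1] + sign * s[:, 2]), 0.0) / 4.0
    best = int(np.argmin(msd))

    r_b, p_b, t_b = float(rr[best]), float(pp[best]), math.degrees(float(t_rad[best]))
    rot, trans, pair_rmsd = kabsch_superpose(cand[best], q)
    curve = HelicalCurve(radius=r_b, rise=p_b, turn=t_b, origin=trans, rotation=rot)
    dists = np.array(
        [
            closest_point_distance(curve, q[j], (j - 1.0, j + 1.0))
            for j in range(4)
        ]
    )
    delta = math.sqrt(float((dists**2).mean()))
    axis = curve.axis
    if float(axis @ (q[3] - q[0])) < 0.0:
        axis = -axis
    return QuadrupleFit(
        start_index=start_index,
        valid=True,
        r=r_b,
        p=p_b,
        t=t_b,
        delta=delta,
        rotation=rot,
        origin=np.asarray(trans, dtype=float),
        axis=axis,
        handedness=handedness,
        pair_rmsd=pair_rmsd,
        point_distances=dists,
    )


def axis_angle(prev_axis: np.ndarray, cur_axis: np.ndarray) -> float:
    """Angle between two unit helix axes, degrees in [0, 180]."""
    prev_axis = np.asarray(prev_axis, dtype=float)
    cur_axis = np.asarray(cur_axis, dtype=float)
    np_, nc = np.linalg.norm(prev_axis), np.linalg.norm(cur_axis)
    if np_ < 1e-12 or nc < 1e-12:
        raise ValueError("axis vectors must be non-zero")
    cosang = float(np.clip(prev_axis @ cur_axis / (np_ * nc), -1.0, 1.0))
    return math.degrees(math.acos(cosang))


def delta_rmsd(fits: list[QuadrupleFit], coords: np.ndarray, i: int) -> float:
    """Seven-residue pooled RMSD δ for residue ``i``.

    Pools the closest-point distances of all member atoms of the up-to-four
    valid quadruple curves starting at i-2, i-1, i, i+1 (each contributing
    its four atoms) and returns their RMS.  ``inf`` when no covering
    quadruple exists, which fails every δ threshold test.
    """
    sq: list[float] = []
    for k in range(i - 2, i + 2):
        if 0 <= k < len(fits) and fits[k].valid and fits[k].point_distances is not None:
            sq.extend(float(x) ** 2 for x in fits[k].point_distances)
    if not sq:
        return math.inf
    return math.sqrt(sum(sq) / len(sq))


def profile_segment(
    coords: np.ndarray,
    grid: GridSpec | None = None,
    handedness: str = "right",
) -> list[ResidueProfile]:
    """Sliding-window fits and per-residue (a, Δ, δ) for one chain segment.

    One quadruple fit per start index 0..n-4.  The axis angle of the first
    profiled residue is 0.0 (it has no predecessor axis); subsequent angles
    are between consecutive fitted axes.  Left-handed profiling mirrors the
    coordinates first and fits the standard curve to the mirror image.

    Segments shorter than 4 residues yield an empty profile.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if n < 4:
        return []
    grid = grid or GridSpec()
    work = mirror_coordinates(coords) if handedness == "left" else coords

    fits = [
        fit_quadruple(work[i : i + 4], grid, start_index=i, handedness=handedness)
        for i in range(n - 3)
    ]
    profiles = [ResidueProfile(index=i) for i in range(n)]
    for i, fit in enumerate(fits):
        prof = profiles[i]
        prof.fit = fit if fit.valid else None
        if fit.valid:
            prof.delta = fit.delta
            if i == 0 or not fits[i - 1].valid:
                prof.a = 0.0  # first profiled residue: no predecessor axis
            else:
                prof.a = axis_angle(fits[i - 1].axis, fit.axis)
    for i in range(n):
        profiles[i].small_delta = delta_rmsd(fits, work, i)
    return profiles
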