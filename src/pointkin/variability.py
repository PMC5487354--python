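"""Spatial trajectory variability via perpendicular-plane cross-sections.

The spatially averaged trajectory is resampled at 300 points equidistant
in arclength.  At each point, every individual trajectory is intersected
with the plane perpendicular to the mean's instantaneous movement
direction, yielding 300 two-dimensional point clouds (oriented in 3D).
Each cloud's 95% confidence ellipse — eigen-decomposition of the 2D
covariance, scaled by the chi-square(2 df) quantile — summarizes spatial
variability as an area (cm^2), as a function of progression along the
movement.

Averaging trajectories while ignoring temporal biases has no closed form;
the fixed-point scheme here alternates between resampling the mean at
equidistant arclength and replacing each mean point by the centroid of the
cross-section it defines, until the mean moves less than 0.1 mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

N_SECTIONS = 300


class InsufficientDataError(ValueError):
    pass


def _as_points(traj) -> np.ndarray:
    """Accept (n, 3) arrays or objects with a ``position`` attribute."""
    p = getattr(traj, "position", traj)
    p = np.asarray(p, dtype=float)
    if p.ndim != 2 or p.shape[1] != 3 or p.shape[0] < 2:
        raise ValueError("trajectory must be an (n>=2, 3) point array")
    return p


def resample_arclength(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a polyline at ``n`` points equidistant in arclength."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate(([0.0], np.cumsum(seg)))
    grid = np.linspace(0.0, s[-1], n)
    return np.column_stack([np.interp(grid, s, points[:, k]) for k in range(3)])


def _tangents(points: np.ndarray) -> np.ndarray:
    t = np.gradient(points, axis=0)
    norms = np.linalg.norm(t, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return t / norms


@dataclass
class MeanTrajectory:
    """Spatially averaged trajectory at equidistant-arclength samples."""

    points: np.ndarray  # (n_sections, 3) meters
    tangents: np.ndarray  # unit average movement direction per point
    converged: bool
    n_iterations: int


@dataclass
class CrossSection:
    """One perpendicular-plane section of the trajectory bundle.

    ``points2d`` holds each contributing trajectory's plane crossing in the
    section's fixed orthonormal 2D basis (meters); trajectories with no
    crossing are counted in ``n_missing``.
    """

    index: int
    center: np.ndarray
    normal: np.ndarray
    basis: np.ndarray  # (2, 3): rows e1, e2
    points2d: np.ndarray  # (n_crossing, 2)
    n_missing: int

    @property
    def centroid3d(self) -> np.ndarray:
        if len(self.points2d) == 0:
            return self.center
        c = self.points2d.mean(axis=0)
        return self.center + c[0] * self.basis[0] + c[1] * self.basis[1]


def _plane_basis(normal: np.ndarray) -> np.ndarray:
    """Fixed orthonormal 2D basis: global x projected into the plane
    (fallback: y when the tangent is parallel to x), then the cross
    product — keeps orientations comparable across sections."""
    for ref in (np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0])):
        e1 = ref - np.dot(ref, normal) * normal
        n1 = np.linalg.norm(e1)
        if n1 > 1e-8:
            e1 /= n1
            return np.vstack([e1, np.cross(normal, e1)])
    raise ValueError("degenerate tangent")


def _crossing(points: np.ndarray, center: np.ndarray, normal: np.ndarray,
              target_fraction: float, multiple: str = "nearest") -> np.ndarray | None:
    """Linear intersection of a polyline with a plane.

    Sign changes of the signed plane distance between consecutive samples
    are linearly interpolated.  With several crossings, ``nearest`` picks
    the one whose sample-index fraction is closest to the section's
    arclength fraction; ``first`` picks the earliest.
    """
    d = (points - center) @ normal
    sign_change = np.flatnonzero(d[:-1] * d[1:] <= 0)
    sign_change = sign_change[(d[sign_change] != 0) | (d[sign_change + 1] != 0)]
    if sign_change.size == 0:
        exact = np.flatnonzero(d == 0)
        if exact.size:
            return points[exact[0]]
        return None
    if multiple == "nearest" and sign_change.size > 1:
        frac = sign_change / max(1, len(points) - 1)
        i = sign_change[np.argmin(np.abs(frac - target_fraction))]
    else:
        i = sign_change[0]
    w = d[i] / (d[i] - d[i + 1])
    return points[i] + w * (points[i + 1] - points[i])


def plane_cross_sections(
    mean: MeanTrajectory,
    trajectories,
    multiple_crossings: str = "nearest",
) -> list[CrossSection]:
    """Intersect every trajectory with the perpendicular plane at each of
    the mean trajectory's points."""
    polylines = [_as_points(t) for t in trajectories]
    n_sections = len(mean.points)
    sections = []
    for k in range(n_sections):
        center, normal = mean.points[k], mean.tangents[k]
        basis = _plane_basis(normal)
        pts, missing = [], 0
        frac = k / max(1, n_sections - 1)
        for poly in polylines:
            p = _crossing(poly, center, normal, frac, multiple_crossings)
            if p is None:
                missing += 1
            else:
                rel = p - center
                pts.append([rel @ basis[0], rel @ basis[1]])
        sections.append(
            CrossSection(
                index=k,
                center=center,
                normal=normal,
                basis=basis,
                points2d=np.asarray(pts, dtype=float).reshape(-1, 2),
                n_missing=missing,
            )
        )
    return sections


def mean_trajectory(
    trajectories,
    n_sections: int = N_SECTIONS,
    tol: float = 1e-4,
    max_iter: int = 20,
) -> MeanTrajectory:
    """Iterative spatial average of a trajectory bundle.

    Initialized as the pointwise average of the (time-normalized) input
    trajectories, then alternates equidistant-arclength resampling with
    per-section centroid replacement until the largest pointwise move is
    below ``tol`` (meters) or ``max_iter`` iterations; non-convergence
    returns the best iterate flagged ``converged=False``.
    """
    polylines = [_as_points(t) for t in trajectories]
    if len(polylines) < 2:
        raise ValueError("need at least 2 trajectories to average")
    lengths = {p.shape[0] for p in polylines}
    if len(lengths) == 1:
        init = np.mean(np.stack(polylines), axis=0)
    else:
        init = np.mean(
            np.stack([resample_arclength(p, n_sections) for p in polylines]), axis=0
        )
    mean_pts = resample_arclength(init, n_sections)

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mt = MeanTrajectory(mean_pts, _tangents(mean_pts), False, it)
        sections = plane_cross_sections(mt, polylines)
        centroids = np.array([s.centroid3d for s in sections])
        new_pts = resample_arclength(centroids, n_sections)
        delta = float(np.max(np.linalg.norm(new_pts - mean_pts, axis=1)))
        mean_pts = new_pts
        if delta < tol:
            converged = True
            break
    return MeanTrajectory(mean_pts, _tangents(mean_pts), converged, it)


@dataclass
class ConfidenceEllipse:
    """95% (by default) confidence ellipse of a 2D point set."""

    semi_axes: tuple[float, float]  # major, minor (meters)
    axes: np.ndarray  # (2, 2) eigenvector columns, major first
    area: float  # m^2
    degenerate: bool

    @property
    def area_cm2(self) -> float:
        return self.area * 1e4

    @property
    def orientation_deg(self) -> float:
        v = self.axes[:, 0]
        return float(np.degrees(np.arctan2(v[1], v[0])) % 180.0)


def confidence_ellipse(points2d: np.ndarray, confidence: float = 0.95) -> ConfidenceEllipse:
    """Confidence ellipse via eigen-decomposition of the 2D covariance.

    Semi-axes are ``sqrt(lambda_i * q)`` with ``q`` the chi-square(2 df)
    quantile at ``confidence``; area is pi times their product.  Fewer than
    3 points raises :class:`InsufficientDataError`; a singular covariance
    yields a degenerate (zero-minor-axis) ellipse with a flag.
    """
    pts = np.asarray(points2d, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points2d must be (n, 2)")
    if pts.shape[0] < 3:
        raise InsufficientDataError("need at least 3 points for an ellipse")
    cov = np.cov(pts.T, ddof=1)
    lam, vec = np.linalg.eigh(cov)
    lam = np.clip(lam, 0.0, None)
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    q = chi2.ppf(confidence, df=2)
    a, b = np.sqrt(lam * q)
    degenerate = bool(lam[1] <= max(lam[0], 1.0) * 1e-15)
    return ConfidenceEllipse(
        semi_axes=(float(a), float(b)),
        axes=vec,
        area=float(np.pi * a * b),
        degenerate=degenerate,
    )


def section_ellipse_table(sections: list[CrossSection]) -> "pd.DataFrame":
    """Per-section summary: arclength fraction, centroid, covariance
    entries, ellipse area (cm^2) and contributing-trial count."""
    import pandas as pd

    rows = []
    n = len(sections)
    for s in sections:
        rec = {
            "section": s.index,
            "arclength_fraction": s.index / max(1, n - 1),
            "cx_m": s.center[0],
            "cy_m": s.center[1],
            "cz_m": s.center[2],
            "n_trials": len(s.points2d),
            "n_missing": s.n_missing,
        }
        if len(s.points2d) >= 3:
            cov = np.cov(s.points2d.T, ddof=1)
            ell = confidence_ellipse(s.points2d)
            rec.update(
                cov11=cov[0, 0], cov12=cov[0, 1], cov22=cov[1, 1],
                area_cm2=ell.area_cm2, degenerate=ell.degenerate,
            )
        else:
            rec.update(cov11=np.nan, cov12=np.nan, cov22=np.nan,
                       area_cm2=np.nan, degenerate=True)
        rows.append(rec)
    return pd.DataFrame(rows)
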