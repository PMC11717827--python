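"""Region-restricted rigid surface registration (trimmed ICP).

Every "superimposition" in the fusion workflows is one call to
:func:`icp_register`: iterative closest point between the vertices of a
named matching region on the source mesh and the vertices of a matching
region on the target mesh, with the worst fraction of correspondences
trimmed each iteration.  Trimming matters here because partial overlap is
the norm — retractor-deformed cheeks, a CBCT skin surface with a truncated
forehead, a tracer only partly visible in the facial photo.

The default error metric is point-to-plane (faster convergence on smooth
facial surfaces); point-to-point is available for sparse regions such as
the anterior tooth crowns.  :func:`coarse_align` provides the initial
guess by matching region centroids and principal axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .mesh_core import TriMesh
from .rigid_geometry import RigidTransform, compose

__all__ = [
    "IcpParams",
    "RegistrationResult",
    "RegistrationFailureError",
    "icp_register",
    "coarse_align",
]


class RegistrationFailureError(RuntimeError):
    """No usable correspondences — never silently returns identity."""


@dataclass
class IcpParams:
    """Tunable knobs of the trimmed-ICP engine.

    trim_fraction discards the worst correspondences each iteration (by
    distance); max_corr_dist (mm) rejects matches outright.  subsample, if
    set, caps the number of source points used, drawn with `seed`.
    """

    max_iterations: int = 100
    convergence_tol: float = 1e-6  # mm change in trimmed RMS
    trim_fraction: float = 0.1
    max_corr_dist: float = 10.0
    metric: str = "point_to_plane"
    seed: int = 0
    subsample: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.trim_fraction < 0.5):
            raise ValueError("trim_fraction must be in [0, 0.5)")
        if self.max_corr_dist <= 0:
            raise ValueError("max_corr_dist must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.metric not in ("point_to_point", "point_to_plane"):
            raise ValueError(f"unknown metric {self.metric!r}")


@dataclass
class RegistrationResult:
    """Outcome of one superimposition step."""

    transform: RigidTransform
    rms_residual: float
    n_correspondences: int
    n_iterations: int
    converged: bool
    rms_history: list[float] = field(default_factory=list)


def _region_points(mesh: TriMesh, region: str | list[str] | None) -> np.ndarray:
    if region is None:
        return np.arange(mesh.n_vertices)
    names = [region] if isinstance(region, str) else list(region)
    idx = np.unique(np.concatenate([mesh.region_index(n) for n in names]))
    return idx


def _vertex_normals(mesh: TriMesh) -> np.ndarray:
    """Area-weighted vertex normals; zero-norm vertices get an arbitrary unit."""
    v, f = mesh.vertices, mesh.faces
    fn = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    vn = np.zeros_like(v)
    for k in range(3):
        np.add.at(vn, f[:, k], fn)
    norm = np.linalg.norm(vn, axis=1)
    bad = norm < 1e-12
    vn[bad] = (0.0, 0.0, 1.0)
    norm[bad] = 1.0
    return vn / norm[:, None]


def _kabsch(p: np.ndarray, q: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform taking points p onto q."""
    cp, cq = p.mean(axis=0), q.mean(axis=0)
    H = (p - cp).T @ (q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return RigidTransform(R, cq - R @ cp)


def _point_to_plane_step(p: np.ndarray, q: np.ndarray, n: np.ndarray) -> RigidTransform:
    """One linearised point-to-plane solve; exact rotation applied from the
    small-angle solution."""
    b = ((q - p) * n).sum(axis=1)
    A = np.hstack([np.cross(p, n), n])
    x, *_ = np.linalg.lstsq(A, b, rcond=None)
    omega, t = x[:3], x[3:]
    R = Rotation.from_rotvec(omega).as_matrix()
    return RigidTransform(R, t)


def icp_register(
    source: TriMesh,
    target: TriMesh,
    source_region: str | list[str] | None = None,
    target_region: str | list[str] | None = None,
    init: RigidTransform | None = None,
    params: IcpParams | None = None,
) -> RegistrationResult:
    """Rigidly register the source region onto the target region.

    The result's transform maps source-frame coordinates into the target
    frame.  Deterministic for identical inputs and seed.  The initial guess
    must be a coarse pre-alignment (within roughly 10 mm / 10 deg for the
    default parameters); use :func:`coarse_align` to obtain one.
    """
    params = params or IcpParams()
    init = init or RigidTransform.identity()

    src_idx = _region_points(source, source_region)
    tgt_idx = _region_points(target, target_region)
    src_pts = source.vertices[src_idx]
    tgt_pts = target.vertices[tgt_idx]
    if params.subsample is not None and len(src_pts) > params.subsample:
        rng = np.random.default_rng(params.seed)
        src_pts = src_pts[rng.choice(len(src_pts), params.subsample, replace=False)]
    tgt_normals = _vertex_normals(target)[tgt_idx]
    tree = cKDTree(tgt_pts)

    current = init
    best = init
    best_rms = np.inf
    history: list[float] = []
    converged = False
    n_corr = 0
    iterations = 0

    for iterations in range(1, params.max_iterations + 1):
        p = current.apply(src_pts)
        dist, j = tree.query(p)
        keep = dist <= params.max_corr_dist
        if not keep.any():
            raise RegistrationFailureError(
                f"no correspondences within {params.max_corr_dist} mm "
                f"(closest was {dist.min():.2f} mm); improve the initial alignment"
            )
        if params.trim_fraction > 0:
            n_keep = max(3, int(np.ceil(keep.sum() * (1 - params.trim_fraction))))
            order = np.argsort(dist)
            kept = order[keep[order]][:n_keep]
        else:
            kept = np.flatnonzero(keep)
        n_corr = len(kept)
        pk, qk = p[kept], tgt_pts[j[kept]]
        rms = float(np.sqrt(np.mean(dist[kept] ** 2)))
        if rms < best_rms:
            best_rms, best = rms, current
        history.append(rms)
        if len(history) >= 2 and abs(history[-2] - history[-1]) < params.convergence_tol:
            converged = True
            break
        if params.metric == "point_to_plane":
            step = _point_to_plane_step(pk, qk, tgt_normals[j[kept]])
        else:
            step = _kabsch(pk, qk)
        current = compose(step, current)

    # final residual of the best transform
    p = best.apply(src_pts)
    dist, _ = tree.query(p)
    keep = dist <= params.max_corr_dist
    if params.trim_fraction > 0 and keep.sum() > 3:
        n_keep = max(3, int(np.ceil(keep.sum() * (1 - params.trim_fraction))))
        dist = np.sort(dist[keep])[:n_keep]
    else:
        dist = dist[keep]
    final_rms = float(np.sqrt(np.mean(dist**2)))

    return RegistrationResult(
        transform=best,
        rms_residual=final_rms,
        n_correspondences=n_corr,
        n_iterations=iterations,
        converged=converged,
        rms_history=history,
    )


def coarse_align(
    source: TriMesh,
    target: TriMesh,
    source_region: str | list[str] | None = None,
    target_region: str | list[str] | None = None,
) -> RigidTransform:
    """Initial alignment from region centroids and principal axes.

    Principal-axis sign ambiguity (four proper-rotation candidates) is
    resolved by picking the candidate with the smallest median
    nearest-neighbour distance.  Raises for degenerate (near-collinear)
    regions, where the axes are not well defined.
    """
    sp = source.vertices[_region_points(source, source_region)]
    tp = target.vertices[_region_points(target, target_region)]
    cs, ct = sp.mean(axis=0), tp.mean(axis=0)

    def _axes(pts: np.ndarray, c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        cov = np.cov((pts - c).T)
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        if np.linalg.det(v) < 0:  # make the axis triad right-handed
            v[:, 2] = -v[:, 2]
        return w, v

    ws, Vs = _axes(sp, cs)
    wt, Vt = _axes(tp, ct)
    if ws[1] < 1e-6 * max(ws[0], 1e-12) or wt[1] < 1e-6 * max(wt[0], 1e-12):
        raise ValueError(
            "region is degenerate (near-collinear); supply a manual initial transform"
        )

    tree = cKDTree(tp)
    best: RigidTransform | None = None
    best_score = np.inf
    # flip pairs of axes to keep det = +1
    for sx, sy in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
        S = np.diag([sx, sy, sx * sy])
        R = Vt @ S @ Vs.T
        if np.linalg.det(R) < 0:  # pragma: no cover - S construction keeps det>0
            continue
        cand = RigidTransform(R, ct - R @ cs)
        d, _ = tree.query(cand.apply(sp))
        score = float(np.median(d))
        if score < best_score:
            best_score, best = score, cand
    assert best is not None
    return best
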