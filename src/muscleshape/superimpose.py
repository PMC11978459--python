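"""Rigid and similarity superimposition of muscle surfaces.

Two layers: the closed-form weighted Kabsch/Umeyama solution for point sets
with known correspondence, and iterative closest point (ICP) for surfaces
without correspondence. ICP here is initialized by principal-axes pose
normalization — muscles are strongly anisotropic, so aligning the long axis
first makes the subsequent local refinement reliable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .mesh_core import SurfaceMesh, rms_size

log = logging.getLogger(__name__)


@dataclass
class RigidTransform:
    """Similarity transform ``x -> scale * rotation @ x + translation``.

    ``scale`` is exactly 1 for pure rigid transforms. The rotation is a
    proper rotation (orthonormal, determinant +1); reflections are never
    produced by the solvers in this module.
    """

    rotation: np.ndarray
    translation: np.ndarray
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=np.float64)
        self.translation = np.asarray(self.translation, dtype=np.float64)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        r = self.rotation
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(r) < 0:
            raise ValueError("rotation has negative determinant (reflection)")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3), 1.0)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.scale * points @ self.rotation.T + self.translation

    def apply_mesh(self, mesh: SurfaceMesh) -> SurfaceMesh:
        return mesh.with_vertices(self.apply(mesh.vertices))

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.scale * self.rotation @ other.translation + self.translation,
            self.scale * other.scale,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation / self.scale,
                              1.0 / self.scale)

    def rotation_angle(self) -> float:
        """Rotation magnitude in radians."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.arccos(np.clip(c, -1.0, 1.0)))


def kabsch(P: np.ndarray, Q: np.ndarray, weights: np.ndarray | None = None,
           allow_scale: bool = False) -> RigidTransform:
    """Least-squares transform taking points ``P`` onto ``Q``.

    Minimizes ``sum_i w_i || s R p_i + t - q_i ||^2`` over proper rotations
    R (reflections excluded by the determinant-sign correction), translation
    t and, when ``allow_scale``, a uniform scale s.
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("P and Q must be matching (n, 3) arrays")
    n = len(P)
    if n < 3:
        raise ValueError("at least 3 point pairs required")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, float)
        if w.shape != (n,) or np.any(w < 0):
            raise ValueError("weights must be n nonnegative reals")
        total = w.sum()
        if total <= 0:
            raise ValueError("weights must sum to a positive value")
        w = w / total
    pbar = w @ P
    qbar = w @ Q
    Pc = P - pbar
    Qc = Q - qbar
    H = (Pc * w[:, None]).T @ Qc
    U, S, Vt = np.linalg.svd(H)
    # degenerate (collinear) configurations leave the rotation underdetermined
    if S[1] <= 1e-12 * max(S[0], 1.0):
        raise ValueError("degenerate (collinear or coincident) point set")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    if allow_scale:
        var_p = float(np.sum(w * np.sum(Pc ** 2, axis=1)))
        s = float((S * np.diag(D)).sum() / var_p)
    else:
        s = 1.0
    t = qbar - s * R @ pbar
    return RigidTransform(R, t, s)


def _closest_on_triangles(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point on triangle ``tri[i]`` to ``points[i]`` (vectorized).

    Standard barycentric-region clamp; ``tri`` has shape (n, 3, 3).
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    ap = points - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = points - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = points - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(points)
    done = np.zeros(len(points), dtype=bool)

    m = (d1 <= 0) & (d2 <= 0)                      # vertex a
    out[m] = a[m]; done |= m
    m = (~done) & (d3 >= 0) & (d4 <= d3)           # vertex b
    out[m] = b[m]; done |= m
    m = (~done) & (d6 >= 0) & (d5 <= d6)           # vertex c
    out[m] = c[m]; done |= m
    vc = d1 * d4 - d3 * d2
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)    # edge ab
    with np.errstate(invalid="ignore", divide="ignore"):
        v = d1 / (d1 - d3)
    out[m] = a[m] + v[m, None] * ab[m]; done |= m
    vb = d5 * d2 - d1 * d6
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)    # edge ac
    with np.errstate(invalid="ignore", divide="ignore"):
        w = d2 / (d2 - d6)
    out[m] = a[m] + w[m, None] * ac[m]; done |= m
    va = d3 * d6 - d5 * d4
    m = (~done) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)   # edge bc
    with np.errstate(invalid="ignore", divide="ignore"):
        w = (d4 - d3) / ((d4 - d3) + (d5 - d6))
    out[m] = b[m] + w[m, None] * (c[m] - b[m]); done |= m
    m = ~done                                      # interior
    denom = va + vb + vc
    with np.errstate(invalid="ignore", divide="ignore"):
        v = vb / denom
        w = vc / denom
    out[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]
    # degenerate (zero-area) triangles: fall back to the nearest corner
    bad = ~np.all(np.isfinite(out), axis=1)
    if np.any(bad):
        corners = tri[bad]                          # (nb, 3, 3)
        d2 = np.sum((corners - points[bad, None, :]) ** 2, axis=2)
        out[bad] = corners[np.arange(len(corners)), np.argmin(d2, axis=1)]
    return out


class SurfaceProjector:
    """Closest point on a triangulated surface, via a face-centroid KD-tree.

    Candidate faces come from the ``k`` nearest face centroids; the exact
    closest point is then computed per candidate triangle. Exact whenever
    the true nearest face is among the candidates (with the default ``k`` this
    holds for all practical purposes on well-shaped meshes).
    """

    def __init__(self, mesh: SurfaceMesh, k: int = 6) -> None:
        self.tri = mesh.vertices[mesh.faces]            # (m, 3, 3)
        self.k = min(k, len(self.tri))
        self._tree = cKDTree(self.tri.mean(axis=1))

    def project(self, points: np.ndarray) -> np.ndarray:
        _, cand = self._tree.query(points, k=self.k)
        cand = np.atleast_2d(cand)
        n, k = cand.shape
        flat_pts = np.repeat(points, k, axis=0)
        flat_tri = self.tri[cand.ravel()]
        closest = _closest_on_triangles(flat_pts, flat_tri).reshape(n, k, 3)
        d2 = np.sum((closest - points[:, None, :]) ** 2, axis=2)
        best = np.argmin(d2, axis=1)
        return closest[np.arange(n), best]


def _symmetric_metric_points(A: np.ndarray, B: np.ndarray,
                             tree_b: cKDTree | None = None) -> float:
    """Symmetric point-weighted RMS closest-point distance (see gpsa module)."""
    tree_a = cKDTree(A)
    tree_b = tree_b if tree_b is not None else cKDTree(B)
    d_ab, _ = tree_b.query(A)
    d_ba, _ = tree_a.query(B)
    return float(np.sqrt(0.5 * (np.mean(d_ab ** 2) + np.mean(d_ba ** 2))))


def icp_align(moving: SurfaceMesh, fixed: SurfaceMesh, max_iter: int = 100,
              tol: float = 1e-6, allow_scale: bool = False,
              correspondence: str = "surface",
              ) -> tuple[RigidTransform, float, int]:
    """Iterative-closest-point alignment of ``moving`` onto ``fixed``.

    Alternates closest-point correspondence with the Kabsch solution on the
    correspondences. ``correspondence="surface"`` (default) matches each
    moving vertex to its closest point on the fixed *surface*
    (point-to-triangle), which converges well below the vertex sampling
    spacing; ``"vertex"`` matches to the nearest fixed vertex, which stalls
    at a sizeable fraction of the spacing on meshes sampled at different
    densities. Iteration stops when the relative improvement of the
    correspondence RMS falls below ``tol``.

    Returns ``(transform, final_metric, n_iterations)``: the transform with
    the lowest correspondence cost observed and the symmetric Procrustes
    surface metric under it. Best-so-far tracking makes the reported result
    non-increasing in ``max_iter``.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be at least 1")
    if correspondence not in ("surface", "vertex"):
        raise ValueError(f"unknown correspondence mode {correspondence!r}")
    src = moving.vertices
    dst = fixed.vertices
    tree_fixed = cKDTree(dst)
    projector = SurfaceProjector(fixed) if correspondence == "surface" else None

    best_T = T_cur = RigidTransform.identity()
    best_cost = np.inf
    current = src
    prev_cost = np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        if projector is not None:
            targets = projector.project(current)
        else:
            _, idx = tree_fixed.query(current)
            targets = dst[idx]
        cost = float(np.sqrt(np.mean(np.sum((current - targets) ** 2,
                                            axis=1))))
        if cost < best_cost:
            best_cost = cost
            best_T = T_cur
        if cost == 0.0 or prev_cost - cost < tol * max(prev_cost, 1e-300):
            break
        prev_cost = cost
        T_cur = kabsch(src, targets, allow_scale=allow_scale)
        current = T_cur.apply(src)
    final_metric = _symmetric_metric_points(best_T.apply(src), dst, tree_fixed)
    return best_T, final_metric, n_iter


def normalize_pose(mesh: SurfaceMesh, unit_scale: bool = False,
                   ) -> tuple[SurfaceMesh, RigidTransform]:
    """Center the mesh and align its principal axes to the coordinate axes.

    The vertex covariance eigenvectors become the new axes with the long
    axis mapped to z; each axis sign is fixed by the sign of the third
    central moment along it, making the pose deterministic and (to numerical
    precision) idempotent. With ``unit_scale`` the RMS vertex radius is
    scaled to 1 — the count-invariant analog of unit centroid size, needed
    because specimens are sampled at different vertex counts. Returns the
    posed mesh and the transform that produced it.
    """
    v = mesh.vertices
    c = v.mean(axis=0)
    vc = v - c
    cov = vc.T @ vc / len(v)
    evals, evecs = np.linalg.eigh(cov)  # ascending: short, mid, long -> x, y, z
    if evals[2] > 0 and (evals[2] - evals[0]) / evals[2] < 1e-9:
        log.warning("%s: near-isotropic shape, principal axes ambiguous",
                    mesh.specimen_id)
    proj = vc @ evecs
    # mixed third-order moment E[p_j * ||p||^2]: more robust than the plain
    # coordinate skewness E[p_j^3], which vanishes for shapes whose vertex
    # positions are symmetric along an axis even when the shape is not
    # (e.g. a taper expressed in girth rather than vertex density)
    third = (proj * np.sum(proj ** 2, axis=1, keepdims=True)).mean(axis=0)
    signs = np.where(third < 0, -1.0, 1.0)
    evecs = evecs * signs
    if np.linalg.det(evecs) < 0:
        # flip the axis whose orientation is least determined
        j = int(np.argmin(np.abs(third)))
        evecs[:, j] *= -1.0
    R = evecs.T
    s = 1.0 / rms_size(mesh) if unit_scale else 1.0
    T = RigidTransform(R, -s * R @ c, s)
    return T.apply_mesh(mesh), T


def random_rigid_transform(rng: np.random.Generator,
                           max_translation: float = 20.0) -> RigidTransform:
    """Uniform random rotation (quaternion method) plus bounded translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    t = rng.uniform(-max_translation, max_translation, size=3)
    return RigidTransform(R, t, 1.0)
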