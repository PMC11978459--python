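"""Principal coordinates analysis of interspecimen shape distances.

Classical (Gower) scaling of the Procrustes surface-metric distance matrix:
double-center the squared distances, eigendecompose, and scale the
eigenvectors by the square roots of the positive eigenvalues. When the
distances are Euclidean this is exactly PCA of the generating configuration;
the surface metric need not be Euclidean, so negative eigenvalues can occur
and are dropped with their magnitude logged, following standard practice.

Also provides the model-space reconstructions used for visualisation:
theoretical shapes at extreme axis scores and the per-vertex variation
heat map between them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .gpsa import GPSAResult
from .mesh_core import SurfaceMesh

log = logging.getLogger(__name__)


@dataclass
class Ordination:
    """PCoA axes of a specimen set.

    ``scores`` has one row per specimen and one column per retained
    (positive-eigenvalue) axis; columns are centered and, by convention,
    oriented so the specimen with the largest absolute score on an axis has
    a positive score.
    """

    scores: np.ndarray
    eigenvalues: np.ndarray
    pct_variance: np.ndarray
    specimen_ids: list[str] = field(default_factory=list)
    negative_eigenvalue_mass: float = 0.0

    @property
    def axis_count(self) -> int:
        return self.scores.shape[1]


def pcoa(D: np.ndarray, ids: list[str] | None = None) -> Ordination:
    """Principal coordinates (classical scaling) of a distance matrix.

    ``B = -1/2 * J (D o D) J`` with the centering matrix
    ``J = I - (1/k) 1 1'`` is eigendecomposed; axes with eigenvalues at or
    below numerical zero are dropped. Variance percentages are shares of the
    positive-eigenvalue total.
    """
    D = np.asarray(D, dtype=np.float64)
    k = D.shape[0]
    if D.ndim != 2 or D.shape[1] != k:
        raise ValueError("D must be a square matrix")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if np.any(D < 0):
        raise ValueError("distance matrix must be nonnegative")
    if not np.allclose(np.diag(D), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    if ids is None:
        ids = [f"S{i}" for i in range(k)]

    J = np.eye(k) - np.full((k, k), 1.0 / k)
    B = -0.5 * J @ (D * D) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]

    tol = max(np.abs(evals).max(initial=0.0), 1.0e-30) * 1e-9
    pos = evals > tol
    neg_mass = float(-evals[evals < -tol].sum())
    if neg_mass > 0:
        log.info("PCoA dropped negative eigenvalue mass %.3g "
                 "(non-Euclidean distances)", neg_mass)
    evals_pos = evals[pos]
    scores = evecs[:, pos] * np.sqrt(evals_pos)
    # orient each axis: largest-|score| specimen gets a positive score
    for j in range(scores.shape[1]):
        i = int(np.argmax(np.abs(scores[:, j])))
        if scores[i, j] < 0:
            scores[:, j] = -scores[:, j]
    total = evals_pos.sum()
    pct = 100.0 * evals_pos / total if total > 0 else np.zeros(0)
    return Ordination(scores=scores, eigenvalues=evals_pos, pct_variance=pct,
                      specimen_ids=list(ids),
                      negative_eigenvalue_mass=neg_mass)


def reconstruct_shape_at_score(result: GPSAResult, ordination: Ordination,
                               axis: int, score: float) -> SurfaceMesh:
    """Theoretical shape at a chosen score along one ordination axis.

    Each mean-surface vertex moves along the per-vertex regression slope of
    the homologized coordinates on the axis scores (regression through the
    mean), scaled by the requested score. ``score = 0`` returns the mean
    surface exactly; displacements are linear in the score.
    """
    if not (0 <= axis < ordination.axis_count):
        raise ValueError(f"axis {axis} outside retained axes "
                         f"(0..{ordination.axis_count - 1})")
    s = ordination.scores[:, axis]
    ss = float(s @ s)
    if ss <= 1e-30:
        raise ValueError(f"axis {axis} has zero score variance")
    H = np.stack(result.homologized)          # (k, p, 3)
    M = H.mean(axis=0)
    beta = np.tensordot(s, H - M, axes=(0, 0)) / ss   # (p, 3)
    out = result.mean_surface.with_vertices(
        result.mean_surface.vertices + score * beta)
    out.specimen_id = f"PC{axis + 1}_score_{score:+g}"
    return out


def extreme_shapes(result: GPSAResult, ordination: Ordination, axis: int,
                   ) -> tuple[SurfaceMesh, SurfaceMesh]:
    """Shapes at the observed minimum and maximum score on an axis."""
    s = ordination.scores[:, axis]
    return (reconstruct_shape_at_score(result, ordination, axis, s.min()),
            reconstruct_shape_at_score(result, ordination, axis, s.max()))


def variation_heatmap(shape_min: SurfaceMesh, shape_max: SurfaceMesh,
                      normalize: bool = False) -> np.ndarray:
    """Per-vertex displacement magnitude between two extreme shapes.

    The scalar field rendered as the low-to-high variation colour map on the
    mean surface. With ``normalize`` the field is scaled to [0, 1] by its
    maximum (left untouched when the shapes coincide).
    """
    if shape_min.n_vertices != shape_max.n_vertices or \
            not np.array_equal(shape_min.faces, shape_max.faces):
        raise ValueError("extreme shapes must share vertex count and "
                         "connectivity")
    d = np.linalg.norm(shape_max.vertices - shape_min.vertices, axis=1)
    if normalize:
        m = d.max()
        if m > 0:
            d = d / m
    return d
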