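"""Rigid Procrustes alignment, Generalized Procrustes Alignment (GPA),
and closest-point correspondence.

Alignment is rigid only (rotation + translation, no scaling) by default,
matching the pose-removal step used before building the shape model; a
similarity mode (uniform scale) exists behind a flag.  Reflections are
excluded: det(R) = +1 is enforced via sign correction in the SVD solution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .meshkit import MeshError, Shape

__all__ = [
    "RigidTransform",
    "CorrespondenceMap",
    "procrustes_pair",
    "gpa",
    "GPAResult",
    "icp_correspondence",
]


@dataclass
class RigidTransform:
    """x -> R @ x + t, with R proper orthonormal (det = +1)."""

    rotation: np.ndarray
    translation: np.ndarray
    scale: float = 1.0

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise MeshError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise MeshError("rotation is not proper (det != +1)")
        self.rotation = R
        self.translation = t

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.scale * np.asarray(points, dtype=float) @ self.rotation.T \
            + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: x -> self(other(x))."""
        R = self.rotation @ other.rotation
        t = self.scale * self.rotation @ (other.translation * 1.0) + self.translation
        return RigidTransform(R, t, self.scale * other.scale)

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        s = 1.0 / self.scale
        return RigidTransform(Rinv, -s * Rinv @ self.translation, s)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass
class CorrespondenceMap:
    """Per-source-point nearest-target assignment."""

    target_index: np.ndarray
    distances: np.ndarray

    def __post_init__(self) -> None:
        self.target_index = np.asarray(self.target_index, dtype=np.int64).reshape(-1)
        self.distances = np.asarray(self.distances, dtype=float).reshape(-1)
        if np.any(self.distances < 0):
            raise MeshError("negative correspondence distance")

    @property
    def source_count(self) -> int:
        return self.target_index.shape[0]


def _as_points(x) -> np.ndarray:
    if isinstance(x, Shape):
        return x.points
    return np.asarray(x, dtype=float).reshape(-1, 3)


def procrustes_pair(X, Y, weights=None, allow_scale: bool = False) -> RigidTransform:
    """Least-squares rigid transform T minimising sum ||T(Y_i) - X_i||^2.

    X and Y are corresponding point sets of equal count (P >= 3,
    non-collinear).  Optional per-point ``weights`` give the weighted
    solution used inside EM registration.  With ``allow_scale`` a uniform
    scale is estimated too (similarity Procrustes); default is rigid only.
    """
    Xp, Yp = _as_points(X), _as_points(Y)
    if Xp.shape != Yp.shape:
        raise MeshError(f"point counts differ: {Xp.shape[0]} vs {Yp.shape[0]}")
    P = Xp.shape[0]
    if P < 3:
        raise MeshError("need at least 3 points")
    if weights is None:
        w = np.full(P, 1.0 / P)
    else:
        w = np.asarray(weights, dtype=float).reshape(-1)
        tot = w.sum()
        if tot <= 0:
            raise MeshError("weights sum to zero")
        w = w / tot
    mx = w @ Xp
    my = w @ Yp
    Xc = Xp - mx
    Yc = Yp - my
    H = (Yc * w[:, None]).T @ Xc  # 3x3 cross-covariance
    U, s, Vt = np.linalg.svd(H)
    # degenerate (collinear) configurations leave the rotation about the
    # line undetermined: two near-zero singular values
    smax = s[0] if s[0] > 0 else 1.0
    if np.sum(s / smax > 1e-9) < 2:
        raise MeshError("degenerate (collinear or coincident) configuration")
    D = np.eye(3)
    D[2, 2] = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ D @ U.T
    if allow_scale:
        denom = float(np.sum(w * np.sum(Yc * Yc, axis=1)))
        scale = float(np.trace(np.diag(s) @ D)) / denom
    else:
        scale = 1.0
    t = mx - scale * R @ my
    return RigidTransform(R, t, scale)


@dataclass
class GPAResult:
    aligned: list
    mean: Shape
    iterations: int
    converged: bool
    mean_movement: float


def gpa(shapes, tol: float = 1e-6, max_iter: int = 100,
        allow_scale: bool = False) -> GPAResult:
    """Generalized Procrustes Alignment of a corresponding shape family.

    Iterates align-to-reference / recompute-mean until the mean moves less
    than ``tol`` (mm RMS per point).  The iteration-0 reference is the first
    shape in input order; the mean is re-centred at the origin each
    iteration to fix the translational gauge.  Non-convergence at
    ``max_iter`` is flagged on the result, never silently dropped.
    """
    shapes = [s if isinstance(s, Shape) else Shape(np.asarray(s)) for s in shapes]
    if len(shapes) < 2:
        raise MeshError("GPA needs at least 2 shapes")
    P = shapes[0].point_count
    if any(s.point_count != P for s in shapes):
        raise MeshError("all shapes must have the same point count")

    reference = shapes[0].points - shapes[0].points.mean(axis=0)
    aligned = [s.points.copy() for s in shapes]
    prev_mean = None
    movement = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        for i, pts in enumerate(aligned):
            T = procrustes_pair(reference, pts, allow_scale=allow_scale)
            aligned[i] = T.apply(pts)
        mean = np.mean(aligned, axis=0)
        mean = mean - mean.mean(axis=0)
        if prev_mean is not None:
            movement = float(np.sqrt(np.mean(np.sum((mean - prev_mean) ** 2, axis=1))))
            if movement < tol:
                prev_mean = mean
                reference = mean
                break
        prev_mean = mean
        reference = mean
    converged = movement < tol or len(shapes) == 0
    # final pass aligns every shape to the converged mean
    aligned = [procrustes_pair(prev_mean, pts, allow_scale=allow_scale).apply(pts)
               for pts in aligned]
    return GPAResult(
        aligned=[Shape(a) for a in aligned],
        mean=Shape(prev_mean),
        iterations=it,
        converged=bool(converged),
        mean_movement=float(movement if np.isfinite(movement) else 0.0),
    )


def nearest_neighbours(source_pts: np.ndarray, target_pts: np.ndarray
                       ) -> CorrespondenceMap:
    """Nearest target point per source point via k-d tree.

    Ties at exactly equal distance resolve to the lowest target index
    (contractually identical to an exhaustive scan).
    """
    tree = cKDTree(target_pts)
    dist, idx = tree.query(source_pts, k=2 if len(target_pts) > 1 else 1)
    if dist.ndim == 2:
        # enforce the lowest-index tie-break, which cKDTree does not promise
        tie = np.isclose(dist[:, 0], dist[:, 1], rtol=0.0, atol=0.0)
        best = np.where(tie, np.minimum(idx[:, 0], idx[:, 1]), idx[:, 0])
        return CorrespondenceMap(best, dist[:, 0])
    return CorrespondenceMap(idx, dist)


def icp_correspondence(source, target, max_iter: int = 50
                       ) -> tuple[RigidTransform, CorrespondenceMap]:
    """Iterative Closest Point: alternate nearest-neighbour assignment and
    rigid Procrustes until the assignment is fixed or ``max_iter``.

    Returns the accumulated rigid transform (source -> target frame) and the
    final nearest-neighbour map under that transform.
    """
    src = _as_points(source)
    tgt = _as_points(target)
    if src.size == 0 or tgt.size == 0:
        raise MeshError("empty point set")
    T = RigidTransform.identity()
    cur = src.copy()
    prev_idx = None
    for _ in range(max_iter):
        cmap = nearest_neighbours(cur, tgt)
        if prev_idx is not None and np.array_equal(cmap.target_index, prev_idx):
            break
        prev_idx = cmap.target_index
        step = procrustes_pair(tgt[cmap.target_index], cur)
        cur = step.apply(cur)
        T = step.compose(T)
    cmap = nearest_neighbours(cur, tgt)
    return T, cmap
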