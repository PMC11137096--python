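"""GMM-based point-set registration (coherent point drift family) with the
morphing workflow used to fit a hexahedral template to target surfaces.

The moving template Y is treated as the centroids of a Gaussian mixture
fitted to the fixed target X.  The maximum-a-posteriori transform

    T(y) = R (y + v(y)) + t,        v = G W

combines a rigid part (R, t) with a motion-coherent displacement field: G
is a Gaussian kernel of width ``beta_smooth`` over the template points and
the prior penalises (lambda_deform / 2) tr(W' G W), which couples nearby
points so the field stays smooth.  EM alternates soft correspondences
(with an explicit uniform outlier class of mass ``outlier_ratio``) with
closed-form updates of the rigid part, the field and the isotropic mixture
variance sigma^2.  A deterministic EM point estimate stands in for
posterior sampling of the transform parameters; in the infinite-stiffness
limit (lambda -> inf) the field vanishes and the method degenerates to a
correspondence-weighted rigid Procrustes, which is exactly how rigid
pre-registration is run (lambda = 1e9).

The multi-layer refinement loop re-registers the previous output as the
new template until the maximum point-to-correspondence Euclidean distance
falls below a threshold (default 0.04 mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import RigidTransform, nearest_neighbours, procrustes_pair
from .meshkit import MeshError, Shape

__all__ = [
    "GMMState",
    "RegistrationParams",
    "RegistrationResult",
    "MultilayerResult",
    "gmm_density",
    "correspondence_posterior",
    "register_rigid",
    "register_nonrigid",
    "multilayer_morph",
]

RIGID_LAMBDA = 1e9  # deformation prior weight that freezes the field


@dataclass
class GMMState:
    """Isotropic Gaussian mixture: centroids mu_j, common variance sigma2,
    component weights summing with the outlier mass to one."""

    centroids: np.ndarray  # (K, 3)
    sigma2: float
    weights: np.ndarray | None = None  # (K,), defaults to uniform
    outlier_ratio: float = 0.0
    outlier_volume: float = 1.0  # bounding volume for the uniform class

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float).reshape(-1, 3)
        K = self.centroids.shape[0]
        if self.weights is None:
            self.weights = np.full(K, (1.0 - self.outlier_ratio) / K)
        else:
            self.weights = np.asarray(self.weights, dtype=float).reshape(-1)
        if np.any(self.weights < 0):
            raise MeshError("negative mixture weight")
        if not np.isclose(self.weights.sum() + self.outlier_ratio, 1.0, atol=1e-8):
            raise MeshError("mixture weights plus outlier mass must sum to 1")
        if self.sigma2 <= 0:
            raise MeshError("sigma2 must be positive")
        if not (0 <= self.outlier_ratio < 1):
            raise MeshError("outlier_ratio must be in [0, 1)")

    @property
    def K(self) -> int:
        return self.centroids.shape[0]


@dataclass
class RegistrationParams:
    """Registration tuning knobs.

    Defaults mirror the morphing workflow's initial parameter set:
    deformation-magnitude weight 2, motion-smoothing weight 8, initial
    matching randomness 2, outlier ratio 0.10, at most 1000 iterations with
    tolerance 1e-15 between consecutive iterations.  The low-rank / search
    accelerations (Nystrom sample counts, neighbour-search radii, the
    k-d-tree switch and the downsample radius) are accepted for config
    compatibility but computation is exact at the problem sizes this
    package targets.
    """

    lambda_deform: float = 2.0
    beta_smooth: float = 8.0
    gamma_init: float = 2.0
    outlier_ratio: float = 0.10
    max_iter: int = 1000
    tol: float = 1e-15
    nystrom_g: int = 70
    nystrom_p: int = 300
    neighbor_scale_d: float = 7.0
    neighbor_radius_e: float = 0.20
    kdtree_switch_f: float = 0.20
    downsample_radius_r: float = 0.50

    def __post_init__(self) -> None:
        if self.lambda_deform <= 0 or self.beta_smooth <= 0 or self.tol <= 0:
            raise MeshError("lambda_deform, beta_smooth and tol must be positive")
        if not (0 <= self.outlier_ratio < 1):
            raise MeshError("outlier_ratio must be in [0, 1)")


@dataclass
class RegistrationResult:
    deformed_template: Shape
    displacement: np.ndarray  # (M, 3), total T(y) - y
    sigma2_trace: list
    iterations: int
    max_euclid_to_target: float
    converged: bool
    flags: list = field(default_factory=list)
    # field internals, needed to carry interior nodes with the same field
    template_points: np.ndarray | None = None  # Y0 in the pre-rigid frame
    kernel_weights: np.ndarray | None = None  # W, (M, 3)
    beta: float = 0.0
    rigid: RigidTransform | None = None
    objective_trace: list = field(default_factory=list)

    def displace(self, points: np.ndarray) -> np.ndarray:
        """Apply the fitted transform to arbitrary points (mm).

        The coherent field extrapolates through the Gaussian kernel against
        the template control points, so interior nodes are carried by the
        same smooth motion as the registered surface.
        """
        pts = np.asarray(points, dtype=float).reshape(-1, 3)
        out = pts.copy()
        if self.kernel_weights is not None and self.template_points is not None \
                and np.any(self.kernel_weights):
            G = _gauss_kernel(pts, self.template_points, self.beta)
            out = out + G @ self.kernel_weights
        if self.rigid is not None:
            out = self.rigid.apply(out)
        return out


def _reference_volume(X: np.ndarray) -> float:
    """Rotation-invariant reference volume for the uniform outlier class:
    the bounding sphere around the centroid (keeps registration exactly
    equivariant under rigid motions of both point sets)."""
    r = float(np.max(np.linalg.norm(X - X.mean(axis=0), axis=1)))
    if r <= 0:
        return 1.0
    return 4.0 / 3.0 * np.pi * r ** 3


def _gauss_kernel(A: np.ndarray, B: np.ndarray, beta: float) -> np.ndarray:
    d2 = np.sum((A[:, None, :] - B[None, :, :]) ** 2, axis=2)
    return np.exp(-d2 / (2.0 * beta * beta))


def gmm_density(point, state: GMMState) -> float:
    """Mixture density at ``point``: sum_j w_j N(point | mu_j, sigma2 I)
    plus the uniform outlier term outlier_ratio / outlier_volume."""
    p = np.asarray(point, dtype=float).reshape(3)
    d2 = np.sum((state.centroids - p) ** 2, axis=1)
    norm = (2.0 * np.pi * state.sigma2) ** -1.5
    dens = float(np.sum(state.weights * norm * np.exp(-d2 / (2.0 * state.sigma2))))
    if state.outlier_ratio > 0:
        dens += state.outlier_ratio / state.outlier_volume
    return dens


def correspondence_posterior(source_pts, target_pts, sigma2: float,
                             outlier_ratio: float = 0.0,
                             outlier_volume: float | None = None) -> np.ndarray:
    """E-step responsibilities of target points against source centroids.

    Returns an (N_target, M_source + 1) row-stochastic matrix; the last
    column is the uniform outlier class.  Computed in log space so rows
    never underflow to NaN.
    """
    Y = np.asarray(source_pts, dtype=float).reshape(-1, 3)
    X = np.asarray(target_pts, dtype=float).reshape(-1, 3)
    M, N = Y.shape[0], X.shape[0]
    if M == 0 or N == 0:
        raise MeshError("empty point set")
    d2 = np.sum((X[:, None, :] - Y[None, :, :]) ** 2, axis=2)  # (N, M)
    log_gauss = -d2 / (2.0 * sigma2) - 1.5 * np.log(2.0 * np.pi * sigma2) \
        + np.log((1.0 - outlier_ratio) / M)
    if outlier_ratio > 0:
        if outlier_volume is None:
            outlier_volume = _reference_volume(X)
        log_out = np.full((N, 1), np.log(outlier_ratio / outlier_volume))
    else:
        log_out = np.full((N, 1), -np.inf)
    logs = np.concatenate([log_gauss, log_out], axis=1)
    mx = logs.max(axis=1, keepdims=True)
    p = np.exp(logs - mx)
    return p / p.sum(axis=1, keepdims=True)


def _em_register(template: np.ndarray, target: np.ndarray,
                 params: RegistrationParams, lambda_deform: float,
                 rigid_only: bool, seed: int,
                 init_rotation: RigidTransform | None = None):
    """Shared EM loop.  Returns a RegistrationResult."""
    Y0 = np.asarray(template, dtype=float).reshape(-1, 3)
    X = np.asarray(target, dtype=float).reshape(-1, 3)
    M, N = Y0.shape[0], X.shape[0]
    if M == 0 or N == 0:
        raise MeshError("empty point set")
    omega = params.outlier_ratio
    volume = _reference_volume(X)

    R = np.eye(3)
    t = np.zeros(3)
    if init_rotation is not None:
        R = init_rotation.rotation.copy()
        t = init_rotation.translation.copy()
    W = np.zeros((M, 3))
    G = None if rigid_only else _gauss_kernel(Y0, Y0, params.beta_smooth)

    def transformed() -> np.ndarray:
        Yd = Y0 if rigid_only else Y0 + G @ W
        return Yd @ R.T + t

    T = transformed()
    base_sigma2 = float(np.sum((X[:, None, :] - T[None, :, :]) ** 2) / (3.0 * M * N))
    sigma2 = params.gamma_init * base_sigma2
    if sigma2 <= 0:
        sigma2 = 1e-6

    sigma2_trace = [sigma2]
    obj_trace: list[float] = []
    flags: list[str] = []
    prev_obj = np.inf
    it = 0
    converged = False
    xx = float(np.sum(X * X))
    for it in range(1, params.max_iter + 1):
        # E-step
        Pmat = correspondence_posterior(T, X, sigma2, omega, volume)  # (N, M+1)
        P = Pmat[:, :M].T  # (M, N)
        P1 = P.sum(axis=1)  # (M,)
        Np = float(P1.sum())
        if Np < 1e-12:
            flags.append("all_outliers")
            break
        PX = P @ X  # (M, 3)
        active = P1 > 1e-12 * Np
        xhat = np.where(active[:, None], PX / np.where(P1[:, None] > 0, P1[:, None], 1.0),
                        T)

        # M-step: rigid block (weighted Procrustes onto soft correspondences)
        Ydef = Y0 if rigid_only else Y0 + G @ W
        try:
            rt = procrustes_pair(xhat, Ydef, weights=np.maximum(P1, 0.0))
            R, t = rt.rotation, rt.translation
        except MeshError:
            flags.append("degenerate_rigid_step")
        # M-step: coherent field block, solved in the rotated template frame
        if not rigid_only:
            xhat_local = (xhat - t) @ R
            rhs = P1[:, None] * (xhat_local - Y0)
            A = P1[:, None] * G + (lambda_deform * sigma2 + 1e-12) * np.eye(M)
            W = np.linalg.solve(A, rhs)
        T = transformed()

        # sigma^2 update
        pt1 = Pmat[:, :M].sum(axis=1)  # (N,) inlier mass per target point
        err = float(np.sum(pt1 * np.sum(X * X, axis=1))
                    - 2.0 * np.sum((P @ X) * T) + np.sum(P1 * np.sum(T * T, axis=1)))
        new_sigma2 = err / (3.0 * Np)
        if not np.isfinite(new_sigma2) or new_sigma2 < 1e-12:
            flags.append("sigma2_collapse")
            sigma2 = max(new_sigma2, 1e-12)
            sigma2_trace.append(sigma2)
            converged = True
            break
        sigma2 = new_sigma2
        sigma2_trace.append(sigma2)

        # negative log-posterior (marginal NLL + coherence prior)
        obj = _neg_log_posterior(X, T, sigma2, omega, volume, lambda_deform, W, G)
        obj_trace.append(obj)
        if abs(prev_obj - obj) < params.tol * max(1.0, abs(prev_obj)):
            converged = True
            break
        prev_obj = obj

    cmap = nearest_neighbours(T, X)
    result = RegistrationResult(
        deformed_template=Shape(T),
        displacement=T - Y0,
        sigma2_trace=sigma2_trace,
        iterations=it,
        max_euclid_to_target=float(cmap.distances.max()),
        converged=converged,
        flags=flags,
        template_points=None if rigid_only else Y0.copy(),
        kernel_weights=None if rigid_only else W.copy(),
        beta=params.beta_smooth,
        rigid=RigidTransform(R, t),
        objective_trace=obj_trace,
    )
    return result


def _neg_log_posterior(X, T, sigma2, omega, volume, lam, W, G) -> float:
    M = T.shape[0]
    d2 = np.sum((X[:, None, :] - T[None, :, :]) ** 2, axis=2)
    logs = -d2 / (2.0 * sigma2) - 1.5 * np.log(2.0 * np.pi * sigma2) \
        + np.log((1.0 - omega) / M)
    if omega > 0:
        logs = np.concatenate(
            [logs, np.full((X.shape[0], 1), np.log(omega / volume))], axis=1)
    mx = logs.max(axis=1, keepdims=True)
    nll = -float(np.sum(mx[:, 0] + np.log(np.exp(logs - mx).sum(axis=1))))
    if G is not None and np.any(W):
        nll += 0.5 * lam * float(np.sum(W * (G @ W)))
    return nll


def register_rigid(template, target, params: RegistrationParams | None = None,
                   multistart: bool = True
                   ) -> tuple[RigidTransform, RegistrationResult]:
    """Rigid registration as the infinite-stiffness limit of the coherent
    model: the deformation prior is so heavy (lambda = 1e9) that the MAP
    field is rigid, i.e. correspondence-weighted Procrustes inside EM.

    A deterministic multi-start over the 24 proper rotations of the cube
    (applied about the template centroid, centroids aligned) guards
    against EM local minima from large initial misalignment; the start
    with the lowest final sigma^2 wins.
    """
    params = params or RegistrationParams()
    Y = template.points if isinstance(template, Shape) else np.asarray(template, float)
    X = target.points if isinstance(target, Shape) else np.asarray(target, float)
    if Y.size == 0 or X.size == 0:
        raise MeshError("empty point set")
    centroid = Y.mean(axis=0)
    starts = _cube_rotations() if multistart else [np.eye(3)]
    best = None
    for R0 in starts:
        init = RigidTransform(R0, X.mean(axis=0) - R0 @ centroid)
        res = _em_register(Y, X, params, RIGID_LAMBDA, rigid_only=True,
                           seed=0, init_rotation=init)
        if best is None or res.sigma2_trace[-1] < best.sigma2_trace[-1]:
            best = res
    assert best is not None
    return best.rigid, best


def _cube_rotations() -> list:
    """The 24 proper rotations of the cube (signed permutation matrices
    with determinant +1), identity first, in a fixed deterministic order."""
    from itertools import permutations, product

    mats = []
    for perm in permutations(range(3)):
        for signs in product((1.0, -1.0), repeat=3):
            R = np.zeros((3, 3))
            for row, (col, s) in enumerate(zip(perm, signs)):
                R[row, col] = s
            if np.linalg.det(R) > 0.5:
                mats.append(R)
    mats.sort(key=lambda R: -float(np.trace(R)))  # identity first
    return mats


def register_nonrigid(template, target, params: RegistrationParams | None = None,
                      seed: int = 0) -> RegistrationResult:
    """Non-rigid coherent registration of ``template`` onto ``target``.

    EM iterates until the objective change falls below ``params.tol`` or
    ``params.max_iter`` is reached; a sigma^2 collapse below 1e-12 stops
    cleanly and is flagged.  Deterministic given the seed (the current
    implementation is fully deterministic; the seed is part of the contract
    for forward compatibility of the initialisation).
    """
    params = params or RegistrationParams()
    Y = template.points if isinstance(template, Shape) else np.asarray(template, float)
    X = target.points if isinstance(target, Shape) else np.asarray(target, float)
    return _em_register(Y, X, params, params.lambda_deform, rigid_only=False,
                        seed=seed)


@dataclass
class MultilayerResult:
    """Composition of the pre-rotation, rigid pass and refinement layers."""

    layers: list  # RegistrationResult per non-rigid layer
    pre_transform: RigidTransform
    rigid_result: RegistrationResult
    final: RegistrationResult
    layers_used: int
    max_euclid_to_target: float
    converged: bool
    flags: list = field(default_factory=list)

    def displace(self, points: np.ndarray) -> np.ndarray:
        """Carry arbitrary points through the full morph chain."""
        pts = self.pre_transform.apply(np.asarray(points, dtype=float).reshape(-1, 3))
        assert self.rigid_result.rigid is not None
        pts = self.rigid_result.rigid.apply(pts)
        for layer in self.layers:
            pts = layer.displace(pts)
        return pts


def multilayer_morph(template, target, params: RegistrationParams | None = None,
                     threshold: float = 0.04, max_layers: int = 10,
                     distance: str = "max", pre_rotation_deg: float = 90.0,
                     seed: int = 0) -> tuple[MultilayerResult, int]:
    """Multi-layer refinement morph of ``template`` onto ``target``.

    Pre-steps follow the morphing workflow: the template is first rotated
    ``pre_rotation_deg`` about the y-axis (about its centroid), rigidly
    registered, then non-rigidly registered; while the per-point Euclidean
    distance to the current correspondence stays above ``threshold`` (mm),
    the previous output becomes the new template and registration repeats.
    ``distance`` selects the max (default) or mean per-point criterion.
    Exhausting ``max_layers`` or stalling (distance reduction < 1 percent
    between layers) returns a flagged, never-raised, result.
    """
    if threshold <= 0:
        raise MeshError("threshold must be positive")
    params = params or RegistrationParams()
    Y = template.points if isinstance(template, Shape) else np.asarray(template, float)
    X = target.points if isinstance(target, Shape) else np.asarray(target, float)

    a = np.radians(pre_rotation_deg)
    Ry = np.array([[np.cos(a), 0, np.sin(a)], [0, 1, 0], [-np.sin(a), 0, np.cos(a)]])
    centroid = Y.mean(axis=0)
    pre = RigidTransform(Ry, centroid - Ry @ centroid)
    cur = pre.apply(Y)

    rigid_T, rigid_res = register_rigid(cur, X, params)
    cur = rigid_T.apply(cur)

    def criterion(pts: np.ndarray) -> float:
        cmap = nearest_neighbours(pts, X)
        return float(cmap.distances.max() if distance == "max"
                     else cmap.distances.mean())

    layers: list[RegistrationResult] = []
    flags: list[str] = []
    dist = criterion(cur)
    converged = dist < threshold
    while not converged and len(layers) < max_layers:
        res = register_nonrigid(cur, X, params, seed=seed)
        layers.append(res)
        cur = res.deformed_template.points
        new_dist = criterion(cur)
        if new_dist < threshold:
            converged = True
            dist = new_dist
            break
        if dist > 0 and (dist - new_dist) < 0.01 * dist:
            flags.append("stalled")
            dist = new_dist
            break
        dist = new_dist
    if not converged and "stalled" not in flags:
        flags.append("layers_exhausted")

    final = layers[-1] if layers else rigid_res
    result = MultilayerResult(
        layers=layers,
        pre_transform=pre,
        rigid_result=rigid_res,
        final=final,
        layers_used=max(1, len(layers)),
        max_euclid_to_target=dist,
        converged=converged,
        flags=flags,
    )
    return result, result.layers_used
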