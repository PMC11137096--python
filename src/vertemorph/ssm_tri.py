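"""PCA statistical shape model (SSM) on aligned corresponding shapes.

The model is mean + modes: a shape is reconstructed as

    shape = mean + sum_i sqrt(d_i) * phi_i * w_i

with phi_i the orthonormal eigenvectors of the shape covariance, d_i the
eigenvalues (variance along each mode, mm^2) and w_i dimensionless weights
in units of standard deviations.  With n training shapes and 3P coordinates
(3P >> n), the eigenproblem is solved in the n-dimensional dual (Gram
matrix) form and the eigenvectors lifted back — mathematically identical to
decomposing the dense 3P x 3P covariance, but tractable at scale.

Model assessment follows the standard triad: compactness (cumulative
explained variance), generalization (leave-one-out reconstruction error)
and specificity (distance of random samples to the nearest training shape).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .meshkit import MeshError, Shape

__all__ = [
    "ShapeModel",
    "ModeWeights",
    "CohortGrid",
    "compute_mean",
    "compute_covariance",
    "fit_model",
    "sample_shape",
    "project_shape",
    "compactness",
    "generalization_loo",
    "specificity",
    "enumerate_cohort",
    "save_model",
    "load_model",
]


def _data_matrix(shapes) -> np.ndarray:
    shapes = [s if isinstance(s, Shape) else Shape(np.asarray(s)) for s in shapes]
    if not shapes:
        raise MeshError("empty shape list")
    P = shapes[0].point_count
    if any(s.point_count != P for s in shapes):
        raise MeshError("shapes have differing point counts")
    return np.stack([s.as_vector() for s in shapes])  # (n, 3P)


@dataclass
class ShapeModel:
    """Linear point-distribution model: mean, orthonormal modes, eigenvalues."""

    mean: np.ndarray  # (3P,)
    modes: np.ndarray  # (3P, m), orthonormal columns
    eigenvalues: np.ndarray  # (m,), descending, mm^2
    n_train: int
    total_variance: float

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).reshape(-1)
        self.modes = np.asarray(self.modes, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float).reshape(-1)
        if self.modes.shape != (self.mean.shape[0], self.eigenvalues.shape[0]):
            raise MeshError("modes matrix shape inconsistent with mean/eigenvalues")
        if np.any(np.diff(self.eigenvalues) > 1e-9):
            raise MeshError("eigenvalues must be sorted descending")
        if np.any(self.eigenvalues < -1e-9):
            raise MeshError("negative eigenvalue")

    @property
    def n_modes(self) -> int:
        return self.eigenvalues.shape[0]

    @property
    def point_count(self) -> int:
        return self.mean.shape[0] // 3

    def mean_shape(self) -> Shape:
        return Shape.from_vector(self.mean)


@dataclass
class ModeWeights:
    """Dimensionless standard-deviation multiples, one per activated mode."""

    w: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float).reshape(-1)
        if not np.all(np.isfinite(self.w)):
            raise MeshError("non-finite mode weight")

    def __len__(self) -> int:
        return self.w.shape[0]


@dataclass
class CohortGrid:
    """Odometer grid over mode weights: ``len(levels)**n_modes`` instances,
    first mode slowest.  The virtual-cohort default is 5 modes swept over
    the seven integer SD levels -3..3 (16807 instances)."""

    n_modes: int = 5
    levels: tuple = (-3, -2, -1, 0, 1, 2, 3)

    @property
    def size(self) -> int:
        return len(self.levels) ** self.n_modes


def compute_mean(shapes) -> np.ndarray:
    """Arithmetic per-coordinate mean of the family, as a 3P-vector."""
    return _data_matrix(shapes).mean(axis=0)


def compute_covariance(shapes):
    """Sample covariance of the family in dual (Gram) form.

    Returns ``(gram, centered, trace)`` where ``gram`` is the n x n matrix
    ``centered @ centered.T / (n - 1)`` whose nonzero eigenvalues equal
    those of the full 3P x 3P covariance ``centered.T @ centered / (n-1)``.
    """
    X = _data_matrix(shapes)
    n = X.shape[0]
    if n < 2:
        raise MeshError("covariance needs at least 2 shapes")
    C = X - X.mean(axis=0)
    gram = C @ C.T / (n - 1)
    return gram, C, float(np.trace(gram))


def fit_model(shapes, m: int | None = None) -> ShapeModel:
    """Fit the PCA shape model, retaining the top ``m`` modes.

    Eigenpairs come from the SVD of the centred data matrix (dual form);
    the sum of all eigenvalues equals the covariance trace.
    """
    X = _data_matrix(shapes)
    n = X.shape[0]
    if n < 2:
        raise MeshError("need at least 2 shapes to fit a model")
    max_m = n - 1
    if m is None:
        m = max_m
    if m < 1 or m > max_m:
        raise MeshError(f"m must be in [1, {max_m}] for n={n} shapes, got {m}")
    mean = X.mean(axis=0)
    C = X - mean
    # SVD of (n, 3P): right singular vectors are the covariance eigenvectors
    U, s, Vt = np.linalg.svd(C, full_matrices=False)
    eigvals = s ** 2 / (n - 1)
    total = float(np.sum(eigvals))
    return ShapeModel(mean=mean, modes=Vt[:m].T, eigenvalues=eigvals[:m],
                      n_train=n, total_variance=total)


def sample_shape(model: ShapeModel, w) -> Shape:
    """shape = mean + sum_i sqrt(d_i) * phi_i * w_i, reshaped to P x 3."""
    if isinstance(w, ModeWeights):
        w = w.w
    w = np.asarray(w, dtype=float).reshape(-1)
    if w.shape[0] != model.n_modes:
        raise MeshError(f"expected {model.n_modes} weights, got {w.shape[0]}")
    vec = model.mean + model.modes @ (np.sqrt(model.eigenvalues) * w)
    return Shape.from_vector(vec)


def project_shape(model: ShapeModel, shape) -> np.ndarray:
    """Inverse of :func:`sample_shape`: w_i = phi_i . (x - mean) / sqrt(d_i).

    Modes with (numerically) zero variance project to weight 0.
    """
    x = shape.as_vector() if isinstance(shape, Shape) else np.asarray(shape).reshape(-1)
    coeff = model.modes.T @ (x - model.mean)
    sd = np.sqrt(model.eigenvalues)
    out = np.zeros_like(coeff)
    nz = sd > 1e-12
    out[nz] = coeff[nz] / sd[nz]
    return out


def reconstruct(model: ShapeModel, shape) -> Shape:
    """Orthogonal projection of a shape onto the model subspace."""
    x = shape.as_vector() if isinstance(shape, Shape) else np.asarray(shape).reshape(-1)
    d = x - model.mean
    return Shape.from_vector(model.mean + model.modes @ (model.modes.T @ d))


def compactness(model: ShapeModel, m: int) -> float:
    """Cumulative explained-variance fraction of the first m modes."""
    if m <= 0:
        raise MeshError("m must be positive")
    if m > model.n_modes:
        raise MeshError(f"model retains only {model.n_modes} modes")
    if model.total_variance <= 0:
        return 1.0
    return float(np.sum(model.eigenvalues[:m]) / model.total_variance)


def _point_rmse(a: Shape, b: Shape) -> float:
    d = a.points - b.points
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def _point_mean_dist(a: Shape, b: Shape) -> float:
    d = a.points - b.points
    return float(np.mean(np.linalg.norm(d, axis=1)))


def generalization_loo(shapes, m: int, seed: int = 0, metric: str = "rmse",
                       n_train_subset: int | None = None):
    """Leave-one-out generalization error of an m-mode model.

    Each shape is left out once; a model fitted on the rest reconstructs it
    by orthogonal projection, and the per-point error is summarised.  The
    learning-curve variant (fit on a random subset of the remaining shapes)
    is exposed via ``n_train_subset`` with an explicit seed.

    Returns ``(mean_error, sd_error, per_fold_errors)`` in mm.
    """
    shapes = [s if isinstance(s, Shape) else Shape(np.asarray(s)) for s in shapes]
    n = len(shapes)
    if n < 3:
        raise MeshError("leave-one-out needs at least 3 shapes")
    if m > n - 2:
        raise MeshError(f"m={m} too large for leave-one-out with n={n}")
    dist = _point_rmse if metric == "rmse" else _point_mean_dist
    rng = np.random.default_rng(seed)
    errs = []
    for i in range(n):
        rest = shapes[:i] + shapes[i + 1:]
        if n_train_subset is not None:
            if not (m + 1 < n_train_subset <= len(rest)):
                raise MeshError("invalid training-subset size")
            sel = rng.choice(len(rest), size=n_train_subset, replace=False)
            rest = [rest[j] for j in sel]
        mdl = fit_model(rest, m=m)
        errs.append(dist(reconstruct(mdl, shapes[i]), shapes[i]))
    errs = np.asarray(errs)
    return float(errs.mean()), float(errs.std(ddof=1)), errs


def specificity(model: ShapeModel, training, N: int = 1000, seed: int = 0,
                metric: str = "rmse"):
    """Specificity of the model: realism of random samples.

    Draws N weight vectors, standard normal per mode truncated to [-3, 3]
    SD, generates the shapes and measures each one's distance to its most
    similar training shape.  Returns ``(mean, sd)`` in mm.
    """
    if N < 1:
        raise MeshError("N must be >= 1")
    training = [s if isinstance(s, Shape) else Shape(np.asarray(s)) for s in training]
    if not training:
        raise MeshError("empty training set")
    T = np.stack([s.as_vector() for s in training])
    P = model.point_count
    rng = np.random.default_rng(seed)
    errs = np.empty(N)
    for i in range(N):
        w = np.clip(rng.standard_normal(model.n_modes), -3.0, 3.0)
        x = model.mean + model.modes @ (np.sqrt(model.eigenvalues) * w)
        diffs = (T - x).reshape(len(training), P, 3)
        per = np.sum(diffs * diffs, axis=2)  # squared point distances
        if metric == "rmse":
            d = np.sqrt(per.mean(axis=1))
        else:
            d = np.sqrt(per).mean(axis=1)
        errs[i] = d.min()
    return float(errs.mean()), float(errs.std(ddof=1) if N > 1 else 0.0)


def enumerate_cohort(model: ShapeModel, grid: CohortGrid):
    """Yield ``(model_id, ModeWeights, Shape)`` over the full grid.

    model_id is the 1-based odometer index (first mode slowest), matching
    the convention that the ID in the annotation table is the model's name.
    """
    if grid.n_modes > model.n_modes:
        raise MeshError(f"grid wants {grid.n_modes} modes, model has {model.n_modes}")
    levels = list(grid.levels)
    L = len(levels)
    for mid in range(1, grid.size + 1):
        rem = mid - 1
        w = np.zeros(grid.n_modes)
        for k in range(grid.n_modes - 1, -1, -1):
            w[k] = levels[rem % L]
            rem //= L
        full = np.zeros(model.n_modes)
        full[:grid.n_modes] = w
        yield mid, ModeWeights(w), sample_shape(model, full)


def save_model(model: ShapeModel, path, provenance: str = "") -> None:
    """Serialize the model to a single .npz archive."""
    np.savez(path, mean=model.mean, modes=model.modes,
             eigenvalues=model.eigenvalues,
             n_train=np.array([model.n_train]),
             total_variance=np.array([model.total_variance]),
             provenance=np.array([provenance]))


def load_model(path) -> ShapeModel:
    with np.load(path, allow_pickle=False) as z:
        return ShapeModel(mean=z["mean"], modes=z["modes"],
                          eigenvalues=z["eigenvalues"],
                          n_train=int(z["n_train"][0]),
                          total_variance=float(z["total_variance"][0]))


def assessment_report(shapes, m: int, seed: int = 0, n_specificity: int = 200
                      ) -> dict:
    """Convenience bundle: fit + compactness/generalization/specificity."""
    model = fit_model(shapes, m=m)
    gen_mean, gen_sd, _ = generalization_loo(shapes, m=m, seed=seed)
    spec_mean, spec_sd = specificity(model, shapes, N=n_specificity, seed=seed)
    return {
        "n_train": model.n_train,
        "n_modes": m,
        "compactness": compactness(model, m),
        "mode_shares": [float(e / model.total_variance) for e in model.eigenvalues[:m]]
        if model.total_variance > 0 else [],
        "generalization_rmse_mm": [gen_mean, gen_sd],
        "specificity_rmse_mm": [spec_mean, spec_sd],
    }
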