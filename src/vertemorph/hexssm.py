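"""Hexahedral statistical shape model: transfer of the triangulated SSM's
deformation fields onto a hexahedral mean template, cohort sampling of
FE-ready coordinate sets, and personalization of mode weights from
sagittal-balance parameters.

The transfer copies each hexahedral node's deformation vector from the
closest point of the mean triangulated shape (after rigid alignment and
closest-point correspondence), so a sampled instance is

    shape = hexahedral_mean + DF @ b

where DF holds per-node copies of the sqrt(eigenvalue)-scaled triangulated
mode vectors and b is the vector of standard-deviation weights (-3..3 for
cohort sampling).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .align import CorrespondenceMap, icp_correspondence, nearest_neighbours
from .meshkit import FEModel, LandmarkRegistry, MeshError, Shape, \
    replace_coordinates
from .morph import RegistrationParams, register_rigid
from .ssm_tri import CohortGrid, ModeWeights, ShapeModel

__all__ = [
    "DeformationFields",
    "HexShapeModel",
    "transfer_fields",
    "sample_hex",
    "enumerate_hex_cohort",
    "personalize",
    "write_coordinates",
    "read_coordinates",
]


@dataclass
class DeformationFields:
    """Per-hex-node deformation field matrix DF (3Q x m) plus the
    hex-node -> tri-point correspondence that produced it."""

    DF: np.ndarray
    source_map: CorrespondenceMap

    def __post_init__(self) -> None:
        self.DF = np.asarray(self.DF, dtype=float)
        if self.DF.shape[0] != 3 * self.source_map.source_count:
            raise MeshError("DF row count must be 3 x mapped node count")

    @property
    def n_modes(self) -> int:
        return self.DF.shape[1]


@dataclass
class HexShapeModel:
    hex_mean: FEModel
    fields: DeformationFields

    def __post_init__(self) -> None:
        if self.fields.DF.shape[0] != 3 * self.hex_mean.node_count:
            raise MeshError("DF rows inconsistent with hex node count")

    @property
    def n_modes(self) -> int:
        return self.fields.n_modes


def transfer_fields(tri_model: ShapeModel, tri_mean: Shape, hex_mean: FEModel,
                    params: RegistrationParams | None = None,
                    rigid_align: bool = True) -> DeformationFields:
    """Build the hexahedral deformation fields from the triangulated SSM.

    The hexahedral mean is rigidly registered to the mean triangulated
    shape (infinite-stiffness registration), closest corresponding points
    are found by ICP, and each hex node's DF rows are copied verbatim from
    the sqrt(d_i)-scaled mode rows of its closest triangulated point.
    """
    if hex_mean.node_count == 0 or tri_mean.point_count == 0:
        raise MeshError("empty mesh in field transfer")
    hex_pts = hex_mean.node_coords
    if rigid_align:
        T, _ = register_rigid(hex_pts, tri_mean.points, params)
        _, cmap = icp_correspondence(T.apply(hex_pts), tri_mean.points)
    else:
        # geometry taken as-is: plain closest points
        cmap = nearest_neighbours(hex_pts, tri_mean.points)
    scaled = model_mode_matrix(tri_model)  # (3P, m)
    Q = hex_pts.shape[0]
    DF = np.empty((3 * Q, tri_model.n_modes))
    for q, p in enumerate(cmap.target_index):
        DF[3 * q: 3 * q + 3] = scaled[3 * p: 3 * p + 3]
    return DeformationFields(DF=DF, source_map=cmap)


def model_mode_matrix(model: ShapeModel) -> np.ndarray:
    """sqrt(eigenvalue)-scaled mode matrix (3P x m)."""
    return model.modes * np.sqrt(model.eigenvalues)[None, :]


def sample_hex(model: HexShapeModel, b) -> FEModel:
    """Instantiate the hexahedral model at weights b; connectivity, sets
    and ties are shared with the mean template (coordinate replacement)."""
    if isinstance(b, ModeWeights):
        b = b.w
    b = np.asarray(b, dtype=float).reshape(-1)
    if b.shape[0] != model.n_modes:
        raise MeshError(f"expected {model.n_modes} weights, got {b.shape[0]}")
    disp = (model.fields.DF @ b).reshape(-1, 3)
    return replace_coordinates(model.hex_mean,
                               model.hex_mean.node_coords + disp)


def write_coordinates(model: FEModel, path) -> None:
    """Plain whitespace-separated ``node_id x y z`` rows in template *NODE
    order, so regeneration is a pure coordinate substitution."""
    with open(path, "w") as fh:
        for nid, (x, y, z) in zip(model.node_ids, model.node_coords):
            fh.write(f"{int(nid)} {x:.9g} {y:.9g} {z:.9g}\n")


def read_coordinates(path) -> tuple[np.ndarray, np.ndarray]:
    ids, coords = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            ids.append(int(parts[0]))
            coords.append([float(v) for v in parts[1:4]])
    return np.asarray(ids, dtype=np.int64), np.asarray(coords, dtype=float)


def enumerate_hex_cohort(model: HexShapeModel, grid: CohortGrid, out_dir
                         ) -> list[dict]:
    """Write one coordinate file per grid instance plus the template INP,
    and return the manifest (model_id, weights, file name, annotation
    placeholder)."""
    from .meshkit import write_inp

    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as e:
        raise MeshError(f"output directory not writable: {e}") from None
    if grid.n_modes > model.n_modes:
        raise MeshError("grid has more modes than the model")
    write_inp(model.hex_mean, out / "Mean_Model_Template.inp")
    levels = list(grid.levels)
    L = len(levels)
    manifest = []
    for mid in range(1, grid.size + 1):
        rem = mid - 1
        w = np.zeros(model.n_modes)
        for k in range(grid.n_modes - 1, -1, -1):
            w[k] = levels[rem % L]
            rem //= L
        inst = sample_hex(model, w)
        fname = f"model_{mid:05d}.txt"
        write_coordinates(inst, out / fname)
        manifest.append({"model_id": mid,
                         "b": list(w[:grid.n_modes]),
                         "coordinates_file": fname,
                         "annotation": None})
    with open(out / "manifest.csv", "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["model_id", "b", "coordinates_file"])
        for row in manifest:
            wr.writerow([row["model_id"],
                         " ".join(str(v) for v in row["b"]),
                         row["coordinates_file"]])
    return manifest


def personalize(model: HexShapeModel, target: dict,
                landmarks: LandmarkRegistry,
                bounds: tuple[float, float] = (-3.0, 3.0),
                coarse_levels: tuple = (-3, -2, -1, 0, 1, 2, 3),
                age_category: str = "adult"):
    """Find mode weights b whose instance best matches target sagittal
    parameters (any subset of PI, PT, SS, LL, in degrees).

    Deterministic: a coarse per-mode sweep over the seven SD levels seeds a
    bounded derivative-free least-squares refinement.  Each
    parameter's squared error is normalised by that parameter's range over
    the mode-1 seven-level sweep so degrees of different magnitude balance.
    Out-of-reach targets return the best effort with a positive residual.

    Returns ``(b, achieved: dict, residual: float)``.
    """
    from scipy.optimize import least_squares

    from .metrics import measure_spinopelvic

    keys = [k for k in ("PI", "PT", "SS", "LL") if k in target]
    if not keys:
        raise MeshError("target must contain at least one of PI/PT/SS/LL")
    for k in keys:
        if not np.isfinite(target[k]):
            raise MeshError(f"target {k} is not finite")
    m = model.n_modes

    def measure(b) -> dict:
        inst = sample_hex(model, b)
        p = measure_spinopelvic(inst, landmarks)
        return {"PI": p.pi, "PT": p.pt, "SS": p.ss, "LL": p.ll}

    # normalisation: parameter spread across the 7-level mode-1 sweep
    spread = {k: [] for k in keys}
    for lev in coarse_levels:
        b = np.zeros(m)
        b[0] = lev
        vals = measure(b)
        for k in keys:
            spread[k].append(vals[k])
    norm = {k: max(max(s) - min(s), 1.0) for k, s in spread.items()}

    def residuals(b) -> np.ndarray:
        vals = measure(np.clip(b, bounds[0], bounds[1]))
        return np.array([(vals[k] - target[k]) / norm[k] for k in keys])

    def objective(b) -> float:
        return float(np.sum(residuals(b) ** 2))

    # coarse seed: greedy odometer, one mode at a time (deterministic)
    best_b = np.zeros(m)
    for mode in range(m):
        best_val = None
        best_lev = 0.0
        for lev in coarse_levels:
            trial = best_b.copy()
            trial[mode] = lev
            v = objective(trial)
            if best_val is None or v < best_val - 1e-12:
                best_val = v
                best_lev = lev
        best_b[mode] = best_lev

    res = least_squares(residuals, best_b, bounds=(bounds[0], bounds[1]),
                        diff_step=1e-4, xtol=1e-12, ftol=1e-12, gtol=1e-12)
    b = np.clip(res.x, bounds[0], bounds[1])
    # never worse than the mean
    if objective(b) > objective(np.zeros(m)):
        b = np.zeros(m)
    achieved = measure(b)
    residual = float(np.sqrt(sum(((achieved[k] - target[k]) / norm[k]) ** 2
                                 for k in keys)))
    return b, achieved, residual
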