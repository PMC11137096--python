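"""Hexahedral/quad mesh-quality validation and clinical annotation.

Quality side: Gauss-point Jacobian determinants of trilinear (hex8) and
serendipity quadratic (hex20) bricks, Jacobian ratio (min/max determinant),
aspect ratio and quad corner angles, with summary percentages in the style
of an FE preprocessor check.  An element is an *error* (invalid, unusable
for FE analysis) when any integration-point Jacobian determinant is
non-positive; a *warning* is a valid element with Jacobian ratio < 0.30,
aspect ratio > 10, or a quad corner angle > 160 degrees.

Clinical side: spinopelvic sagittal-balance parameters measured from named
landmarks (coordinate convention: x lateral, y posterior->anterior,
z cranial; the sagittal plane is y-z), the Global Alignment and Proportion
(GAP) score, deformity classification and the cohort inclusion filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .meshkit import FEModel, LandmarkRegistry, MeshError, Shape

__all__ = [
    "QualityReport",
    "SpinoPelvicParams",
    "jacobian_ratio",
    "aspect_ratio",
    "max_quad_angle",
    "validate_mesh",
    "measure_spinopelvic",
    "gap_score",
    "GAP_SCHEME",
    "ideal_sacral_slope",
    "ideal_lumbar_lordosis",
    "ideal_global_tilt",
    "classify_deformity",
    "inclusion_filter",
]


# --------------------------------------------------------------------------
# Element quality
# --------------------------------------------------------------------------

# hex8 natural coordinates, Abaqus node order
_HEX8_XI = np.array([
    [-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
    [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1],
], dtype=float)

# hex20 midside nodes (Abaqus order 9..20): bottom ring, top ring, verticals
_HEX20_MID = np.array([
    [0, -1, -1], [1, 0, -1], [0, 1, -1], [-1, 0, -1],
    [0, -1, 1], [1, 0, 1], [0, 1, 1], [-1, 0, 1],
    [-1, -1, 0], [1, -1, 0], [1, 1, 0], [-1, 1, 0],
], dtype=float)


def _hex8_dN(xi: np.ndarray) -> np.ndarray:
    """Derivatives dN_i/d(xi, eta, zeta) for the trilinear brick, (8, 3)."""
    g = _HEX8_XI
    x, y, z = xi
    dN = np.empty((8, 3))
    dN[:, 0] = 0.125 * g[:, 0] * (1 + g[:, 1] * y) * (1 + g[:, 2] * z)
    dN[:, 1] = 0.125 * (1 + g[:, 0] * x) * g[:, 1] * (1 + g[:, 2] * z)
    dN[:, 2] = 0.125 * (1 + g[:, 0] * x) * (1 + g[:, 1] * y) * g[:, 2]
    return dN


def _hex20_dN(xi: np.ndarray) -> np.ndarray:
    """Derivatives for the 20-node serendipity brick, (20, 3)."""
    x, y, z = xi
    dN = np.empty((20, 3))
    for i, (a, b, c) in enumerate(_HEX8_XI):
        f = a * x + b * y + c * z - 2.0
        dN[i, 0] = 0.125 * a * (1 + b * y) * (1 + c * z) * (f + (1 + a * x))
        dN[i, 1] = 0.125 * (1 + a * x) * b * (1 + c * z) * (f + (1 + b * y))
        dN[i, 2] = 0.125 * (1 + a * x) * (1 + b * y) * c * (f + (1 + c * z))
    for k, (a, b, c) in enumerate(_HEX20_MID):
        i = 8 + k
        if a == 0:
            dN[i, 0] = -0.5 * x * (1 + b * y) * (1 + c * z)
            dN[i, 1] = 0.25 * (1 - x * x) * b * (1 + c * z)
            dN[i, 2] = 0.25 * (1 - x * x) * (1 + b * y) * c
        elif b == 0:
            dN[i, 0] = 0.25 * a * (1 - y * y) * (1 + c * z)
            dN[i, 1] = -0.5 * y * (1 + a * x) * (1 + c * z)
            dN[i, 2] = 0.25 * (1 + a * x) * (1 - y * y) * c
        else:
            dN[i, 0] = 0.25 * a * (1 + b * y) * (1 - z * z)
            dN[i, 1] = 0.25 * (1 + a * x) * b * (1 - z * z)
            dN[i, 2] = -0.5 * z * (1 + a * x) * (1 + b * y)
    return dN


def _gauss_points(kind: str) -> np.ndarray:
    if kind == "hex8":
        g = 1.0 / math.sqrt(3.0)
        pts = [-g, g]
    elif kind == "hex20":
        g = math.sqrt(3.0 / 5.0)
        pts = [-g, 0.0, g]
    else:
        raise MeshError(f"no Gauss rule for kind {kind!r}")
    return np.array([[a, b, c] for a in pts for b in pts for c in pts])


def jacobian_determinants(coords: np.ndarray, kind: str = "hex8") -> np.ndarray:
    """Jacobian determinants of the isoparametric map at the element's
    Gauss points (8 for hex8, 27 for hex20)."""
    coords = np.asarray(coords, dtype=float)
    dN_fn = _hex8_dN if kind == "hex8" else _hex20_dN
    n_nodes = 8 if kind == "hex8" else 20
    if coords.shape != (n_nodes, 3):
        raise MeshError(f"{kind} expects {n_nodes} x 3 coordinates, got {coords.shape}")
    dets = []
    for xi in _gauss_points(kind):
        J = dN_fn(xi).T @ coords  # (3, 3)
        dets.append(float(np.linalg.det(J)))
    return np.asarray(dets)


def jacobian_ratio(coords: np.ndarray, kind: str = "hex8"
                   ) -> tuple[float, bool]:
    """(min/max Gauss-point Jacobian determinant, validity flag).

    The element is invalid — unusable for FE analysis — when any
    determinant is non-positive (inverted or degenerate mapping).  Ratios
    between roughly 0.30 and 0.80 are conventionally considered acceptable;
    validity itself is keyed only to the determinant sign.
    """
    dets = jacobian_determinants(coords, kind)
    valid = bool(np.all(dets > 0))
    dmax = float(np.max(np.abs(dets)))
    if dmax == 0.0:
        return 0.0, False
    ratio = float(np.min(dets) / np.max(dets)) if valid \
        else float(np.min(dets) / dmax)
    return ratio, valid


_HEX_EDGES = [(0, 1), (1, 2), (2, 3), (3, 0), (4, 5), (5, 6), (6, 7), (7, 4),
              (0, 4), (1, 5), (2, 6), (3, 7)]
_QUAD_EDGES = [(0, 1), (1, 2), (2, 3), (3, 0)]


def aspect_ratio(coords: np.ndarray, kind: str = "hex8") -> float:
    """Longest over shortest edge length; infinite for zero-length edges."""
    coords = np.asarray(coords, dtype=float)
    edges = _HEX_EDGES if kind in ("hex8", "hex20") else _QUAD_EDGES
    if kind == "hex20":
        coords = coords[:8]
    L = np.array([np.linalg.norm(coords[a] - coords[b]) for a, b in edges])
    lo = L.min()
    if lo == 0.0:
        return float("inf")
    return float(L.max() / lo)


def max_quad_angle(coords: np.ndarray) -> float:
    """Maximum interior corner angle of a quad4 face, degrees.

    Reflex corners report their true interior angle (> 180), and a
    self-intersecting (bow-tie) quad reports 180, so both are always
    flagged by the > 160 degree check.
    """
    coords = np.asarray(coords, dtype=float).reshape(4, 3)
    centroid = coords.mean(axis=0)
    rel = coords - centroid
    # best-fit plane normal (smallest principal direction)
    _, _, Vt = np.linalg.svd(rel)
    normal = Vt[2]
    uv = np.column_stack([rel @ Vt[0], rel @ Vt[1]])

    def seg_cross(p1, p2, p3, p4) -> bool:
        d1, d2 = p2 - p1, p4 - p3
        den = d1[0] * d2[1] - d1[1] * d2[0]
        if abs(den) < 1e-14:
            return False
        t = ((p3[0] - p1[0]) * d2[1] - (p3[1] - p1[1]) * d2[0]) / den
        u = ((p3[0] - p1[0]) * d1[1] - (p3[1] - p1[1]) * d1[0]) / den
        return 1e-12 < t < 1 - 1e-12 and 1e-12 < u < 1 - 1e-12

    if seg_cross(uv[0], uv[1], uv[2], uv[3]) \
            or seg_cross(uv[1], uv[2], uv[3], uv[0]):
        return 180.0

    # polygon orientation from the shoelace sign
    area2 = sum(uv[i][0] * uv[(i + 1) % 4][1] - uv[(i + 1) % 4][0] * uv[i][1]
                for i in range(4))
    orient = 1.0 if area2 >= 0 else -1.0
    angles = []
    for i in range(4):
        a = uv[(i - 1) % 4] - uv[i]
        b = uv[(i + 1) % 4] - uv[i]
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na == 0 or nb == 0:
            return 180.0
        c = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
        ang = math.degrees(math.acos(c))
        cross = b[0] * a[1] - b[1] * a[0]
        if cross * orient < 0:  # reflex corner
            ang = 360.0 - ang
        angles.append(ang)
    return float(max(angles))


@dataclass
class QualityReport:
    element_ids: np.ndarray
    kinds: list
    jacobian_ratios: np.ndarray  # NaN for non-hex elements
    valid: np.ndarray  # bool per element
    aspect_ratios: np.ndarray
    max_quad_angles: np.ndarray  # NaN for non-quad elements
    percent_errors: float
    percent_warnings: float
    percent_aspect_gt_10: float
    percent_quad_angle_gt_160: float

    def summary(self) -> dict:
        return {
            "n_elements": int(len(self.element_ids)),
            "percent_errors": self.percent_errors,
            "percent_warnings": self.percent_warnings,
            "percent_aspect_gt_10": self.percent_aspect_gt_10,
            "percent_quad_angle_gt_160": self.percent_quad_angle_gt_160,
        }


def validate_mesh(model: FEModel) -> QualityReport:
    """Per-element quality metrics plus preprocessor-style summary
    percentages.  Percentages are taken over the relevant element classes:
    errors over hexes, aspect warnings over hexes+quads, angle warnings
    over quads."""
    idx = model.node_index()
    eids, kinds, jr, valid, ar, qa = [], [], [], [], [], []
    for b in model.element_blocks:
        for eid, row in zip(b.element_ids, b.connectivity):
            coords = model.node_coords[[idx[int(n)] for n in row]]
            eids.append(int(eid))
            kinds.append(b.kind)
            if b.kind in ("hex8", "hex20"):
                r, v = jacobian_ratio(coords, b.kind)
                jr.append(r)
                valid.append(v)
                ar.append(aspect_ratio(coords, b.kind))
                qa.append(np.nan)
            elif b.kind == "quad4":
                jr.append(np.nan)
                valid.append(True)
                ar.append(aspect_ratio(coords, "quad4"))
                qa.append(max_quad_angle(coords))
            else:
                jr.append(np.nan)
                valid.append(True)
                ar.append(np.nan)
                qa.append(np.nan)
    jr = np.asarray(jr)
    valid = np.asarray(valid, dtype=bool)
    ar = np.asarray(ar)
    qa = np.asarray(qa)
    kinds_arr = np.asarray(kinds)
    is_hex = np.isin(kinds_arr, ["hex8", "hex20"])
    is_quad = kinds_arr == "quad4"
    n_hex = int(is_hex.sum())
    n_hq = int(is_hex.sum() + is_quad.sum())
    n_quad = int(is_quad.sum())

    errors = is_hex & ~valid
    with np.errstate(invalid="ignore"):
        low_jac = is_hex & valid & (jr < 0.30)
        bad_ar = (is_hex | is_quad) & (ar > 10.0)
        bad_qa = is_quad & (qa > 160.0)
    warn = (low_jac | bad_ar | bad_qa) & ~errors

    def pct(count: int, total: int) -> float:
        return 100.0 * count / total if total else 0.0

    return QualityReport(
        element_ids=np.asarray(eids, dtype=np.int64),
        kinds=kinds,
        jacobian_ratios=jr,
        valid=valid,
        aspect_ratios=ar,
        max_quad_angles=qa,
        percent_errors=pct(int(errors.sum()), n_hex),
        percent_warnings=pct(int(warn.sum()), n_hq),
        percent_aspect_gt_10=pct(int(bad_ar.sum()), n_hq),
        percent_quad_angle_gt_160=pct(int(bad_qa.sum()), n_quad),
    )


# --------------------------------------------------------------------------
# Spinopelvic parameters
# --------------------------------------------------------------------------

@dataclass
class SpinoPelvicParams:
    """Sagittal-balance annotation record; angles in degrees, SVA in mm."""

    pi: float
    pt: float
    ss: float
    ll: float  # signed, lordosis negative
    llpi: float  # PI - |LL|
    gt: float
    rpv: float
    rll: float
    ldi: float
    rsa: float
    tpa: float
    sva: float
    cobb: float
    gap: int | None = None
    warnings: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "PI": self.pi, "PT": self.pt, "SS": self.ss, "LL": self.ll,
            "LL-PI": self.llpi, "GT": self.gt, "RPV": self.rpv,
            "RLL": self.rll, "LDI": self.ldi, "RSA": self.rsa,
            "TPA": self.tpa, "SVA": self.sva, "cobb": self.cobb,
            "GAP": self.gap,
        }


def ideal_sacral_slope(pi: float) -> float:
    """PI-proportioned ideal sacral slope: 0.59 PI + 9 (deg)."""
    return 0.59 * pi + 9.0


def ideal_lumbar_lordosis(pi: float) -> float:
    """PI-proportioned ideal lumbar lordosis magnitude: 0.62 PI + 29 (deg)."""
    return 0.62 * pi + 29.0


def ideal_global_tilt(pi: float) -> float:
    """PI-proportioned ideal global tilt: 0.9 PI - 48 (deg)."""
    return 0.9 * pi - 48.0


def _angle_between(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise MeshError("zero-length vector in angle measurement")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return math.degrees(math.acos(c))


_REQUIRED_LANDMARKS = [
    "femoral_head_left", "femoral_head_right",
    "s1_plate_anterior", "s1_plate_posterior", "s1_plate_center",
    "L1_sup_anterior", "L1_sup_posterior",
    "L4_sup_anterior", "L4_sup_posterior",
    "c7_center",
]


def measure_spinopelvic(model, landmarks: LandmarkRegistry,
                        compute_gap_components: bool = True
                        ) -> SpinoPelvicParams:
    """Measure the sagittal-balance parameter set from named landmarks.

    ``model`` is a Shape (landmarks are 0-based point indices) or an
    FEModel (landmarks are 1-based node IDs).  Sagittal quantities use the
    y-z projection; the scoliosis Cobb angle uses the coronal x-z
    projection, maximising the inter-endplate angle over vertebra pairs.
    """
    landmarks.require(_REQUIRED_LANDMARKS)

    if isinstance(model, FEModel):
        idx = model.node_index()

        def p(name: str) -> np.ndarray:
            return model.node_coords[idx[int(landmarks[name])]]
    elif isinstance(model, Shape):
        def p(name: str) -> np.ndarray:
            return model.points[landmarks[name]]
    else:
        raise MeshError("model must be a Shape or FEModel")

    # body-fixed frame: the lateral axis follows the bicoxofemoral axis
    # (projected to the horizontal plane), the vertical axis stays gravity;
    # measurements are then invariant to the patient's rotation about the
    # vertical, as on a properly positioned lateral radiograph
    fh_l, fh_r = p("femoral_head_left"), p("femoral_head_right")
    zhat = np.array([0.0, 0.0, 1.0])
    xraw = fh_r - fh_l
    xraw = xraw - (xraw @ zhat) * zhat
    nx = np.linalg.norm(xraw)
    xhat = xraw / nx if nx > 1e-9 else np.array([1.0, 0.0, 0.0])
    yhat = np.cross(zhat, xhat)

    def sag(v: np.ndarray) -> np.ndarray:  # (anterior, cranial) projection
        return np.array([v @ yhat, v @ zhat])

    def cor(v: np.ndarray) -> np.ndarray:  # coronal (lateral, cranial)
        return np.array([v @ xhat, v @ zhat])

    ha = 0.5 * (fh_l + fh_r)
    s1c = p("s1_plate_center")
    s1a, s1p = p("s1_plate_anterior"), p("s1_plate_posterior")

    # sacral slope: sacral plate line vs horizontal
    d_plate = sag(s1a) - sag(s1p)
    ss = math.degrees(math.atan2(-d_plate[1], d_plate[0]))
    # anatomical SS is reported as a positive inclination
    # (plate descending anteriorly in this frame)

    # pelvic tilt: HA -> S1 center vs vertical, positive when S1 posterior
    u = sag(s1c) - sag(ha)
    pt = math.degrees(math.atan2(-u[0], u[1]))

    # pelvic incidence: plate normal (caudal side) vs line S1 center -> HA;
    # position-independent by construction
    n2 = np.array([d_plate[1], -d_plate[0]])
    if n2[1] > 0:
        n2 = -n2
    pi_angle = _angle_between(n2, sag(ha) - sag(s1c))

    def plate_angle(v: str) -> float:
        d = sag(p(f"{v}_sup_anterior")) - sag(p(f"{v}_sup_posterior"))
        return math.degrees(math.atan2(d[1], d[0]))

    theta_s1 = math.degrees(math.atan2(d_plate[1], d_plate[0]))
    ll = theta_s1 - plate_angle("L1")  # negative for lordosis
    ll_l4 = theta_s1 - plate_angle("L4")
    llpi = pi_angle - abs(ll)
    ldi = 100.0 * (ll_l4 / ll) if ll != 0 else float("nan")

    # global tilt: angle between the C7 -> sacral-plate-centre line
    # (continued) and the sacral-plate-centre -> hip-axis line
    c7 = p("c7_center")
    gt = _angle_between(sag(s1c) - sag(c7), sag(ha) - sag(s1c))
    sva = float((c7 - s1p) @ yhat)  # C7 plumb line vs posterior S1 corner

    if "T1_sup_center" in landmarks:
        t1 = p("T1_sup_center")
        tpa = _angle_between(sag(t1) - sag(ha), sag(s1c) - sag(ha))
    else:
        tpa = float("nan")

    cobb = _cobb_coronal(p, landmarks, cor)

    warnings = []
    if abs(pi_angle - (pt + ss)) > 3.0:
        warnings.append(f"PI deviates from PT+SS by "
                        f"{abs(pi_angle - (pt + ss)):.2f} deg")

    rpv = ss - ideal_sacral_slope(pi_angle)
    rll = abs(ll) - ideal_lumbar_lordosis(pi_angle)
    rsa = gt - ideal_global_tilt(pi_angle)

    return SpinoPelvicParams(
        pi=pi_angle, pt=pt, ss=ss, ll=ll, llpi=llpi, gt=gt,
        rpv=rpv, rll=rll, ldi=ldi, rsa=rsa, tpa=tpa, sva=sva, cobb=cobb,
        warnings=warnings,
    )


def _cobb_coronal(p, landmarks: LandmarkRegistry, cor) -> float:
    """Cobb angle on the coronal projection: maximum angle between
    superior-endplate lines over all vertebra pairs (automatic end-vertebra
    choice)."""
    angles = []
    names = [k for k in landmarks.landmarks if k.endswith("_sup_left")]
    for name in names:
        v = name[:-len("_sup_left")]
        right = f"{v}_sup_right"
        if right not in landmarks:
            continue
        proj = cor(p(right)) - cor(p(name))
        if np.linalg.norm(proj) == 0:
            continue
        angles.append(math.degrees(math.atan2(proj[1], proj[0])))
    if len(angles) < 2:
        return 0.0
    return float(max(angles) - min(angles))


# --------------------------------------------------------------------------
# GAP score and classification
# --------------------------------------------------------------------------

# Editable category/point scheme for the Global Alignment and Proportion
# score.  Each entry: (lower_bound, upper_bound, points), bounds inclusive
# of the lower edge, exclusive of the upper.  Sum of the worst categories
# plus the age factor is 13.
GAP_SCHEME: dict = {
    "rpv": [(-math.inf, -10.0, 3),   # severe pelvic retroversion
            (-10.0, -4.0, 1),        # moderate pelvic retroversion
            (-4.0, math.inf, 0)],    # aligned
    "rll": [(-math.inf, -25.0, 3),   # severe hypolordosis
            (-25.0, -14.0, 2),       # moderate hypolordosis
            (-14.0, math.inf, 0)],   # aligned
    "ldi": [(-math.inf, 40.0, 2),    # severe hypolordotic maldistribution
            (40.0, 50.0, 1),         # moderate maldistribution
            (50.0, 80.0, 0),         # aligned
            (80.0, math.inf, 3)],    # hyperlordotic maldistribution
    "rsa": [(-math.inf, 7.0, 0),     # aligned
            (7.0, 17.0, 1),          # moderate malalignment
            (17.0, math.inf, 3)],    # severe malalignment
    "age": {"young": 1, "adult": 0},  # age factor: under 60 years adds 1
}


def _lookup(component: str, value: float, scheme: dict) -> int:
    for lo, hi, pts in scheme[component]:
        if lo <= value < hi:
            return pts
    raise MeshError(f"value {value} outside {component} scheme bands")


def gap_score(params: SpinoPelvicParams, age_category: str = "adult",
              scheme: dict | None = None) -> int:
    """Global Alignment and Proportion score, 0-13.

    Sums the category points of the PI-proportioned components (relative
    pelvic version, relative lumbar lordosis, lumbar distribution index,
    relative spinopelvic alignment) plus the age factor.  ``age_category``
    is 'adult' (60 years or older, 0 points) or 'young' (under 60, 1
    point); an integer age is also accepted.
    """
    scheme = scheme or GAP_SCHEME
    for comp in ("rpv", "rll", "ldi", "rsa"):
        v = getattr(params, comp)
        if v is None or not np.isfinite(v):
            raise MeshError(f"GAP component {comp} missing or non-finite")
    if isinstance(age_category, (int, float)):
        age_category = "young" if age_category < 60 else "adult"
    if age_category not in scheme["age"]:
        raise MeshError(f"unknown age category {age_category!r}")
    total = (_lookup("rpv", params.rpv, scheme)
             + _lookup("rll", params.rll, scheme)
             + _lookup("ldi", params.ldi, scheme)
             + _lookup("rsa", params.rsa, scheme)
             + scheme["age"][age_category])
    return int(total)


def classify_deformity(params: SpinoPelvicParams) -> tuple[str, str]:
    """(sagittal class from GAP, scoliosis class from the Cobb angle).

    Sagittal: GAP 0-2 aligned, 3-6 moderate, 7-13 severe.  Scoliosis:
    Cobb < 10 deg none, 10-20 moderate, > 20 severe.
    """
    if params.gap is None:
        raise MeshError("GAP score not set on params")
    g = params.gap
    if not (0 <= g <= 13):
        raise MeshError(f"GAP score {g} outside 0-13")
    sagittal = "aligned" if g <= 2 else ("moderate" if g <= 6 else "severe")
    c = params.cobb
    scoliosis = "none" if c < 10.0 else ("moderate" if c <= 20.0 else "severe")
    return sagittal, scoliosis


def inclusion_filter(age: float, params: SpinoPelvicParams) -> bool:
    """Deformity-cohort inclusion: age 50-75 years plus all of
    |LL - PI| mismatch > 10 deg, PT > 20 deg and SVA > 5 cm, with strict
    inequalities on the three thresholds."""
    for name in ("llpi", "pt", "sva"):
        v = getattr(params, name)
        if v is None or not np.isfinite(v):
            raise MeshError(f"inclusion filter: missing parameter {name}")
    if not (50 <= age <= 75):
        return False
    return abs(params.llpi) > 10.0 and params.pt > 20.0 and params.sva > 50.0
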