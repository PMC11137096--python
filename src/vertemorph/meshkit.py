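"""Mesh data model, STL / Abaqus-INP I/O, and synthetic fixture generation.

Units are millimetres throughout; angles elsewhere in the package are degrees.
Internal point and element indices are 0-based; INP node/element IDs are
1-based and preserved verbatim on round-trip.
"""

from __future__ import annotations

import io
import re
import struct
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Shape",
    "TriSurface",
    "QuadSurface",
    "ElementBlock",
    "FEModel",
    "LandmarkRegistry",
    "MeshError",
    "read_stl",
    "write_stl",
    "read_inp",
    "write_inp",
    "replace_coordinates",
    "make_fixture_family",
    "make_spine_constellation",
    "make_spine_family",
    "make_spine_fe_template",
    "spine_landmark_names",
    "ELEMENT_ARITY",
]


class MeshError(ValueError):
    """Raised for malformed mesh files or inconsistent mesh structures."""


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass
class Shape:
    """An ordered set of P corresponding 3-D points (mm) for one individual.

    Correspondence across a shape family is positional: point i of every
    shape denotes the same anatomical location.
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise MeshError(f"Shape points must be P x 3, got {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise MeshError("Shape contains non-finite coordinates")
        self.points = pts

    @property
    def point_count(self) -> int:
        return self.points.shape[0]

    def as_vector(self) -> np.ndarray:
        """Flattened 3P-vector (x0, y0, z0, x1, ...)."""
        return self.points.reshape(-1)

    @classmethod
    def from_vector(cls, v: np.ndarray) -> "Shape":
        return cls(np.asarray(v, dtype=float).reshape(-1, 3))

    def copy(self) -> "Shape":
        return Shape(self.points.copy())


@dataclass
class TriSurface:
    """Indexed triangulated surface: a Shape plus T x 3 point-index faces."""

    shape: Shape
    faces: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.faces, dtype=np.int64)
        if f.ndim != 2 or f.shape[1] != 3:
            raise MeshError(f"faces must be T x 3, got {f.shape}")
        P = self.shape.point_count
        if f.size and (f.min() < 0 or f.max() >= P):
            raise MeshError("face index out of range")
        if f.size and np.any(
            (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
        ):
            raise MeshError("degenerate face (repeated vertex index)")
        self.faces = f

    @property
    def points(self) -> np.ndarray:
        return self.shape.points


@dataclass
class QuadSurface:
    """Indexed quadrilateral surface (morphing target for IVD construction)."""

    points: np.ndarray
    quads: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        q = np.asarray(self.quads, dtype=np.int64)
        if q.ndim != 2 or q.shape[1] != 4:
            raise MeshError(f"quads must be Q x 4, got {q.shape}")
        self.quads = q


ELEMENT_ARITY = {"hex8": 8, "hex20": 20, "quad4": 4, "tri3": 3, "line2": 2}

# Abaqus element-type keyword -> internal kind
_ABAQUS_KINDS = {
    "C3D8": "hex8", "C3D8R": "hex8", "C3D8I": "hex8", "C3D8H": "hex8",
    "C3D20": "hex20", "C3D20R": "hex20", "C3D20RH": "hex20",
    "S4": "quad4", "S4R": "quad4", "M3D4": "quad4", "SFM3D4": "quad4",
    "S3": "tri3", "S3R": "tri3", "M3D3": "tri3", "SFM3D3": "tri3",
    "T3D2": "line2", "B31": "line2", "SPRINGA": "line2", "CONN3D2": "line2",
}
_KIND_ABAQUS = {"hex8": "C3D8", "hex20": "C3D20", "quad4": "S4",
                "tri3": "S3", "line2": "T3D2"}


@dataclass
class ElementBlock:
    name: str
    kind: str  # hex8 | hex20 | quad4 | tri3 | line2
    element_ids: np.ndarray  # 1-based, shape (E,)
    connectivity: np.ndarray  # node IDs, shape (E, arity)
    abaqus_type: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ELEMENT_ARITY:
            raise MeshError(f"unknown element kind {self.kind!r}")
        self.element_ids = np.asarray(self.element_ids, dtype=np.int64).reshape(-1)
        conn = np.asarray(self.connectivity, dtype=np.int64)
        arity = ELEMENT_ARITY[self.kind]
        if conn.ndim != 2 or conn.shape[1] != arity:
            raise MeshError(
                f"{self.kind} connectivity must have {arity} nodes per "
                f"element, got shape {conn.shape}")
        self.connectivity = conn
        if not self.abaqus_type:
            self.abaqus_type = _KIND_ABAQUS[self.kind]


@dataclass
class FEModel:
    """Finite-element mesh: nodes, typed element blocks, named sets, ties.

    ``extra_sections`` carries unparsed INP keyword sections verbatim so the
    template workflow stays bit-faithful outside the interpreted subset.
    """

    node_ids: np.ndarray  # 1-based, shape (Q,)
    node_coords: np.ndarray  # (Q, 3) mm
    element_blocks: list[ElementBlock] = field(default_factory=list)
    element_sets: dict[str, np.ndarray] = field(default_factory=dict)
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)
    ties: list[tuple[str, str]] = field(default_factory=list)
    extra_sections: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.node_ids = np.asarray(self.node_ids, dtype=np.int64).reshape(-1)
        self.node_coords = np.asarray(self.node_coords, dtype=float).reshape(-1, 3)
        if self.node_ids.shape[0] != self.node_coords.shape[0]:
            raise MeshError("node_ids and node_coords length mismatch")
        self.element_sets = {k: np.asarray(v, dtype=np.int64).reshape(-1)
                             for k, v in self.element_sets.items()}
        self.node_sets = {k: np.asarray(v, dtype=np.int64).reshape(-1)
                          for k, v in self.node_sets.items()}

    # -- lookups ----------------------------------------------------------
    @property
    def node_count(self) -> int:
        return self.node_ids.shape[0]

    def node_index(self) -> dict[int, int]:
        """node ID -> 0-based row in node_coords."""
        return {int(nid): i for i, nid in enumerate(self.node_ids)}

    def coords_of(self, node_ids) -> np.ndarray:
        idx = self.node_index()
        rows = [idx[int(n)] for n in np.asarray(node_ids).reshape(-1)]
        return self.node_coords[rows]

    def all_element_ids(self) -> np.ndarray:
        if not self.element_blocks:
            return np.empty(0, dtype=np.int64)
        return np.concatenate([b.element_ids for b in self.element_blocks])

    def element_conn(self) -> dict[int, tuple[str, np.ndarray]]:
        """element ID -> (kind, connectivity row)."""
        out: dict[int, tuple[str, np.ndarray]] = {}
        for b in self.element_blocks:
            for eid, row in zip(b.element_ids, b.connectivity):
                out[int(eid)] = (b.kind, row)
        return out

    def validate(self) -> None:
        known = set(int(n) for n in self.node_ids)
        for b in self.element_blocks:
            missing = sorted(set(int(n) for n in b.connectivity.reshape(-1)) - known)
            if missing:
                raise MeshError(
                    f"block {b.name!r} references missing node IDs {missing[:10]}")
        eids = set(int(e) for e in self.all_element_ids())
        for name, members in self.element_sets.items():
            bad = sorted(set(int(e) for e in members) - eids)
            if bad:
                raise MeshError(f"element set {name!r} references unknown elements {bad[:10]}")
        for name, members in self.node_sets.items():
            bad = sorted(set(int(n) for n in members) - known)
            if bad:
                raise MeshError(f"node set {name!r} references unknown nodes {bad[:10]}")

    def copy(self) -> "FEModel":
        return FEModel(
            node_ids=self.node_ids.copy(),
            node_coords=self.node_coords.copy(),
            element_blocks=[replace(b, element_ids=b.element_ids.copy(),
                                    connectivity=b.connectivity.copy())
                            for b in self.element_blocks],
            element_sets={k: v.copy() for k, v in self.element_sets.items()},
            node_sets={k: v.copy() for k, v in self.node_sets.items()},
            ties=list(self.ties),
            extra_sections=list(self.extra_sections),
        )


@dataclass
class LandmarkRegistry:
    """Named anatomical landmarks as node IDs (FEModel) or 0-based point
    indices (Shape) on a stated reference mesh."""

    landmarks: dict[str, int]

    def __getitem__(self, name: str) -> int:
        try:
            return self.landmarks[name]
        except KeyError:
            raise MeshError(f"missing landmark {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self.landmarks

    def require(self, names) -> None:
        missing = [n for n in names if n not in self.landmarks]
        if missing:
            raise MeshError(f"missing landmarks: {missing}")

    def check_against(self, model: FEModel) -> None:
        known = set(int(n) for n in model.node_ids)
        bad = {k: v for k, v in self.landmarks.items() if int(v) not in known}
        if bad:
            raise MeshError(f"landmarks reference unknown node IDs: {bad}")


# --------------------------------------------------------------------------
# STL I/O
#
# STL carries no vertex indexing; correspondence across corresponding files
# is preserved by welding duplicate vertices at a fixed tolerance in
# first-occurrence order.
# --------------------------------------------------------------------------

WELD_TOL = 1e-6  # mm


def _weld(tri_vertices: np.ndarray, tol: float = WELD_TOL):
    """Weld (3T, 3) per-facet vertices into unique points, first-occurrence
    order, returning (points, faces)."""
    if tol <= 0:
        keys = [tuple(v) for v in tri_vertices]
    else:
        keys = [tuple(k) for k in np.round(tri_vertices / tol).astype(np.int64)]
    index: dict[tuple, int] = {}
    order: list[int] = []
    face_idx = np.empty(len(keys), dtype=np.int64)
    for i, key in enumerate(keys):
        j = index.get(key)
        if j is None:
            j = len(order)
            index[key] = j
            order.append(i)
        face_idx[i] = j
    points = tri_vertices[order]
    faces = face_idx.reshape(-1, 3)
    return points, faces


def read_stl(path, tol: float = WELD_TOL) -> TriSurface:
    """Read an ASCII or binary STL file into an indexed :class:`TriSurface`.

    Vertices are welded at ``tol`` (mm) in first-occurrence file order so
    that corresponding files yield identically ordered point lists.
    """
    with open(path, "rb") as fh:
        raw = fh.read()
    if _looks_ascii_stl(raw):
        tri = _parse_ascii_stl(raw.decode("ascii", errors="replace"))
    else:
        tri = _parse_binary_stl(raw)
    if tri.shape[0] == 0:
        raise MeshError(f"{path}: STL contains no facets")
    points, faces = _weld(tri.reshape(-1, 3), tol)
    keep = ~((faces[:, 0] == faces[:, 1]) | (faces[:, 1] == faces[:, 2])
             | (faces[:, 0] == faces[:, 2]))
    return TriSurface(Shape(points), faces[keep])


def _looks_ascii_stl(raw: bytes) -> bool:
    head = raw[:512].lstrip()
    if not head.lower().startswith(b"solid"):
        return False
    # binary files may start with "solid" in the 80-byte header; an ASCII
    # file must contain the "facet" keyword early on
    return b"facet" in raw[:2048].lower() or len(raw) < 84


def _parse_ascii_stl(text: str) -> np.ndarray:
    verts: list[list[float]] = []
    facet = 0
    for lineno, line in enumerate(text.splitlines(), 1):
        s = line.strip().lower()
        if s.startswith("facet"):
            facet += 1
        elif s.startswith("vertex"):
            parts = s.split()
            if len(parts) != 4:
                raise MeshError(f"malformed vertex record in facet {facet} "
                                f"(line {lineno}): {line.strip()!r}")
            try:
                verts.append([float(p) for p in parts[1:]])
            except ValueError:
                raise MeshError(f"malformed vertex record in facet {facet} "
                                f"(line {lineno}): {line.strip()!r}") from None
    if len(verts) % 3 != 0:
        raise MeshError(f"ASCII STL has {len(verts)} vertices "
                        f"(not a multiple of 3); last facet {facet} malformed")
    return np.asarray(verts, dtype=float).reshape(-1, 3, 3)


def _parse_binary_stl(raw: bytes) -> np.ndarray:
    if len(raw) < 84:
        raise MeshError("binary STL shorter than 84-byte header")
    (count,) = struct.unpack_from("<I", raw, 80)
    expected = 84 + 50 * count
    if len(raw) < expected:
        got = (len(raw) - 84) // 50
        raise MeshError(f"binary STL truncated at facet {got} of {count}")
    rec = np.frombuffer(raw, dtype=np.dtype([
        ("normal", "<f4", (3,)), ("verts", "<f4", (3, 3)), ("attr", "<u2"),
    ]), count=count, offset=84)
    return rec["verts"].astype(float)


def write_stl(surface: TriSurface, path, mode: str = "binary") -> None:
    """Write a TriSurface as STL; facet normals are recomputed from the
    vertex winding.  Binary output is bit-stable for identical input."""
    if surface.faces.shape[0] == 0:
        raise MeshError("refusing to write empty surface")
    pts = surface.points
    tris = pts[surface.faces]  # (T, 3, 3)
    n = np.cross(tris[:, 1] - tris[:, 0], tris[:, 2] - tris[:, 0])
    norm = np.linalg.norm(n, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        n = np.where(norm > 0, n / np.where(norm == 0, 1.0, norm), 0.0)
    if mode == "binary":
        rec = np.zeros(len(tris), dtype=np.dtype([
            ("normal", "<f4", (3,)), ("verts", "<f4", (3, 3)), ("attr", "<u2"),
        ]))
        rec["normal"] = n
        rec["verts"] = tris
        with open(path, "wb") as fh:
            fh.write(b"vertemorph binary stl".ljust(80, b"\0"))
            fh.write(struct.pack("<I", len(tris)))
            fh.write(rec.tobytes())
    elif mode == "ascii":
        buf = io.StringIO()
        buf.write("solid vertemorph\n")
        for nn, tri in zip(n, tris):
            buf.write(f"  facet normal {nn[0]:.9e} {nn[1]:.9e} {nn[2]:.9e}\n")
            buf.write("    outer loop\n")
            for v in tri:
                buf.write(f"      vertex {v[0]:.9e} {v[1]:.9e} {v[2]:.9e}\n")
            buf.write("    endloop\n  endfacet\n")
        buf.write("endsolid vertemorph\n")
        with open(path, "w") as fh:
            fh.write(buf.getvalue())
    else:
        raise MeshError(f"unknown STL mode {mode!r}")


# --------------------------------------------------------------------------
# Abaqus INP dialect subset
#
# Interpreted keywords: *NODE, *ELEMENT (TYPE=, ELSET=), *ELSET, *NSET
# (with GENERATE), *TIE (pairs of set names).  Comment lines "**" inside
# interpreted sections are skipped; every other keyword section is carried
# as opaque text so round-trips stay bit-faithful outside the subset.
# --------------------------------------------------------------------------

_KEYWORD_RE = re.compile(r"^\*([A-Za-z][A-Za-z0-9 _-]*)")


def _parse_keyword_line(line: str) -> tuple[str, dict[str, str]]:
    parts = [p.strip() for p in line.split(",")]
    kw = parts[0].lstrip("*").strip().upper()
    opts: dict[str, str] = {}
    for p in parts[1:]:
        if "=" in p:
            k, v = p.split("=", 1)
            opts[k.strip().upper()] = v.strip()
        elif p:
            opts[p.upper()] = ""
    return kw, opts


def read_inp(path) -> FEModel:
    """Read the Abaqus-INP dialect subset into an :class:`FEModel`."""
    with open(path) as fh:
        lines = fh.read().splitlines()

    node_ids: list[int] = []
    coords: list[list[float]] = []
    blocks: list[ElementBlock] = []
    elsets: dict[str, list[int]] = {}
    nsets: dict[str, list[int]] = {}
    ties: list[tuple[str, str]] = []
    extras: list[str] = []

    i = 0
    n_lines = len(lines)

    def data_lines(start: int):
        j = start
        while j < n_lines:
            s = lines[j].strip()
            if s.startswith("**"):
                j += 1
                continue
            if s.startswith("*"):
                break
            yield j, s
            j += 1
        # communicate the stop position via attribute
        data_lines.stop = j

    while i < n_lines:
        line = lines[i].strip()
        if not line or line.startswith("**"):
            i += 1
            continue
        if not line.startswith("*"):
            raise MeshError(f"line {i + 1}: stray data outside any keyword "
                            f"section: {line!r}")
        kw, opts = _parse_keyword_line(line)
        if kw == "NODE":
            data_lines.stop = i + 1
            for j, s in data_lines(i + 1):
                parts = [p for p in s.replace(",", " ").split() if p]
                if len(parts) < 4:
                    raise MeshError(f"line {j + 1}: malformed node record {s!r}")
                node_ids.append(int(float(parts[0])))
                coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
            i = data_lines.stop
        elif kw == "ELEMENT":
            atype = opts.get("TYPE", "").upper()
            kind = _ABAQUS_KINDS.get(atype)
            if kind is None:
                raise MeshError(f"line {i + 1}: unsupported element TYPE={atype!r}")
            arity = ELEMENT_ARITY[kind]
            name = opts.get("ELSET", f"EB{len(blocks) + 1}")
            eids: list[int] = []
            conn: list[list[int]] = []
            pending: list[int] = []
            data_lines.stop = i + 1
            for j, s in data_lines(i + 1):
                nums = [int(float(p)) for p in s.replace(",", " ").split() if p]
                pending.extend(nums)
                while len(pending) >= arity + 1:
                    eids.append(pending[0])
                    conn.append(pending[1:arity + 1])
                    pending = pending[arity + 1:]
            if pending:
                raise MeshError(f"element block {name!r}: trailing incomplete "
                                f"element record {pending}")
            i = data_lines.stop
            blocks.append(ElementBlock(name=name, kind=kind,
                                       element_ids=np.array(eids, dtype=np.int64),
                                       connectivity=np.array(conn, dtype=np.int64)
                                       .reshape(-1, arity),
                                       abaqus_type=atype))
            elsets.setdefault(name, []).extend(eids)
        elif kw in ("ELSET", "NSET"):
            key = "ELSET" if kw == "ELSET" else "NSET"
            name = opts.get(key, "")
            if not name:
                raise MeshError(f"line {i + 1}: {kw} without a name")
            gen = "GENERATE" in opts
            members: list[int] = []
            data_lines.stop = i + 1
            for j, s in data_lines(i + 1):
                nums = [int(float(p)) for p in s.replace(",", " ").split() if p]
                if gen:
                    if len(nums) == 2:
                        nums = nums + [1]
                    members.extend(range(nums[0], nums[1] + 1, nums[2]))
                else:
                    members.extend(nums)
            i = data_lines.stop
            target = elsets if kw == "ELSET" else nsets
            target.setdefault(name, []).extend(members)
        elif kw == "TIE":
            data_lines.stop = i + 1
            for j, s in data_lines(i + 1):
                names = [p.strip() for p in s.split(",") if p.strip()]
                if len(names) != 2:
                    raise MeshError(f"line {j + 1}: TIE data must be "
                                    f"'secondary, primary', got {s!r}")
                ties.append((names[0], names[1]))
            i = data_lines.stop
        else:
            # opaque section: keyword line plus data lines, kept verbatim
            section = [lines[i]]
            j = i + 1
            while j < n_lines and not lines[j].strip().startswith("*"):
                section.append(lines[j])
                j += 1
            extras.append("\n".join(section))
            i = j

    model = FEModel(
        node_ids=np.array(node_ids, dtype=np.int64),
        node_coords=np.array(coords, dtype=float).reshape(-1, 3),
        element_blocks=blocks,
        element_sets={k: np.array(v, dtype=np.int64) for k, v in elsets.items()},
        node_sets={k: np.array(v, dtype=np.int64) for k, v in nsets.items()},
        ties=ties,
        extra_sections=extras,
    )
    model.validate()
    return model


def write_inp(model: FEModel, path) -> None:
    """Write an :class:`FEModel` in the INP dialect subset."""
    buf = io.StringIO()
    buf.write("*NODE\n")
    for nid, (x, y, z) in zip(model.node_ids, model.node_coords):
        buf.write(f"{int(nid)}, {x:.9g}, {y:.9g}, {z:.9g}\n")
    for b in model.element_blocks:
        buf.write(f"*ELEMENT, TYPE={b.abaqus_type}, ELSET={b.name}\n")
        for eid, row in zip(b.element_ids, b.connectivity):
            buf.write(", ".join([str(int(eid))] + [str(int(n)) for n in row]) + "\n")
    block_names = {b.name for b in model.element_blocks}
    for name, members in model.element_sets.items():
        if name in block_names:
            continue  # implied by ELSET= on the element block
        buf.write(f"*ELSET, ELSET={name}\n")
        _write_id_rows(buf, members)
    for name, members in model.node_sets.items():
        buf.write(f"*NSET, NSET={name}\n")
        _write_id_rows(buf, members)
    for sec, pri in model.ties:
        buf.write("*TIE\n")
        buf.write(f"{sec}, {pri}\n")
    for section in model.extra_sections:
        buf.write(section.rstrip("\n") + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def _write_id_rows(buf, members, per_line: int = 12) -> None:
    members = [str(int(m)) for m in np.asarray(members).reshape(-1)]
    for k in range(0, len(members), per_line):
        buf.write(", ".join(members[k:k + per_line]) + "\n")


def replace_coordinates(template: FEModel, coords: np.ndarray) -> FEModel:
    """Return a copy of ``template`` with node coordinates replaced.

    Connectivity, sets, ties and opaque sections are shared structure: only
    the *NODE coordinates differ, mirroring the coordinate-substitution
    workflow used to regenerate cohort input files from a mean template.
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    if coords.shape[0] != template.node_count:
        raise MeshError(
            f"coordinate row count {coords.shape[0]} != template node count "
            f"{template.node_count}")
    out = template.copy()
    out.node_coords = coords.copy()
    return out


# --------------------------------------------------------------------------
# Synthetic fixtures: planted-mode shape family
# --------------------------------------------------------------------------

def make_fixture_family(
    P: int,
    n: int,
    planted_variances,
    noise_sd: float = 0.0,
    seed: int = 0,
    rigid_nuisance: bool = False,
    mean: np.ndarray | None = None,
    modes: np.ndarray | None = None,
):
    """Draw a low-rank "planted-mode" family of corresponding shapes.

    Shapes are ``mean + sum_j sqrt(var_j) z_j mode_j + noise`` with z drawn
    standard normal.  The planted mean, orthonormal modes (3P x k) and
    variances are returned alongside the family so recovery can be checked.
    When ``rigid_nuisance`` is on, each shape additionally receives a random
    rigid transform (rotations uniform within +/-30 deg per axis) to emulate
    unaligned acquisitions.

    Returns ``(shapes, mean_vector, modes_matrix, variances)``.
    """
    planted_variances = np.asarray(planted_variances, dtype=float).reshape(-1)
    k = planted_variances.size
    if k >= n - 1:
        raise MeshError(f"rank {k} not recoverable from {n} shapes (need k < n-1)")
    if np.any(planted_variances <= 0) or np.any(np.diff(planted_variances) > 0):
        raise MeshError("planted variances must be positive and descending")
    rng = np.random.default_rng(seed)
    d = 3 * P
    if mean is None:
        mean = rng.normal(scale=10.0, size=d)
    else:
        mean = np.asarray(mean, dtype=float).reshape(d)
    if modes is None:
        raw = rng.normal(size=(d, k))
        modes, _ = np.linalg.qr(raw)
    else:
        modes = np.asarray(modes, dtype=float).reshape(d, k)
    z = rng.normal(size=(n, k))
    data = mean[None, :] + (z * np.sqrt(planted_variances)) @ modes.T
    if noise_sd > 0:
        data = data + rng.normal(scale=noise_sd, size=data.shape)
    shapes = [Shape.from_vector(v) for v in data]
    if rigid_nuisance:
        out = []
        for s in shapes:
            angles = rng.uniform(-np.pi / 6, np.pi / 6, size=3)
            t = rng.normal(scale=5.0, size=3)
            R = _euler_rotation(angles)
            out.append(Shape(s.points @ R.T + t))
        shapes = out
    return shapes, mean, modes, planted_variances


def _euler_rotation(angles) -> np.ndarray:
    ax, ay, az = angles
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


# --------------------------------------------------------------------------
# Synthetic fixtures: spinopelvic landmark constellation and spine family
#
# Coordinate convention (after alignment): x lateral, y posterior->anterior,
# z cranial.  The sagittal plane is y-z.
# --------------------------------------------------------------------------

_LUMBAR = ["L5", "L4", "L3", "L2", "L1"]
_THORACIC = [f"T{i}" for i in range(12, 0, -1)]
# share of total lumbar lordosis realised below each superior endplate,
# cumulative from S1 upward (L5/S1 segment largest, as in healthy spines)
_LORDOSIS_SHARE = {"L5": 0.30, "L4": 0.25, "L3": 0.20, "L2": 0.15, "L1": 0.10}


def spine_landmark_names() -> list[str]:
    names = ["femoral_head_left", "femoral_head_right",
             "s1_plate_anterior", "s1_plate_posterior",
             "s1_plate_left", "s1_plate_right", "s1_plate_center",
             "c7_center"]
    for v in _LUMBAR + _THORACIC:
        for suffix in ("sup_anterior", "sup_posterior", "sup_left",
                       "sup_right", "sup_center", "body_center",
                       "spinous_process"):
            names.append(f"{v}_{suffix}")
    return names


def make_spine_constellation(
    pt_deg: float = 20.0,
    ss_deg: float = 35.0,
    ll_deg: float = -55.0,
    tk_deg: float = 40.0,
    cobb_deg: float = 0.0,
    pelvic_arm: float = 70.0,
    plate_width: float = 45.0,
    disc_height: float = 10.0,
    body_height: float = 28.0,
) -> tuple[Shape, LandmarkRegistry]:
    """Build an idealised sagittal-plane spinopelvic landmark constellation.

    The construction realises the requested pelvic tilt (PT), sacral slope
    (SS) and lumbar lordosis (LL, signed negative for lordosis), so pelvic
    incidence PI = PT + SS by the classic geometric identity.  Thoracic
    kyphosis ``tk_deg`` bends the thoracic endplates the opposite way;
    ``cobb_deg`` adds a coronal scoliotic bow.  All lengths in mm, angles in
    degrees.  Returns the point set and a landmark registry of 0-based point
    indices.
    """
    pt = np.radians(pt_deg)
    ss = np.radians(ss_deg)
    names: list[str] = []
    pts: list[np.ndarray] = []

    def add(name: str, p) -> None:
        names.append(name)
        pts.append(np.asarray(p, dtype=float))

    # femoral heads; bicoxofemoral axis midpoint at the origin
    add("femoral_head_left", (-40.0, 0.0, 0.0))
    add("femoral_head_right", (40.0, 0.0, 0.0))

    # sacral plate: center sits pelvic_arm away from the hip axis, tilted
    # posteriorly by PT from the vertical; the plate descends anteriorly at
    # SS from the horizontal (its normal points antero-superiorly), which
    # realises the identity PI = PT + SS
    s1c = np.array([0.0, -pelvic_arm * np.sin(pt), pelvic_arm * np.cos(pt)])
    plate_dir = np.array([0.0, np.cos(ss), -np.sin(ss)])  # posterior -> anterior
    half = 0.5 * plate_width
    add("s1_plate_anterior", s1c + half * plate_dir)
    add("s1_plate_posterior", s1c - half * plate_dir)
    add("s1_plate_left", s1c + np.array([-half, 0.0, 0.0]))
    add("s1_plate_right", s1c + np.array([half, 0.0, 0.0]))
    add("s1_plate_center", s1c)

    # stack vertebrae: theta is the signed angle of each superior endplate's
    # anterior-pointing direction versus horizontal (positive rising
    # anteriorly); the sacral plate sits at -SS, lumbar lordosis unwinds it
    # by LL, thoracic kyphosis winds it back by TK
    ll_mag = abs(ll_deg)
    cum = 0.0
    theta0 = -ss
    theta = theta0
    theta_l1 = theta0 + np.radians(ll_mag) * (1.0 if ll_deg < 0 else -1.0)
    center = s1c.copy()
    seg = disc_height + body_height
    n_levels = len(_LUMBAR + _THORACIC)
    coronal = np.radians(cobb_deg)
    for i, v in enumerate(_LUMBAR + _THORACIC):
        if v in _LORDOSIS_SHARE:
            cum += _LORDOSIS_SHARE[v] * ll_mag
            theta = theta0 + np.radians(cum) * (1.0 if ll_deg < 0 else -1.0)
        else:
            frac = (_THORACIC.index(v) + 1) / len(_THORACIC)
            theta = theta_l1 - np.radians(tk_deg) * frac
        # climb along the cranial normal of the current endplate
        axis = np.array([0.0, -np.sin(theta), np.cos(theta)])
        center = center + seg * axis
        # coronal scoliotic bow: sine bump in x, maximal mid-stack
        bow = np.sin(np.pi * (i + 1) / (n_levels + 1))
        cor_x = 200.0 * np.tan(coronal / 4.0) * bow if cobb_deg else 0.0
        cor_tilt = 0.5 * coronal * np.cos(np.pi * (i + 1) / (n_levels + 1))
        c = center + np.array([cor_x, 0.0, 0.0])
        d_sag = np.array([0.0, np.cos(theta), np.sin(theta)])
        d_cor = np.array([np.cos(cor_tilt), 0.0, np.sin(cor_tilt)])
        hw = 0.5 * plate_width * (1.0 if v in _LUMBAR else 0.85)
        add(f"{v}_sup_anterior", c + hw * d_sag)
        add(f"{v}_sup_posterior", c - hw * d_sag)
        add(f"{v}_sup_left", c - hw * d_cor)
        add(f"{v}_sup_right", c + hw * d_cor)
        add(f"{v}_sup_center", c)
        add(f"{v}_body_center", c - np.array([0.0, 0.0, 0.5 * body_height]))
        add(f"{v}_spinous_process", c - (hw + 25.0) * d_sag)
    add("c7_center", center + seg * np.array([0.0, -np.sin(theta), np.cos(theta)]))
    shape = Shape(np.vstack(pts))
    registry = LandmarkRegistry({n: i for i, n in enumerate(names)})
    return shape, registry


def make_spine_family(
    n: int = 12,
    seed: int = 0,
    pt_sd: float = 6.0,
    ss_sd: float = 6.0,
    ll_sd: float = 10.0,
    tk_sd: float = 8.0,
    cobb_sd: float = 0.0,
    noise_sd: float = 0.0,
) -> tuple[list[Shape], LandmarkRegistry]:
    """A corresponding family of spinopelvic constellations with anatomical
    parameter variation, emulating an EOS-reconstructed patient cohort.

    Parameter spreads default to values typical of an adult-deformity cohort
    (PT/SS spread ~6 deg, LL ~10 deg, kyphosis ~8 deg).
    """
    rng = np.random.default_rng(seed)
    shapes = []
    registry = None
    for _ in range(n):
        s, registry = make_spine_constellation(
            pt_deg=20.0 + rng.normal(scale=pt_sd),
            ss_deg=35.0 + rng.normal(scale=ss_sd),
            ll_deg=-55.0 + rng.normal(scale=ll_sd),
            tk_deg=40.0 + rng.normal(scale=tk_sd),
            cobb_deg=max(0.0, rng.normal(scale=cobb_sd)) if cobb_sd else 0.0,
        )
        pts = s.points
        if noise_sd > 0:
            pts = pts + rng.normal(scale=noise_sd, size=pts.shape)
        shapes.append(Shape(pts))
    return shapes, registry


def make_spine_fe_template(
    constellation: Shape | None = None,
    registry: LandmarkRegistry | None = None,
    body_width: float = 40.0,
    body_depth: float = 32.0,
    body_height: float = 24.0,
) -> tuple[FEModel, LandmarkRegistry]:
    """Build a simplified hexahedral spine FE template from a landmark
    constellation: one hex8 block per vertebral body plus the landmark
    nodes themselves, with per-vertebra element sets and interspinous
    ligament line elements.

    Landmark nodes are placed first and keep the constellation's ordering,
    so the returned registry maps names to 1-based node IDs 1..P.
    """
    if constellation is None or registry is None:
        constellation, registry = make_spine_constellation()
    pts = constellation.points
    P = pts.shape[0]
    node_ids = list(range(1, P + 1))
    coords = [p for p in pts]
    next_node = P + 1
    blocks: list[ElementBlock] = []
    elsets: dict[str, list[int]] = {}
    next_elem = 1

    hex_ids_all: list[int] = []
    for v in _LUMBAR + _THORACIC:
        c = pts[registry[f"{v}_body_center"]]
        dx = np.array([body_width / 2, 0, 0])
        dy = np.array([0, body_depth / 2, 0])
        dz = np.array([0, 0, body_height / 2])
        corners = [c - dx - dy - dz, c + dx - dy - dz, c + dx + dy - dz,
                   c - dx + dy - dz, c - dx - dy + dz, c + dx - dy + dz,
                   c + dx + dy + dz, c - dx + dy + dz]
        ids = list(range(next_node, next_node + 8))
        next_node += 8
        node_ids.extend(ids)
        coords.extend(corners)
        blocks.append(ElementBlock(name=f"{v}_BODY", kind="hex8",
                                   element_ids=np.array([next_elem]),
                                   connectivity=np.array([ids])))
        elsets[f"{v}_BODY"] = [next_elem]
        hex_ids_all.append(next_elem)
        next_elem += 1
    elsets["VERTEBRAL_BODIES"] = hex_ids_all

    # interspinous ligaments between consecutive spinous processes
    lig_ids, lig_conn = [], []
    levels = _LUMBAR + _THORACIC
    for lo, hi in zip(levels[:-1], levels[1:]):
        lig_ids.append(next_elem)
        lig_conn.append([registry[f"{lo}_spinous_process"] + 1,
                         registry[f"{hi}_spinous_process"] + 1])
        next_elem += 1
    blocks.append(ElementBlock(name="ISL", kind="line2",
                               element_ids=np.array(lig_ids),
                               connectivity=np.array(lig_conn)))
    elsets["ISL"] = lig_ids

    model = FEModel(
        node_ids=np.array(node_ids, dtype=np.int64),
        node_coords=np.array(coords, dtype=float),
        element_blocks=blocks,
        element_sets={k: np.array(v, dtype=np.int64) for k, v in elsets.items()},
        node_sets={"LANDMARKS": np.arange(1, P + 1, dtype=np.int64)},
    )
    node_registry = LandmarkRegistry({k: v + 1 for k, v in registry.landmarks.items()})
    model.validate()
    node_registry.check_against(model)
    return model, node_registry
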