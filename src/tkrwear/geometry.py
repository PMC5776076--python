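"""Triangulated articulating surfaces and synthetic implant geometry.

All meshes live in a left-knee coordinate frame with x = anterior(+),
y = superior(+), z = medial(+).  Lengths are mm, forces N, stresses MPa
(N/mm^2), frictional work N*mm.

The parametric insert/femoral generators stand in for proprietary implant
CAD: each condyle (and each insert dish) is a crossed-circular-arc height
field whose principal radii of curvature at the contact point equal the
requested sagittal/distal and frontal radii.  The absolute shapes are
synthetic; only the contact-mechanics character (moderately conforming
curved-on-curved) is intended to be representative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import trimesh


# --------------------------------------------------------------------------
# core mesh container
# --------------------------------------------------------------------------

@dataclass
class SurfaceMesh:
    """Open triangulated surface with per-vertex normals and areas.

    vertex_area uses the barycentric one-third split: each triangle
    contributes one third of its area to each of its vertices, so the
    vertex areas exactly partition the total surface area.
    """

    vertices: np.ndarray          # (n, 3) float
    faces: np.ndarray             # (m, 3) int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (m, 3)")
        if self.faces.size and (self.faces.min() < 0
                                or self.faces.max() >= len(self.vertices)):
            raise ValueError("face indices out of range")
        self._recompute()

    # geometry caches -------------------------------------------------------
    def _recompute(self) -> None:
        v, f = self.vertices, self.faces
        e1 = v[f[:, 1]] - v[f[:, 0]]
        e2 = v[f[:, 2]] - v[f[:, 0]]
        cr = np.cross(e1, e2)
        fa2 = np.linalg.norm(cr, axis=1)          # 2 * face area
        self.face_area = 0.5 * fa2
        with np.errstate(invalid="ignore", divide="ignore"):
            self.face_normal = cr / np.where(fa2 > 0, fa2, 1.0)[:, None]
        # one-third barycentric split
        va = np.zeros(len(v))
        np.add.at(va, f.ravel(), np.repeat(self.face_area / 3.0, 3))
        self.vertex_area = va
        # area-weighted vertex normals
        vn = np.zeros_like(v)
        w = (self.face_area[:, None] * self.face_normal)
        for k in range(3):
            np.add.at(vn, f[:, k], w)
        nrm = np.linalg.norm(vn, axis=1)
        self.vertex_normal = vn / np.where(nrm > 0, nrm, 1.0)[:, None]

    # convenience -----------------------------------------------------------
    @property
    def total_area(self) -> float:
        return float(self.face_area.sum())

    def with_vertices(self, vertices: np.ndarray) -> "SurfaceMesh":
        """New mesh with the same topology but displaced vertices."""
        return SurfaceMesh(vertices, self.faces.copy(), dict(self.metadata))

    def summary(self) -> dict:
        bb_lo = self.vertices.min(axis=0).tolist()
        bb_hi = self.vertices.max(axis=0).tolist()
        return {
            "n_vertices": int(len(self.vertices)),
            "n_faces": int(len(self.faces)),
            "total_area_mm2": self.total_area,
            "bbox_min": bb_lo,
            "bbox_max": bb_hi,
        }

    def summary_json(self) -> str:
        return json.dumps(self.summary(), indent=2)


# --------------------------------------------------------------------------
# parametric implant geometry
# --------------------------------------------------------------------------

@dataclass
class ImplantParams:
    """Knobs of the synthetic curved-insert / bicondylar-femur pair.

    Radii are NOT taken from any commercial implant; they are chosen to
    give a moderately conforming fixed-bearing contact.  The 10 mm insert
    thickness is the one documented implant dimension.
    """

    condyle_distal_radius: float = 32.0       # femoral sagittal radius [mm]
    condyle_frontal_radius: float = 20.0      # femoral frontal radius [mm]
    condyle_spacing: float = 46.0             # centre-to-centre, ML [mm]
    insert_dish_sagittal_radius: float = 45.0  # [mm]
    insert_dish_frontal_radius: float = 25.0   # [mm]
    insert_thickness: float = 10.0            # [mm]
    insert_width: float = 70.0                # total ML width [mm]
    grid_resolution: int = 64                 # vertices per edge

    def validate(self) -> None:
        if self.insert_thickness <= 0:
            raise ValueError("insert_thickness must be > 0")
        if self.insert_dish_sagittal_radius < self.condyle_distal_radius:
            raise ValueError(
                "non-conforming geometry: insert sagittal radius "
                f"{self.insert_dish_sagittal_radius} < condyle distal radius "
                f"{self.condyle_distal_radius}")
        if self.insert_dish_frontal_radius < self.condyle_frontal_radius:
            raise ValueError(
                "non-conforming geometry: insert frontal radius "
                f"{self.insert_dish_frontal_radius} < condyle frontal radius "
                f"{self.condyle_frontal_radius}")
        if self.grid_resolution < 2:
            raise ValueError("grid_resolution must be >= 2")
        if self.condyle_spacing <= 0 or self.insert_width <= 0:
            raise ValueError("spacing and width must be > 0")

    @property
    def ap_length(self) -> float:
        """AP extent of the articulating patch (fixed fraction of width)."""
        return 0.6 * self.insert_width


def _arc_drop(x: np.ndarray, radius: float) -> np.ndarray:
    """Height of a circular arc of given radius above its lowest point."""
    x = np.clip(x, -0.999 * radius, 0.999 * radius)
    return radius - np.sqrt(radius * radius - x * x)


def _through_points(lo: float, hi: float, n: int, anchors) -> np.ndarray:
    """n-point grid over [lo, hi] passing exactly through the anchor
    coordinates (lowest points, condyle centres, midline)."""
    anchors = sorted({lo, hi, *[a for a in anchors if lo < a < hi]})
    spans = np.diff(anchors)
    counts = np.maximum(1, np.round(spans / spans.sum()
                                    * (n - 1)).astype(int))
    # adjust so segment counts sum to n - 1
    while counts.sum() > n - 1:
        counts[np.argmax(counts)] -= 1
    while counts.sum() < n - 1:
        counts[np.argmin(counts)] += 1
    pieces = [np.array([anchors[0]])]
    for a, b, c in zip(anchors[:-1], anchors[1:], counts):
        pieces.append(np.linspace(a, b, c + 1)[1:])
    return np.concatenate(pieces)


def _grid_heightfield(xs, zs, yfun, metadata) -> SurfaceMesh:
    """Structured-grid height field y(x, z), triangulated, normals +y."""
    X, Z = np.meshgrid(xs, zs, indexing="ij")
    Y = yfun(X, Z)
    nx, nz = X.shape
    verts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    idx = np.arange(nx * nz).reshape(nx, nz)
    a = idx[:-1, :-1].ravel()
    b = idx[1:, :-1].ravel()
    c = idx[1:, 1:].ravel()
    d = idx[:-1, 1:].ravel()
    # wind so normals point along +y for an upward-opening field
    faces = np.concatenate([
        np.column_stack([a, c, b]),
        np.column_stack([a, d, c]),
    ])
    return SurfaceMesh(verts, faces, metadata)


def _bicondylar_height(x, z, sag_radius, frontal_radius, spacing):
    """Crossed-arc height of two symmetric dishes/condyles about z = 0."""
    zc = np.where(z >= 0, spacing / 2.0, -spacing / 2.0)
    return _arc_drop(x, sag_radius) + _arc_drop(z - zc, frontal_radius)


def make_insert_surface(params: ImplantParams | None = None) -> SurfaceMesh:
    """Upper articulating sheet of the tibial insert.

    Two symmetric dishes about the sagittal midplane; the lowest points sit
    at y = 0, x = 0, z = +-condyle_spacing/2.  The insert material occupies
    [-insert_thickness, surface] below the sheet.
    """
    p = params or ImplantParams()
    p.validate()
    g = p.grid_resolution
    s2 = p.condyle_spacing / 2
    xs = _through_points(-p.ap_length / 2, p.ap_length / 2, g, [0.0])
    zs = _through_points(-p.insert_width / 2, p.insert_width / 2, g,
                         [-s2, 0.0, s2])
    half = p.insert_width / 2 - p.condyle_spacing / 2
    if half >= p.insert_dish_frontal_radius:
        raise ValueError("insert_width too large for dish frontal radius")
    if p.ap_length / 2 >= p.insert_dish_sagittal_radius:
        raise ValueError("insert AP extent exceeds dish sagittal radius")

    def y(x, z):
        return _bicondylar_height(
            x, z, p.insert_dish_sagittal_radius,
            p.insert_dish_frontal_radius, p.condyle_spacing)

    meta = {"kind": "insert", "thickness": p.insert_thickness,
            "condyle_spacing": p.condyle_spacing}
    return _grid_heightfield(xs, zs, y, meta)


def make_femoral_surface(params: ImplantParams | None = None,
                         mirrored: bool = False) -> SurfaceMesh:
    """Lower (distal) articulating sheet of the bicondylar femoral component.

    Each condyle is a torus segment about the flexion axis (the z-direction
    line through (0, condyle_distal_radius, 0)): sagittal sections are
    circles of radius rho(z) = R_distal - frontal_arc_drop(z) centred on
    that axis.  The surface is therefore exactly invariant under flexion
    rotation — contact geometry depends only on AP/IE/load, while femoral
    material points still sweep along the arc (rolling/sliding).  At the
    neutral pose it touches a matching insert at the two lowest points.
    """
    p = params or ImplantParams()
    p.validate()
    g = p.grid_resolution
    s2 = p.condyle_spacing / 2
    xs = _through_points(-p.ap_length / 2, p.ap_length / 2, g, [0.0])
    half = s2 + 0.9 * p.condyle_frontal_radius
    zs = _through_points(-half, half, g, [-s2, 0.0, s2])
    rd = p.condyle_distal_radius

    def y(x, z):
        zc = np.where(z >= 0, p.condyle_spacing / 2.0,
                      -p.condyle_spacing / 2.0)
        rho = rd - _arc_drop(z - zc, p.condyle_frontal_radius)
        xc = np.clip(x, -0.999 * rho, 0.999 * rho)
        return rd - np.sqrt(rho * rho - xc * xc)

    meta = {"kind": "femoral",
            "flexion_axis_point": (0.0, p.condyle_distal_radius, 0.0),
            "flexion_axis_dir": (0.0, 0.0, 1.0),
            "flexion_invariant": True,
            "condyle_spacing": p.condyle_spacing}
    mesh = _grid_heightfield(xs, zs, y, meta)
    if mirrored:
        v = mesh.vertices.copy()
        v[:, 2] *= -1.0
        # re-wind to keep outward orientation after reflection
        f = mesh.faces[:, ::-1].copy()
        mesh = SurfaceMesh(v, f, dict(mesh.metadata))
    return mesh


def make_primitive(kind: str, **dims) -> SurfaceMesh:
    """Simple test-rig surfaces: flat_plate, cylindrical_pin_face, sphere.

    flat_plate:            width, length [mm], grid (vertices per edge)
    cylindrical_pin_face:  diameter [mm], n_radial, n_angular
    sphere:                diameter [mm], grid  (UV sphere centred at origin)
    """
    if kind == "flat_plate":
        w = float(dims.get("width", 40.0))
        ln = float(dims.get("length", 40.0))
        g = int(dims.get("grid", 32))
        xs = np.linspace(-ln / 2, ln / 2, g)
        zs = np.linspace(-w / 2, w / 2, g)
        return _grid_heightfield(xs, zs, lambda x, z: np.zeros_like(x),
                                 {"kind": "flat_plate"})

    if kind == "cylindrical_pin_face":
        d = float(dims.get("diameter", 5.0))
        g = dims.get("grid")
        nr = int(dims.get("n_radial", max(g // 4, 4) if g else 16))
        na = int(dims.get("n_angular", g if g else 32))
        r_edges = np.linspace(0.0, d / 2, nr + 1)
        thetas = np.linspace(0.0, 2 * np.pi, na, endpoint=False)
        verts = [np.array([0.0, 0.0, 0.0])]
        rings = []
        for r in r_edges[1:]:
            start = len(verts)
            for th in thetas:
                verts.append(np.array([r * np.cos(th), 0.0, r * np.sin(th)]))
            rings.append(start)
        faces = []
        first = rings[0]
        for j in range(na):
            faces.append([0, first + j, first + (j + 1) % na])
        for i in range(len(rings) - 1):
            a0, b0 = rings[i], rings[i + 1]
            for j in range(na):
                j1 = (j + 1) % na
                faces.append([a0 + j, b0 + j, b0 + j1])
                faces.append([a0 + j, b0 + j1, a0 + j1])
        mesh = SurfaceMesh(np.array(verts), np.array(faces),
                           {"kind": "pin_face", "diameter": d})
        # wind downward-facing? pin face articulates downward onto the plate;
        # flip if the mean normal points along -y so normals are +y (outward
        # of the pin material above the face is -y; we keep +y for the
        # contacting side convention used by the contact backend).
        if mesh.vertex_normal[:, 1].mean() < 0:
            mesh = SurfaceMesh(mesh.vertices, mesh.faces[:, ::-1],
                               dict(mesh.metadata))
        return mesh

    if kind == "sphere":
        d = float(dims.get("diameter", 63.5))
        g = int(dims.get("grid", 48))
        tm = trimesh.creation.uv_sphere(radius=d / 2,
                                        count=(max(g, 8), max(g, 8)))
        # poles along the superior (y) axis so the apex is an exact vertex
        v = np.asarray(tm.vertices)[:, [0, 2, 1]]
        return SurfaceMesh(v, np.asarray(tm.faces),
                           {"kind": "sphere", "diameter": d})

    raise ValueError(f"unknown primitive kind: {kind!r}")


# --------------------------------------------------------------------------
# STL I/O (binary and ASCII via trimesh)
# --------------------------------------------------------------------------

def read_stl(path) -> SurfaceMesh:
    tm = trimesh.load_mesh(str(path), file_type="stl", process=False)
    if tm.vertices.size == 0 or tm.faces.size == 0:
        raise ValueError(f"no triangles in STL file: {path}")
    # merge exactly coincident vertices created by the STL triangle soup
    tm.merge_vertices()
    return SurfaceMesh(np.asarray(tm.vertices, dtype=float),
                       np.asarray(tm.faces), {"source": str(path)})


def write_stl(mesh: SurfaceMesh, path, ascii: bool = False) -> None:
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces,
                         process=False)
    data = trimesh.exchange.stl.export_stl_ascii(tm) if ascii else \
        trimesh.exchange.stl.export_stl(tm)
    mode = "w" if isinstance(data, str) else "wb"
    with open(path, mode) as fh:
        fh.write(data)
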