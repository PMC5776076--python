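"""Elastic-foundation (Winkler) contact between a rigid counterface and the
polyethylene bearing surface, with a Hertzian closed form as accuracy anchor.

The deformable insert is modelled as a bed of independent springs of depth
``layer_thickness``: contact pressure is proportional to local penetration,

    p = K * penetration / h,     K = (1 - nu) E / ((1 + nu)(1 - 2 nu))

(the confined/oedometric modulus of the layer).  The counterface (femoral
component, pin, ball) is rigid.  Penetration is measured along the superior
(y) axis by vertical projection of the counterface surface onto the insert
vertices, matching the direction of the applied joint load.

Equilibrium in vertical translation and adduction-abduction (AA) rotation
about the (possibly medially offset) load axis is found by a damped
two-variable Newton iteration with a bisection fallback; AA enters the gap
function in small-angle linearisation.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial.transform import Rotation

from .geometry import SurfaceMesh

FORCE_RTOL = 1e-3          # |sum p a - load| <= FORCE_RTOL * load
MOMENT_ARM_TOL = 1.0       # moment tolerance = FORCE_RTOL * load * 1 mm


@dataclass
class MaterialProperties:
    """Equivalent elastic modulus E [MPa], Poisson's ratio nu [-],
    density rho [mg/mm^3], friction coefficient mu [-] of the bearing."""

    E: float = 553.0
    nu: float = 0.32
    rho: float = 0.93
    mu: float = 0.04

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValueError("E must be > 0")
        if not (0.0 <= self.nu < 0.5):
            raise ValueError("nu must be in [0, 0.5)")
        if self.rho <= 0:
            raise ValueError("rho must be > 0")
        if self.mu < 0:
            raise ValueError("mu must be >= 0")

    @property
    def confined_modulus(self) -> float:
        """K = (1-nu)E/((1+nu)(1-2nu)), the foundation spring modulus."""
        return (1.0 - self.nu) * self.E / ((1.0 + self.nu)
                                           * (1.0 - 2.0 * self.nu))


@dataclass
class Pose:
    """Relative placement of femoral component and insert for one step.

    flexion_deg rotates the femoral component about its flexion axis (the
    line stored in its metadata, through the distal-radius centre); ap_mm
    translates the insert along its anterior direction, ml_mm along its
    medial direction; ie_deg rotates the insert about the vertical axis
    through its control point (origin).
    """

    flexion_deg: float = 0.0
    ap_mm: float = 0.0
    ie_deg: float = 0.0
    ml_mm: float = 0.0


@dataclass
class ContactSolution:
    pressure: np.ndarray          # MPa per insert vertex, 0 off-contact
    vertex_area: np.ndarray       # mm^2 per insert vertex
    contact_area: float           # mm^2
    resultant_force: float        # N
    equilibrium_pose: tuple       # (vertical translation mm, AA rotation deg)
    load_axis_z: float = 0.0
    converged: bool = True
    residuals: dict = field(default_factory=dict)

    def export_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["vertex_id", "pressure_mpa", "area_mm2"])
            for i, (p, a) in enumerate(zip(self.pressure, self.vertex_area)):
                w.writerow([i, f"{p:.6g}", f"{a:.6g}"])

    def summary_json(self) -> str:
        return json.dumps({
            "contact_area_mm2": self.contact_area,
            "resultant_force_n": self.resultant_force,
            "max_pressure_mpa": float(self.pressure.max(initial=0.0)),
            "equilibrium_pose": list(self.equilibrium_pose),
            "converged": self.converged,
        }, indent=2)


# --------------------------------------------------------------------------
# pressure law and Hertz oracle
# --------------------------------------------------------------------------

def foundation_pressure(penetration, mat: MaterialProperties,
                        layer_thickness: float):
    """Winkler pressure for a given penetration [mm] through a layer [mm]."""
    if layer_thickness <= 0:
        raise ValueError("layer_thickness must be > 0")
    if mat.nu >= 0.5:
        raise ValueError("nu = 0.5 is incompressible: foundation modulus "
                         "is singular")
    pen = np.asarray(penetration, dtype=float)
    p = mat.confined_modulus * np.clip(pen, 0.0, None) / layer_thickness
    return float(p) if np.isscalar(penetration) else p


def hertz_ball_on_flat(F: float, R: float, mat: MaterialProperties):
    """Closed-form Hertz contact of a rigid ball (radius R) on an elastic
    half-space: returns (contact_radius mm, area mm^2, p_max MPa)."""
    if F <= 0 or R <= 0:
        raise ValueError("F and R must be > 0")
    e_star = mat.E / (1.0 - mat.nu ** 2)
    a = (3.0 * F * R / (4.0 * e_star)) ** (1.0 / 3.0)
    area = math.pi * a * a
    p_max = 3.0 * F / (2.0 * area)
    return a, area, p_max


def calibrate_layer_thickness(mat: MaterialProperties, R: float,
                              F: float) -> float:
    """Layer depth h for which the analytic foundation ball-on-flat contact
    radius equals the Hertz radius at load F.

    For a sphere the foundation model gives a = (2 R d)^(1/2) with
    F = pi K R d^2 / h, hence h = pi K a_H^4 / (4 F R).
    """
    a_h, _, _ = hertz_ball_on_flat(F, R, mat)
    return math.pi * mat.confined_modulus * a_h ** 4 / (4.0 * F * R)


# --------------------------------------------------------------------------
# posing helpers
# --------------------------------------------------------------------------

def pose_femoral_vertices(femoral: SurfaceMesh, pose: Pose) -> np.ndarray:
    """Femoral vertices after flexion about the stored flexion axis."""
    v = femoral.vertices
    if abs(pose.flexion_deg) < 1e-15:
        return v.copy()
    pt = np.asarray(femoral.metadata.get("flexion_axis_point", (0, 0, 0)),
                    dtype=float)
    ax = np.asarray(femoral.metadata.get("flexion_axis_dir", (0, 0, 1)),
                    dtype=float)
    rot = Rotation.from_rotvec(np.deg2rad(pose.flexion_deg) * ax)
    return rot.apply(v - pt) + pt


def insert_axes(insert: SurfaceMesh):
    """(anterior, medial) unit directions of the insert body frame."""
    ant = np.asarray(insert.metadata.get("anterior_dir", (1.0, 0.0, 0.0)),
                     dtype=float)
    med = np.asarray(insert.metadata.get("medial_dir", (0.0, 0.0, 1.0)),
                     dtype=float)
    return ant, med


def pose_insert_vertices(insert: SurfaceMesh, pose: Pose) -> np.ndarray:
    """Insert vertices after IE rotation (about the vertical axis through
    the control point at the origin) and AP/ML translation."""
    v = insert.vertices
    if abs(pose.ie_deg) >= 1e-15:
        rot = Rotation.from_rotvec(np.deg2rad(pose.ie_deg)
                                   * np.array([0.0, 1.0, 0.0]))
        v = rot.apply(v)
    else:
        v = v.copy()
    ant, med = insert_axes(insert)
    v += pose.ap_mm * ant + pose.ml_mm * med
    return v


def _lower_envelope(vertices: np.ndarray) -> np.ndarray:
    """Keep, per rounded (x, z) cell, only the lowest vertex (the side of a
    closed counterface that can actually touch the insert)."""
    xz = vertices[:, [0, 2]]
    span = max(xz.max(initial=0) - xz.min(initial=0), 1e-9)
    key = np.round(xz / (span / 2000.0)).astype(np.int64)
    order = np.argsort(vertices[:, 1], kind="stable")
    seen = {}
    keep = []
    for i in order:
        k = (key[i, 0], key[i, 1])
        if k not in seen:
            seen[k] = True
            keep.append(i)
    return vertices[np.array(keep)]


class ContactError(RuntimeError):
    pass


def solve_contact(femoral: SurfaceMesh, insert: SurfaceMesh,
                  pose: Pose | None, axial_load: float,
                  mat: MaterialProperties, layer_thickness: float = 10.0,
                  load_axis_z: float = 0.0,
                  allow_aa: bool = True,
                  max_iter: int = 60) -> ContactSolution:
    """Find vertical translation (and AA rotation about the load axis) of the
    rigid counterface that balances the axial load on the foundation layer.
    """
    if axial_load < 0:
        raise ValueError("axial_load must be >= 0")
    pose = pose or Pose()
    n = len(insert.vertices)
    area = insert.vertex_area.copy()

    if axial_load == 0.0:
        return ContactSolution(np.zeros(n), area, 0.0, 0.0, (0.0, 0.0),
                               load_axis_z)

    fem_v = _lower_envelope(pose_femoral_vertices(femoral, pose))
    ins_v = pose_insert_vertices(insert, pose)
    interp = LinearNDInterpolator(fem_v[:, [0, 2]], fem_v[:, 1],
                                  fill_value=np.nan)
    y_fem = interp(ins_v[:, [0, 2]])
    gap = y_fem - ins_v[:, 1]              # clearance at u = alpha = 0
    gap[np.isnan(gap)] = np.inf
    if not np.isfinite(gap).any():
        raise ContactError("no vertical overlap between surfaces")

    k = mat.confined_modulus / layer_thickness
    _, med = insert_axes(insert)
    zeta = ins_v @ med - load_axis_z
    f_tol = FORCE_RTOL * axial_load
    m_tol = FORCE_RTOL * axial_load * MOMENT_ARM_TOL

    def residuals(u, alpha):
        pen = u + alpha * zeta - gap
        act = pen > 0
        pa = k * pen[act] * area[act]
        F = pa.sum()
        M = (pa * zeta[act]).sum()
        return F, M, act, pen

    g_min = float(np.min(gap[np.isfinite(gap)]))
    u = g_min + 1e-6
    alpha = 0.0
    hist = []
    for it in range(max_iter):
        F, M, act, pen = residuals(u, alpha)
        hist.append((F, M))
        if abs(F - axial_load) <= f_tol and abs(M) <= m_tol:
            break
        ka = k * area[act]
        j11 = ka.sum()
        j12 = (ka * zeta[act]).sum()
        j22 = (ka * zeta[act] ** 2).sum()
        if j11 <= 0:
            u += 1e-3
            continue
        if allow_aa and j22 > 0 and j11 * j22 - j12 * j12 > 1e-12 * j11 * j22 + 1e-300:
            # solve J [du, da] = [load - F, -M]
            det = j11 * j22 - j12 * j12
            b1, b2 = axial_load - F, -M
            du = (j22 * b1 - j12 * b2) / det
            da = (-j12 * b1 + j11 * b2) / det
        else:
            du = (axial_load - F) / j11
            da = 0.0
        # damping: limit steps to keep the active set from exploding
        scale = 1.0
        span = float(np.ptp(gap[np.isfinite(gap)])) or 1.0
        if abs(du) > 0.5 * span + 1.0:
            scale = (0.5 * span + 1.0) / abs(du)
        u += scale * du
        alpha += scale * da
        if u < g_min:
            u = g_min + 1e-9
    else:
        # bisection fallback on u at the last alpha
        lo, hi = g_min, g_min + 1.0
        while residuals(hi, alpha)[0] < axial_load:
            hi += max(hi - g_min, 1e-3)
            if hi - g_min > 1e6:
                raise ContactError(
                    f"contact solve failed; residual history {hist[-5:]}")
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            F, M, act, pen = residuals(mid, alpha)
            if abs(F - axial_load) <= f_tol:
                u = mid
                break
            if F < axial_load:
                lo = mid
            else:
                hi = mid
        else:
            raise ContactError(
                f"contact solve did not converge; history {hist[-5:]}")
        F, M, act, pen = residuals(u, alpha)
        if allow_aa and abs(M) > m_tol:
            raise ContactError(
                f"moment balance failed: |M|={abs(M):.4g} N mm")

    F, M, act, pen = residuals(u, alpha)
    pressure = np.where(pen > 0, k * pen, 0.0)
    contact_area = float(area[pressure > 0].sum())
    return ContactSolution(
        pressure=pressure, vertex_area=area, contact_area=contact_area,
        resultant_force=float(F),
        equilibrium_pose=(-u, math.degrees(alpha)),
        load_axis_z=load_axis_z, converged=True,
        residuals={"force": float(F - axial_load), "moment": float(M),
                   "iterations": it + 1})
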