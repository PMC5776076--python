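"""Activity kinematic profiles and multidirectional pin-on-plate trajectories.

Activity waveforms are smooth 1 s periodic composites whose extrema equal
the published values for standard walking, deep squat and stairs ascent
exactly; the waveform *shapes* between the extrema are synthetic stand-ins
(the published plots are not tabulated), and real ISO-style profiles can be
supplied as CSV instead.

Sign conventions: anterior tibial shift is negative AP motion (femoral
rollback polarity); angles are degrees at every interface and radians
internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .contact import ContactSolution, Pose, pose_insert_vertices
from .geometry import SurfaceMesh

PROFILE_COLUMNS = ("time_s", "load_N", "fe_deg", "ap_mm", "ie_deg")

# printed per-activity extrema: (max load N, max |AP| mm, FE range deg,
# IE range deg).  AP is applied with rollback polarity (negative anterior).
ACTIVITY_EXTREMA = {
    "walking": dict(load=2600.0, ap=14.0, fe=(0.0, 58.0), ie=(-5.0, 5.0)),
    "deep_squat": dict(load=2879.0, ap=17.0, fe=(0.0, 104.0), ie=(0.0, 5.0)),
    "stairs_ascent": dict(load=3008.0, ap=12.0, fe=(0.0, 60.0),
                          ie=(-5.0, 5.0)),
}
SWING_LOAD_N = 150.0       # synthetic minimum (swing-phase) axial load


@dataclass
class KinematicProfile:
    """Per-step axial load, flexion-extension, AP translation, IE rotation
    over one activity cycle.  Arrays hold n_steps + 1 samples (closed cycle:
    sample 0 and sample n_steps describe the same instant of the next cycle).
    """

    time_s: np.ndarray
    load_n: np.ndarray
    fe_deg: np.ndarray
    ap_mm: np.ndarray
    ie_deg: np.ndarray
    ml_mm: np.ndarray | None = None   # optional medial-lateral channel
    cycle_period: float = 1.0
    name: str = "custom"

    def __post_init__(self) -> None:
        arrays = [self.time_s, self.load_n, self.fe_deg, self.ap_mm,
                  self.ie_deg]
        if self.ml_mm is None:
            self.ml_mm = np.zeros_like(np.asarray(self.time_s, dtype=float))
        arrays.append(self.ml_mm)
        lens = {len(a) for a in arrays}
        if len(lens) != 1:
            raise ValueError("profile columns must have equal length")
        for nm in ("time_s", "load_n", "fe_deg", "ap_mm", "ie_deg", "ml_mm"):
            setattr(self, nm, np.asarray(getattr(self, nm), dtype=float))
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time_s must be strictly increasing")
        if np.any(self.load_n < 0):
            raise ValueError("loads must be >= 0")

    @property
    def n_steps(self) -> int:
        return len(self.time_s) - 1

    def is_cyclic(self, rtol: float = 1e-6) -> bool:
        span = lambda a: max(np.ptp(a), 1.0)
        return all(abs(a[0] - a[-1]) <= rtol * span(a)
                   for a in (self.load_n, self.fe_deg, self.ap_mm,
                             self.ie_deg, self.ml_mm))

    def pose_at(self, k: int) -> Pose:
        return Pose(flexion_deg=self.fe_deg[k], ap_mm=self.ap_mm[k],
                    ie_deg=self.ie_deg[k], ml_mm=self.ml_mm[k])


def _rescaled(shape: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Affinely map a waveform onto [lo, hi] so the extrema are bit-exact."""
    smin, smax = shape.min(), shape.max()
    if smax == smin:
        return np.full_like(shape, lo)
    out = lo + (hi - lo) * (shape - smin) / (smax - smin)
    return out


def generate_profile(activity: str, n_steps: int = 128) -> KinematicProfile:
    """Synthetic activity profile hitting the published extrema exactly.

    n_steps should be divisible by 4 so the waveform extrema fall on grid
    points (they do for the default 128).
    """
    if activity not in ACTIVITY_EXTREMA:
        raise ValueError(f"unknown activity {activity!r}; choose from "
                         f"{sorted(ACTIVITY_EXTREMA)}")
    if n_steps < 4:
        raise ValueError("n_steps must be >= 4")
    ex = ACTIVITY_EXTREMA[activity]
    t = np.arange(n_steps + 1) / n_steps
    # double-hump stance load for walking/stairs, single hump for squat
    if activity == "deep_squat":
        load_shape = np.sin(np.pi * t) ** 2
    else:
        load_shape = np.sin(2.0 * np.pi * t) ** 2 * (1.0 - 0.3 *
                                                     np.sin(np.pi * t) ** 2)
    load = _rescaled(load_shape, SWING_LOAD_N, ex["load"])
    fe = _rescaled(np.sin(np.pi * t) ** 2, *ex["fe"])
    # anterior tibial shift is negative AP
    ap = _rescaled(np.sin(np.pi * t) ** 2, 0.0, -ex["ap"])
    ie = _rescaled(np.sin(2.0 * np.pi * t), *ex["ie"])
    return KinematicProfile(t, load, fe, ap, ie, cycle_period=1.0,
                            name=activity)


# --------------------------------------------------------------------------
# profile CSV I/O
# --------------------------------------------------------------------------

def write_profile_csv(profile: KinematicProfile, path) -> None:
    df = pd.DataFrame({
        "time_s": profile.time_s, "load_N": profile.load_n,
        "fe_deg": profile.fe_deg, "ap_mm": profile.ap_mm,
        "ie_deg": profile.ie_deg,
    })
    if np.any(profile.ml_mm != 0):
        df["ml_mm"] = profile.ml_mm
    df.to_csv(path, index=False, float_format="%.17g")


def read_profile_csv(path) -> KinematicProfile:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"profile CSV missing columns: {missing}")
    ml = df["ml_mm"].to_numpy() if "ml_mm" in df.columns else None
    return KinematicProfile(
        df["time_s"].to_numpy(), df["load_N"].to_numpy(),
        df["fe_deg"].to_numpy(), df["ap_mm"].to_numpy(),
        df["ie_deg"].to_numpy(), ml_mm=ml)


# --------------------------------------------------------------------------
# pin-on-plate trajectories
# --------------------------------------------------------------------------

@dataclass
class PinOnPlateConfig:
    """One multidirectional pin-on-plate condition: reciprocating plate
    stroke with an in-phase pin rotation about the pin axis."""

    pin_diameter: float           # mm
    load: float                   # N
    stroke_length: float          # mm, peak-to-peak plate travel
    rotation_amplitude: float     # +-deg pin rotation
    frequency: float = 1.0        # Hz
    in_phase: bool = True
    n_steps: int = 128
    weeks: float = 2.0            # test period (cycle bookkeeping)

    def __post_init__(self) -> None:
        if self.pin_diameter <= 0 or self.load <= 0:
            raise ValueError("pin_diameter and load must be > 0")
        if self.stroke_length < 0 or self.rotation_amplitude < 0:
            raise ValueError("stroke and rotation amplitude must be >= 0")
        if self.n_steps <= 0:
            raise ValueError("n_steps must be > 0")

    @property
    def pin_area(self) -> float:
        return np.pi * (self.pin_diameter / 2.0) ** 2

    @property
    def nominal_stress(self) -> float:
        return self.load / self.pin_area

    @property
    def total_cycles(self) -> float:
        """Cycle count for the configured test period ("two weeks" of the
        published protocol corresponds to 660,000 cycles)."""
        return self.weeks * CYCLES_PER_WEEK

    @classmethod
    def from_yaml(cls, path) -> "PinOnPlateConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


CYCLES_PER_WEEK = 330000.0   # "two weeks (660,000 cycles)"


@dataclass
class SlidingIncrement:
    """Tangential relative displacement of the counterface with respect to
    the polyethylene surface points over one time step, expressed in the
    polyethylene body frame, plus the acting pressure and point areas."""

    displacement: np.ndarray      # (n_pts, 3) mm, tangent-plane vectors
    pressure: np.ndarray          # (n_pts,) MPa
    vertex_area: np.ndarray       # (n_pts,) mm^2


def pin_face_sample_points(diameter: float, n_radial: int = 16,
                           n_angular: int = 32):
    """Polar area-weighted sampling of the pin face: returns (points (n,3)
    with y=0, weights mm^2 summing to the face area)."""
    r_edges = np.linspace(0.0, diameter / 2.0, n_radial + 1)
    r_mid = 0.5 * (r_edges[:-1] + r_edges[1:])
    ring_area = np.pi * (r_edges[1:] ** 2 - r_edges[:-1] ** 2) / n_angular
    th = (np.arange(n_angular) + 0.5) / n_angular * 2.0 * np.pi
    R, TH = np.meshgrid(r_mid, th, indexing="ij")
    pts = np.column_stack([(R * np.cos(TH)).ravel(),
                           np.zeros(R.size),
                           (R * np.sin(TH)).ravel()])
    w = np.repeat(ring_area, n_angular)
    return pts, w


def pop_trajectory(cfg: PinOnPlateConfig, sample_points: np.ndarray,
                   weights: np.ndarray | None = None,
                   pressure: float | None = None) -> list[SlidingIncrement]:
    """Sliding increments over one cycle at points on the pin face.

    Plate displacement x(t) = (stroke/2) cos(2 pi f t) and pin rotation
    theta(t) = amplitude cos(2 pi f t) share the same cosine phase.  The
    increment at a pin material point is the relative displacement of the
    plate with respect to that point, rotated into the pin body frame.
    """
    pts = np.asarray(sample_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("sample_points must be (n, 3)")
    r = np.hypot(pts[:, 0], pts[:, 2])
    if np.any(r > cfg.pin_diameter / 2.0 + 1e-9):
        raise ValueError("sample points must lie on the pin face")
    if weights is None:
        weights = np.full(len(pts), cfg.pin_area / len(pts))
    p = cfg.nominal_stress if pressure is None else pressure

    n = cfg.n_steps
    t = np.arange(n + 1) / n / cfg.frequency
    phase = 2.0 * np.pi * cfg.frequency * t
    amp = np.deg2rad(cfg.rotation_amplitude)
    if not cfg.in_phase:
        theta = amp * np.sin(phase)
    else:
        theta = amp * np.cos(phase)
    xplate = (cfg.stroke_length / 2.0) * np.cos(phase)

    # pin-face tangent plane is the xz plane; work in (x, z) 2-vectors
    xz = pts[:, [0, 2]]
    incs = []
    press = np.full(len(pts), p)
    for k in range(n):
        th0, th1 = theta[k], theta[k + 1]
        thm = 0.5 * (th0 + th1)
        # lab displacement of plate relative to the pin material points:
        # plate moves dx in x; pin points move along their rotation arcs
        c0, s0 = np.cos(th0), np.sin(th0)
        c1, s1 = np.cos(th1), np.sin(th1)
        # rotation about the vertical (y) axis maps (x, z) ->
        # (x cos th - z sin th, x sin th + z cos th)
        p0 = np.column_stack([xz[:, 0] * c0 - xz[:, 1] * s0,
                              xz[:, 0] * s0 + xz[:, 1] * c0])
        p1 = np.column_stack([xz[:, 0] * c1 - xz[:, 1] * s1,
                              xz[:, 0] * s1 + xz[:, 1] * c1])
        d_lab = np.empty_like(p0)
        d_lab[:, 0] = (xplate[k + 1] - xplate[k]) - (p1[:, 0] - p0[:, 0])
        d_lab[:, 1] = -(p1[:, 1] - p0[:, 1])
        # express in the pin body frame at mid-step (rotate by -theta_mid)
        cm, sm = np.cos(-thm), np.sin(-thm)
        d_body = np.column_stack([d_lab[:, 0] * cm - d_lab[:, 1] * sm,
                                  d_lab[:, 0] * sm + d_lab[:, 1] * cm])
        disp3 = np.column_stack([d_body[:, 0],
                                 np.zeros(len(pts)),
                                 d_body[:, 1]])
        incs.append(SlidingIncrement(disp3, press.copy(), weights.copy()))
    return incs


# --------------------------------------------------------------------------
# knee step sliding
# --------------------------------------------------------------------------

def knee_step_sliding(femoral: SurfaceMesh, insert: SurfaceMesh,
                      pose_a: Pose, pose_b: Pose,
                      contact: ContactSolution,
                      equilibrium_a: tuple | None = None,
                      equilibrium_b: tuple | None = None
                      ) -> SlidingIncrement:
    """Tangential relative motion of the femoral surface against each
    loaded insert vertex between two consecutive poses of one profile.

    The femoral material point considered at each insert vertex is the one
    vertically above it at pose_a; its displacement between the two poses,
    minus the insert vertex's own displacement, is projected onto the
    insert tangent plane and expressed in the insert body frame.
    """
    from scipy.spatial.transform import Rotation

    act = contact.pressure > 0
    n_all = len(insert.vertices)
    disp = np.zeros((n_all, 3))
    if act.any():
        # femoral body points above the loaded insert vertices at pose_a;
        # a flexion-invariant femoral surface may be interpolated unflexed
        if femoral.metadata.get("flexion_invariant"):
            interp_pose = Pose(0.0, pose_a.ap_mm, pose_a.ie_deg,
                               pose_a.ml_mm)
        else:
            interp_pose = pose_a
        fem_a = _posed_femoral(femoral, interp_pose, equilibrium_a)
        from scipy.interpolate import LinearNDInterpolator
        from .contact import _lower_envelope
        fl = _lower_envelope(fem_a)
        interp = LinearNDInterpolator(fl[:, [0, 2]], fl[:, 1],
                                      fill_value=np.nan)
        ins_a = pose_insert_vertices(insert, pose_a)
        lab_a = ins_a[act].copy()
        yf = interp(lab_a[:, [0, 2]])
        ok = ~np.isnan(yf)
        lab_a[ok, 1] = yf[ok]
        # pull the femoral contact points back into femoral body coords
        fem_body = _unpose_femoral(femoral, pose_a, equilibrium_a, lab_a)
        # push them forward through pose_b
        lab_b = _apply_femoral(femoral, pose_b, equilibrium_b, fem_body)
        df = lab_b - lab_a
        # insert vertex displacement between poses
        ins_b = pose_insert_vertices(insert, pose_b)
        di = ins_b[act] - ins_a[act]
        rel = df - di
        # rotate into insert body frame at pose_a (undo IE rotation)
        if abs(pose_a.ie_deg) >= 1e-15:
            rot = Rotation.from_rotvec(np.deg2rad(-pose_a.ie_deg)
                                       * np.array([0.0, 1.0, 0.0]))
            rel = rot.apply(rel)
        nrm = insert.vertex_normal[act]
        rel -= (np.einsum("ij,ij->i", rel, nrm))[:, None] * nrm
        disp[act] = rel
    return SlidingIncrement(disp, contact.pressure.copy(),
                            insert.vertex_area.copy())


def _femoral_frames(femoral: SurfaceMesh, pose: Pose, equilibrium):
    pt = np.asarray(femoral.metadata.get("flexion_axis_point", (0, 0, 0)),
                    dtype=float)
    ax = np.asarray(femoral.metadata.get("flexion_axis_dir", (0, 0, 1)),
                    dtype=float)
    from scipy.spatial.transform import Rotation
    rot = Rotation.from_rotvec(np.deg2rad(pose.flexion_deg) * ax)
    dy = 0.0 if equilibrium is None else float(equilibrium[0])
    return pt, rot, dy


def _posed_femoral(femoral, pose, equilibrium):
    pt, rot, dy = _femoral_frames(femoral, pose, equilibrium)
    v = rot.apply(femoral.vertices - pt) + pt
    v[:, 1] += dy
    return v


def _apply_femoral(femoral, pose, equilibrium, body_points):
    pt, rot, dy = _femoral_frames(femoral, pose, equilibrium)
    v = rot.apply(body_points - pt) + pt
    v[:, 1] += dy
    return v


def _unpose_femoral(femoral, pose, equilibrium, lab_points):
    pt, rot, dy = _femoral_frames(femoral, pose, equilibrium)
    v = lab_points.copy()
    v[:, 1] -= dy
    return rot.inv().apply(v - pt) + pt
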