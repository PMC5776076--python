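"""Inverse identification of compressive material properties from measured
contact areas.

Two model-generated calibration curves are built and inverted:

* Poisson's ratio — a 12 mm diameter, 10.2 mm long polyethylene cylinder is
  compressed 1 mm between rigid platens (displacement control, so the
  end-face contact area is independent of the elastic modulus).  The full
  elastic boundary-value problem is replaced by an axisymmetric bonded-end
  barreling approximation: the lateral bulge is a parabolic profile pinned
  at the bonded ends whose magnitude conserves the elastic volume change
  Delta V = -V0 eps (1 - 2 nu), and a fixed fraction of the near-end bulge
  folds onto the platen as extra footprint.  Only the monotone
  area-vs-parameter relationship (and hence the inversion) is contractual,
  not absolute agreement with any particular measurement.

* Equivalent elastic modulus — a rigid 63.5 mm ball is pressed into a flat
  10 mm polyethylene specimen at the 500 N peak of a 0-500 N sinusoidal
  load; the contact area comes from the Hertz-calibrated elastic-foundation
  backend and decreases with E.  Creep under the dynamic load is absorbed
  into the "equivalent" modulus.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.interpolate import PchipInterpolator

from .contact import (MaterialProperties, calibrate_layer_thickness,
                      hertz_ball_on_flat, solve_contact)
from .geometry import make_primitive

FOLDOVER_FRACTION = 0.5     # fraction of the end bulge contacting the platen


@dataclass
class CalibrationCurve:
    """Monotone (parameter, predicted contact area mm^2) relationship."""

    parameter: np.ndarray
    area: np.ndarray
    kind: str = "generic"
    _interp: PchipInterpolator = field(init=False, repr=False)
    _inverse: PchipInterpolator = field(init=False, repr=False)

    def __post_init__(self) -> None:
        p = np.asarray(self.parameter, dtype=float)
        a = np.asarray(self.area, dtype=float)
        if len(p) < 5:
            raise ValueError("need >= 5 support points")
        order = np.argsort(p)
        p, a = p[order], a[order]
        d = np.diff(a)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("calibration curve is not strictly monotone "
                             f"in the parameter ({self.kind})")
        self.parameter, self.area = p, a
        self._interp = PchipInterpolator(p, a)
        if d[0] > 0:
            self._inverse = PchipInterpolator(a, p)
        else:
            self._inverse = PchipInterpolator(a[::-1], p[::-1])

    def predict_area(self, parameter):
        return self._interp(parameter)

    def invert(self, measured_area: float) -> float:
        lo, hi = self.area.min(), self.area.max()
        if not (lo <= measured_area <= hi):
            raise ValueError(
                f"measured area {measured_area:.4g} mm^2 outside the "
                f"calibrated range [{lo:.4g}, {hi:.4g}]; extrapolation "
                "refused")
        return float(self._inverse(measured_area))

    def export_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["parameter", "area_mm2"])
            for p, a in zip(self.parameter, self.area):
                w.writerow([f"{p:.6g}", f"{a:.6g}"])


def invert(curve: CalibrationCurve, measured_area: float) -> float:
    return curve.invert(measured_area)


# --------------------------------------------------------------------------
# Poisson's ratio: bonded-end cylinder compression
# --------------------------------------------------------------------------

def cylinder_end_contact_area(nu: float, diameter: float = 12.0,
                              length: float = 10.2,
                              compression: float = 1.0) -> float:
    """End-face footprint of the bonded-end barreling approximation [mm^2].

    Independent of E by construction (displacement control); nu = 0 gives
    exactly the nominal face area (no lateral expansion).
    """
    if not (0.0 <= nu < 0.5):
        raise ValueError("nu must be in [0, 0.5)")
    r0 = diameter / 2.0
    eps = compression / length
    l1 = length - compression
    v1 = np.pi * r0 * r0 * length * (1.0 - eps * (1.0 - 2.0 * nu))
    # parabolic barrel r(xi) = r0 + dr (1 - xi^2), xi in [-1, 1]:
    # V = pi l1 (r0^2 + (4/3) r0 dr + (8/15) dr^2); solve for dr >= 0
    a = (8.0 / 15.0) * np.pi * l1
    b = (4.0 / 3.0) * np.pi * l1 * r0
    c = np.pi * l1 * r0 * r0 - v1
    disc = b * b - 4.0 * a * c
    dr = (-b + np.sqrt(max(disc, 0.0))) / (2.0 * a)
    r_eff = r0 + FOLDOVER_FRACTION * max(dr, 0.0)
    return float(np.pi * r_eff * r_eff)


def build_poisson_curve(cyl_diameter: float = 12.0, length: float = 10.2,
                        compression: float = 1.0, E_any: float = 553.0,
                        nu_grid=None) -> CalibrationCurve:
    """Contact-area-vs-Poisson's-ratio calibration (E plays no role)."""
    if nu_grid is None:
        nu_grid = np.linspace(0.05, 0.48, 16)
    nu_grid = np.asarray(nu_grid, dtype=float)
    if np.any(nu_grid < 0) or np.any(nu_grid > 0.49):
        raise ValueError("nu_grid must lie within [0, 0.49]")
    areas = [cylinder_end_contact_area(nu, cyl_diameter, length,
                                       compression) for nu in nu_grid]
    return CalibrationCurve(nu_grid, np.asarray(areas), kind="poisson")


# --------------------------------------------------------------------------
# equivalent modulus: ball-on-flat at peak load
# --------------------------------------------------------------------------

def ball_on_flat_contact_area(E: float, nu: float = 0.32,
                              ball_diameter: float = 63.5,
                              load: float = 500.0,
                              grid: int = 96) -> float:
    """Contact area [mm^2] of a rigid ball on the foundation layer, with
    the layer depth Hertz-calibrated per material."""
    mat = MaterialProperties(E=E, nu=nu)
    R = ball_diameter / 2.0
    h = calibrate_layer_thickness(mat, R, load)
    ball = make_primitive("sphere", diameter=ball_diameter, grid=grid)
    # apex of the lower hemisphere just touching the plate at y = 0
    v = ball.vertices.copy()
    v[:, 1] += R
    ball = ball.with_vertices(v)
    # mesh only the specimen region around the expected contact patch
    a_h, _, _ = hertz_ball_on_flat(load, R, mat)
    w = 6.0 * a_h
    plate = make_primitive("flat_plate", width=w, length=w, grid=grid)
    sol = solve_contact(ball, plate, None, load, mat, layer_thickness=h,
                        allow_aa=False)
    # spherical-cap area 2 pi R d from the solved peak penetration: smooth
    # in E, whereas the vertex-area sum is quantised by the mesh
    d_max = sol.pressure.max() * h / mat.confined_modulus
    return float(2.0 * np.pi * R * d_max)


def build_modulus_curve(ball_diameter: float = 63.5,
                        mean_load: float = 250.0, nu: float = 0.32,
                        E_grid=None, grid: int = 96) -> CalibrationCurve:
    """Contact-area-vs-modulus calibration at the load peak (2 x mean)."""
    if E_grid is None:
        E_grid = np.linspace(300.0, 900.0, 9)
    E_grid = np.asarray(E_grid, dtype=float)
    if E_grid.size < 5:
        raise ValueError("E_grid needs >= 5 points")
    peak = 2.0 * mean_load
    areas = [ball_on_flat_contact_area(E, nu, ball_diameter, peak, grid)
             for E in E_grid]
    return CalibrationCurve(E_grid, np.asarray(areas), kind="modulus")


# --------------------------------------------------------------------------
# specimen-set estimates
# --------------------------------------------------------------------------

def estimate_from_areas(curve: CalibrationCurve, areas,
                        confidence: float = 0.95) -> dict:
    """Invert several specimen areas; mean +- t-based CI half-width."""
    vals = np.array([curve.invert(float(a)) for a in np.asarray(areas)])
    n = len(vals)
    mean = float(vals.mean())
    if n > 1 and vals.std(ddof=1) > 0:
        half = float(stats.t.ppf(0.5 + confidence / 2.0, n - 1)
                     * vals.std(ddof=1) / np.sqrt(n))
    else:
        half = 0.0
    return {"kind": curve.kind, "n": n, "estimate": mean,
            "ci_halfwidth": half, "values": vals.tolist()}


def estimates_json(result: dict) -> str:
    return json.dumps(result, indent=2)
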