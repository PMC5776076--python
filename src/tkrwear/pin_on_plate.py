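"""End-to-end simulation and data reduction of multidirectional
pin-on-plate wear tests (flat UHMWPE pin on a reciprocating CoCr plate with
in-phase pin rotation).

The published test matrix spans nominal contact stresses of 4-80 MPa and
cross-shear ratios of 0 (unidirectional) to 0.18; `published_conditions`
bundles those twelve conditions.  Nominal (uniform) pressure is assumed on
the pin face, CS is the area-weighted face average of the per-point
cross-shear ratios, and the per-cycle sliding distance is the centre-point
path length (2 x stroke for the reciprocating plate).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .contact import MaterialProperties
from .kinematics import (CYCLES_PER_WEEK, PinOnPlateConfig,
                         pin_face_sample_points, pop_trajectory)
from .tribology import (FrictionalWorkTensor, WearCoefficientModel,
                        coefficient_from_measurement, cross_shear_field,
                        mass_to_volume, volumetric_wear, wear_coefficient)


@dataclass
class PopResult:
    nominal_stress: float         # MPa
    p_over_e: float               # [-]
    cs_face_avg: float            # [-]
    cs_center: float              # [-]
    sliding_per_cycle: float      # mm
    predicted_c: float            # [-]
    wear_rate_mm3_per_mc: float   # mm^3 per million cycles

    def as_dict(self) -> dict:
        return asdict(self)


# the twelve published test conditions (pin diameter mm, load N, stroke mm,
# rotation +-deg, test weeks); stresses/CS are derived, not stored
_TEST_MATRIX = """pin_diameter_mm,load_N,stroke_mm,rotation_deg,weeks
5,80,28,30,3
5,216,28,30,3
4,252,28,30,3
3,212,28,30,3
3,283,28,30,3
2,252,28,30,3
5,216,28,0,2
5,216,10,10,2
5,216,12,15,2
5,216,26,45,2
5,80,10,10,2
2,252,10,10,2
"""


def published_conditions() -> pd.DataFrame:
    """Bundled pin-on-plate test matrix (one row per condition)."""
    return pd.read_csv(io.StringIO(_TEST_MATRIX))


def configs_from_table(df: pd.DataFrame, n_steps: int = 128
                       ) -> list[PinOnPlateConfig]:
    required = {"pin_diameter_mm", "load_N", "stroke_mm", "rotation_deg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"test matrix missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        out.append(PinOnPlateConfig(
            pin_diameter=float(row["pin_diameter_mm"]),
            load=float(row["load_N"]),
            stroke_length=float(row["stroke_mm"]),
            rotation_amplitude=float(row["rotation_deg"]),
            weeks=float(row.get("weeks", 2.0)),
            n_steps=n_steps))
    return out


def face_average_cross_shear(cfg: PinOnPlateConfig,
                             mat: MaterialProperties,
                             n_radial: int = 16, n_angular: int = 32):
    """Area-weighted face-averaged CS plus the centre-point CS.

    Points with zero accumulated work (a motionless test) are excluded;
    an all-zero-work face has CS = 0 by the non-wearing convention.
    """
    pts, w = pin_face_sample_points(cfg.pin_diameter, n_radial, n_angular)
    # append the exact centre point for the centre-point value
    pts_all = np.vstack([pts, [[0.0, 0.0, 0.0]]])
    w_all = np.concatenate([w, [0.0]])
    incs = pop_trajectory(cfg, pts_all, w_all)
    tensors = FrictionalWorkTensor(len(pts_all))
    ones = np.ones(len(pts_all))
    for inc in incs:
        tensors.accumulate(inc.displacement[:, [0, 2]],
                           np.full(len(pts_all), cfg.nominal_stress),
                           ones, mat.mu)
    cs = cross_shear_field(tensors)
    face_cs = cs[:-1]
    ok = ~np.isnan(face_cs)
    if not ok.any():
        return 0.0, 0.0
    avg = float(np.average(face_cs[ok], weights=w[ok]))
    center = float(cs[-1]) if not np.isnan(cs[-1]) else 0.0
    return avg, center


def sliding_per_cycle(cfg: PinOnPlateConfig) -> float:
    """Centre-point path length over one cycle (= 2 x stroke)."""
    center = np.zeros((1, 3))
    incs = pop_trajectory(cfg, center, np.array([cfg.pin_area]))
    return float(sum(np.linalg.norm(inc.displacement[0]) for inc in incs))


def run_pop(cfg: PinOnPlateConfig, mat: MaterialProperties | None = None,
            model: WearCoefficientModel | None = None,
            n_radial: int = 16, n_angular: int = 32) -> PopResult:
    """Predict the wear rate of one pin-on-plate condition."""
    mat = mat or MaterialProperties()
    model = model or WearCoefficientModel()
    p = cfg.nominal_stress
    cs_avg, cs_center = face_average_cross_shear(cfg, mat, n_radial,
                                                 n_angular)
    s = sliding_per_cycle(cfg)
    c = wear_coefficient(model, cs_avg, p / mat.E)
    w_cycle = volumetric_wear(cfg.pin_area, s, c)
    return PopResult(
        nominal_stress=p, p_over_e=p / mat.E, cs_face_avg=cs_avg,
        cs_center=cs_center, sliding_per_cycle=s, predicted_c=c,
        wear_rate_mm3_per_mc=w_cycle * 1e6)


def run_pop_table(df: pd.DataFrame, mat: MaterialProperties | None = None,
                  model: WearCoefficientModel | None = None,
                  n_steps: int = 128) -> pd.DataFrame:
    """Run every condition of a test matrix; returns the matrix columns
    plus derived stresses, CS, and wear predictions."""
    mat = mat or MaterialProperties()
    model = model or WearCoefficientModel()
    rows = []
    for cfg, (_, row) in zip(configs_from_table(df, n_steps), df.iterrows()):
        res = run_pop(cfg, mat, model)
        rec = dict(row)
        rec.update(stress_mpa=res.nominal_stress, p_over_e=res.p_over_e,
                   cs=res.cs_face_avg, cs_center=res.cs_center,
                   sliding_mm_per_cycle=res.sliding_per_cycle,
                   predicted_c=res.predicted_c,
                   wear_rate_mm3_per_mc=res.wear_rate_mm3_per_mc)
        rows.append(rec)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# experimental data reduction
# --------------------------------------------------------------------------

def reduce_experiment(weights: pd.DataFrame, cfg: PinOnPlateConfig,
                      rho: float = 0.93, confidence: float = 0.95):
    """Wear coefficients from gravimetric pin weight loss.

    `weights` needs columns specimen_id, mass_loss_mg and either cycles or
    a weeks column (two weeks = 660,000 cycles).  Returns (per-specimen
    DataFrame, mean C, 95% CI half-width).
    """
    df = weights.copy()
    if "mass_loss_mg" not in df.columns:
        raise ValueError("weights table needs a mass_loss_mg column")
    if "cycles" not in df.columns:
        if "weeks" in df.columns:
            df["cycles"] = df["weeks"] * CYCLES_PER_WEEK
        else:
            raise ValueError("weights table needs cycles (or weeks)")
    if len(df) < 1:
        raise ValueError("need at least one specimen")
    s_cycle = sliding_per_cycle(cfg)
    vol = mass_to_volume(df["mass_loss_mg"].to_numpy(), rho)
    s_total = s_cycle * df["cycles"].to_numpy()
    c = coefficient_from_measurement(vol, cfg.pin_area, s_total)
    df = df.assign(wear_volume_mm3=vol, sliding_total_mm=s_total,
                   wear_coefficient=c)
    mean = float(np.mean(c))
    n = len(c)
    if n > 1 and np.std(c, ddof=1) > 0:
        se = float(np.std(c, ddof=1) / np.sqrt(n))
        half = float(stats.t.ppf(0.5 + confidence / 2.0, n - 1) * se)
    else:
        half = 0.0
    return df, mean, half


def anova_oneway(groups) -> tuple[float, float]:
    """Convenience one-way ANOVA across specimen groups: (F, p)."""
    f, p = stats.f_oneway(*[np.asarray(g, dtype=float) for g in groups])
    return float(f), float(p)
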