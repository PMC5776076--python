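"""Cross-shear-dependent polyethylene wear law.

Wear volume follows the contact-area form of Archard's law,

    W = A * S * C,        delta = S * C        (linear depth),

with a non-dimensional wear coefficient C that depends on the cross-shear
ratio CS and the non-dimensional contact stress P/E:

    C(CS, P/E) = a * (1 - exp(-b * CS)) * (c + d * (P/E)**e).

The published fitted surface for moderately cross-linked UHMWPE
(GUR 1020, 5 Mrad) has a = 1.47e-9, b = 116.21, c = 0.84, d = 450.23,
e = 1.49.

CS derives from the unified theory of wear and frictional work: per node a
symmetric 2x2 frictional-work tensor M = sum mu p a |ds| u u^T accumulates
over the sliding increments of one cycle (u = ds/|ds| in the local tangent
plane).  The principal molecular orientation (PMO) is the eigenvector of
the larger eigenvalue (direction accruing the most frictional work) and

    CS = E_cross / E_total = lambda_min / (lambda_min + lambda_max),

bounded in [0, 0.5] and invariant to the choice of tangent-plane basis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import yaml
from scipy.optimize import curve_fit


class ZeroWorkError(ValueError):
    """Raised when CS is requested for a node with zero total frictional
    work; callers treat such nodes as non-wearing."""


# --------------------------------------------------------------------------
# frictional-work tensor and cross-shear ratio
# --------------------------------------------------------------------------

class FrictionalWorkTensor:
    """Per-node accumulated 2x2 frictional-work tensors [N mm].

    Increments are 2D tangent-plane sliding vectors; the work weight of an
    increment is mu * p * a * |ds|.
    """

    def __init__(self, n_nodes: int):
        self.M = np.zeros((n_nodes, 2, 2))

    def accumulate(self, ds: np.ndarray, pressure: np.ndarray,
                   area: np.ndarray, mu: float) -> None:
        ds = np.asarray(ds, dtype=float)
        if ds.ndim != 2 or ds.shape != (len(self.M), 2):
            raise ValueError("ds must be (n_nodes, 2) tangent vectors")
        mag = np.linalg.norm(ds, axis=1)
        act = mag > 0
        u = ds[act] / mag[act, None]
        w = mu * np.asarray(pressure)[act] * np.asarray(area)[act] * mag[act]
        self.M[act] += w[:, None, None] * np.einsum("ij,ik->ijk", u, u)

    @property
    def total_work(self) -> np.ndarray:
        return np.trace(self.M, axis1=1, axis2=2)


def cross_shear(M: np.ndarray):
    """Cross-shear ratio and PMO direction of one 2x2 work tensor.

    Returns (CS in [0, 0.5], pmo unit 2-vector).  Degenerate (isotropic)
    tensors give CS = 0.5 with the lowest-index basis vector as PMO.
    """
    M = np.asarray(M, dtype=float)
    tr = M[0, 0] + M[1, 1]
    if tr <= 0:
        raise ZeroWorkError("zero total frictional work: CS undefined")
    evals, evecs = np.linalg.eigh(M)
    lam_min, lam_max = max(evals[0], 0.0), evals[1]
    if lam_max - lam_min <= 1e-12 * tr:
        return 0.5, np.array([1.0, 0.0])
    cs = lam_min / (lam_min + lam_max)
    pmo = evecs[:, 1]
    # deterministic sign: first nonzero component positive
    if pmo[0] < 0 or (pmo[0] == 0 and pmo[1] < 0):
        pmo = -pmo
    return float(cs), pmo


def cross_shear_field(tensors: FrictionalWorkTensor):
    """Vectorised CS over all nodes; nodes with zero work get CS = nan."""
    M = tensors.M
    tr = tensors.total_work
    cs = np.full(len(M), np.nan)
    act = tr > 0
    if act.any():
        evals = np.linalg.eigvalsh(M[act])
        lam_min = np.clip(evals[:, 0], 0.0, None)
        lam_max = evals[:, 1]
        cs[act] = lam_min / (lam_min + lam_max)
    return cs


# --------------------------------------------------------------------------
# wear-coefficient surface
# --------------------------------------------------------------------------

@dataclass
class WearCoefficientModel:
    """Parameters of C(CS, P/E) = scale (1 - e^{-cs_rate CS})
    (offset + stress_gain (P/E)^stress_exp); defaults are the published
    fit for moderately cross-linked UHMWPE."""

    scale: float = 1.47e-9
    cs_rate: float = 116.21
    offset: float = 0.84
    stress_gain: float = 450.23
    stress_exp: float = 1.49

    def __post_init__(self) -> None:
        for k, v in asdict(self).items():
            if v < 0:
                raise ValueError(f"{k} must be >= 0, got {v}")
            setattr(self, k, float(v))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "WearCoefficientModel":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def wear_coefficient(model: WearCoefficientModel, cs, p_over_e):
    """Non-dimensional wear coefficient C(CS, P/E)."""
    cs = np.asarray(cs, dtype=float)
    x = np.asarray(p_over_e, dtype=float)
    if np.any(cs < 0) or np.any(x < 0):
        raise ValueError("CS and P/E must be >= 0")
    c = model.scale * (1.0 - np.exp(-model.cs_rate * cs)) \
        * (model.offset + model.stress_gain * x ** model.stress_exp)
    return float(c) if c.ndim == 0 else c


def linear_wear(S, C):
    """Linear wear depth delta = S * C [mm]."""
    return S * C


def volumetric_wear(A, S, C):
    """Wear volume W = A * S * C [mm^3]."""
    return A * S * C


def coefficient_from_measurement(W, A, S):
    """Invert the wear law: C = W / (A * S)."""
    denom = A * S
    if np.any(np.asarray(denom) <= 0):
        raise ValueError("A * S must be > 0")
    return W / denom


def mass_to_volume(delta_mass_mg, rho: float = 0.93):
    """Gravimetric conversion: volume [mm^3] = mass [mg] / rho [mg/mm^3]."""
    if rho <= 0:
        raise ValueError("rho must be > 0")
    return delta_mass_mg / rho


# --------------------------------------------------------------------------
# coefficient-surface fitting
# --------------------------------------------------------------------------

class FitError(RuntimeError):
    def __init__(self, msg, history=None):
        super().__init__(msg)
        self.history = history or []


def r_squared(predicted, observed) -> float:
    """Squared Pearson correlation between predicted and observed.

    Note this is the correlation convention of the coefficient of
    determination (symmetric in its arguments, insensitive to affine
    offsets), not 1 - SS_res/SS_tot.
    """
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape or p.size < 2:
        raise ValueError("need two equal-length vectors of size >= 2")
    dp, do = p - p.mean(), o - o.mean()
    denom = np.sqrt((dp ** 2).sum() * (do ** 2).sum())
    if denom == 0:
        return 1.0 if np.allclose(dp, do) else 0.0
    r = float((dp * do).sum() / denom)
    return r * r


def fit_coefficient_model(observations, init: WearCoefficientModel | None
                          = None, fixed_scale: float = 1.47e-9,
                          seed: int = 0):
    """Nonlinear least squares of the coefficient surface on (CS, P/E, C)
    observations.

    The surface a(1-e^{-b CS})(c + d x^e) has an exact a <-> (c, d) scale
    degeneracy, so the scale a is held fixed (default the published value)
    and only the shape parameters b, c, d, e are free.  Residuals are taken
    on C directly.  Returns (WearCoefficientModel, R^2 of the fit).
    """
    obs = np.asarray(observations, dtype=float)
    if obs.ndim != 2 or obs.shape[1] != 3:
        raise ValueError("observations must be (n, 3): cs, p_over_e, c")
    if len(obs) < 5:
        raise ValueError("need >= 5 observations")
    cs, x, c_obs = obs.T
    if np.ptp(cs) <= 0:
        raise FitError("unidentifiable cs_rate: no CS variation in the "
                       "observations")
    if np.ptp(x) <= 0:
        raise FitError("unidentifiable stress terms: no P/E variation")

    a = fixed_scale

    # fit on C/a so residuals are O(1); identical least-squares problem
    def f(X, b, c, d, e):
        cs_, x_ = X
        return (1.0 - np.exp(-b * cs_)) * (c + d * x_ ** e)

    init = init or WearCoefficientModel(scale=a, cs_rate=100.0, offset=1.0,
                                        stress_gain=400.0, stress_exp=1.5)
    p0 = [init.cs_rate, init.offset, init.stress_gain, init.stress_exp]
    rng = np.random.default_rng(seed)
    history = []
    starts = [np.asarray(p0, dtype=float)]
    starts += [np.asarray(p0) * rng.uniform(0.3, 3.0, size=4)
               for _ in range(5)]
    c_scaled = c_obs / a
    for start in starts:
        try:
            popt, _ = curve_fit(f, (cs, x), c_scaled, p0=start,
                                bounds=(0.0, np.inf), maxfev=20000)
        except (RuntimeError, ValueError) as err:
            history.append((list(start), str(err)))
            continue
        pred = a * f((cs, x), *popt)
        resid = float(((pred - c_obs) ** 2).sum())
        history.append((list(start), resid))
        model = WearCoefficientModel(scale=a, cs_rate=popt[0],
                                     offset=popt[1], stress_gain=popt[2],
                                     stress_exp=popt[3])
        return model, r_squared(pred, c_obs)
    raise FitError("coefficient fit did not converge from any start",
                   history)
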