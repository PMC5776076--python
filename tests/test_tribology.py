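import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tkrwear import (WearCoefficientModel, coefficient_from_measurement,
                     cross_shear, fit_coefficient_model, linear_wear,
                     mass_to_volume, r_squared, volumetric_wear,
                     wear_coefficient)
from tkrwear.tribology import (FitError, FrictionalWorkTensor, ZeroWorkError,
                               cross_shear_field)


def brute_force_cs(M, step_deg=1.0):
    """Independent oracle: scan tangent-plane orientations and minimise the
    cross (perpendicular) work fraction."""
    best = np.inf
    tr = np.trace(M)
    for ang in np.arange(0.0, 180.0, step_deg):
        n = np.array([np.cos(np.radians(ang)), np.sin(np.radians(ang))])
        cross = tr - n @ M @ n
        best = min(best, cross / tr)
    return best


def random_work_tensor(rng):
    """PSD tensor from a handful of random sliding increments."""
    M = np.zeros((2, 2))
    for _ in range(rng.integers(2, 8)):
        ang = rng.uniform(0, 2 * np.pi)
        u = np.array([np.cos(ang), np.sin(ang)])
        M += rng.uniform(0.1, 5.0) * np.outer(u, u)
    return M


class TestCrossShear:
    def test_collinear_increments_give_zero(self):
        u = np.array([0.6, 0.8])
        assert cross_shear(3.7 * np.outer(u, u))[0] == pytest.approx(0.0,
                                                                     abs=1e-12)

    def test_isotropic_tensor_gives_half_and_deterministic_pmo(self):
        cs, pmo = cross_shear(np.eye(2) * 2.0)
        assert cs == 0.5
        assert np.allclose(pmo, [1.0, 0.0])

    def test_zero_work_raises(self):
        with pytest.raises(ZeroWorkError):
            cross_shear(np.zeros((2, 2)))

    def test_bounds_and_brute_force_agreement(self, rng):
        for _ in range(50):
            M = random_work_tensor(rng)
            cs, _ = cross_shear(M)
            assert 0.0 <= cs <= 0.5
            assert cs == pytest.approx(brute_force_cs(M, 0.25), abs=1e-4)

    def test_basis_rotation_invariance(self, rng):
        M = random_work_tensor(rng)
        cs0, _ = cross_shear(M)
        th = rng.uniform(0, np.pi)
        R = np.array([[np.cos(th), -np.sin(th)],
                      [np.sin(th), np.cos(th)]])
        cs1, _ = cross_shear(R @ M @ R.T)
        assert cs1 == pytest.approx(cs0, rel=1e-9)

    def test_pmo_is_major_work_direction(self):
        M = np.diag([5.0, 1.0])
        cs, pmo = cross_shear(M)
        assert np.allclose(pmo, [1.0, 0.0])
        assert cs == pytest.approx(1.0 / 6.0)

    def test_accumulate_and_field(self):
        t = FrictionalWorkTensor(2)
        t.accumulate(np.array([[1.0, 0.0], [0.0, 0.0]]),
                     pressure=np.array([2.0, 2.0]),
                     area=np.array([1.0, 1.0]), mu=0.04)
        t.accumulate(np.array([[0.0, 1.0], [0.0, 0.0]]),
                     pressure=np.array([2.0, 2.0]),
                     area=np.array([1.0, 1.0]), mu=0.04)
        cs = cross_shear_field(t)
        assert cs[0] == pytest.approx(0.5)
        assert np.isnan(cs[1])
        assert t.total_work[0] == pytest.approx(2 * 0.04 * 2.0)


class TestWearCoefficient:
    def test_zero_cross_shear_gives_zero(self, wear_model):
        assert wear_coefficient(wear_model, 0.0, 0.1) == 0.0

    def test_saturated_cs_zero_stress_limit(self, wear_model):
        # CS -> inf: C -> a*c = 1.47e-9 * 0.84
        c = wear_coefficient(wear_model, 1e6, 0.0)
        assert c == pytest.approx(1.2348e-9, rel=1e-12)

    def test_against_arbitrary_precision_oracle(self, wear_model):
        # frozen from a 20-digit symbolic evaluation of the fitted surface
        c = wear_coefficient(wear_model, 0.087, 0.007)
        assert c == pytest.approx(1.6420645883511108e-9, rel=1e-12)

    def test_negative_inputs_rejected(self, wear_model):
        with pytest.raises(ValueError):
            wear_coefficient(wear_model, -0.1, 0.1)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(cs1=st.floats(0, 0.5), cs2=st.floats(0, 0.5),
           x1=st.floats(0, 0.2), x2=st.floats(0, 0.2))
    def test_monotone_in_both_arguments(self, cs1, cs2, x1, x2):
        m = WearCoefficientModel()
        lo_cs, hi_cs = sorted((cs1, cs2))
        lo_x, hi_x = sorted((x1, x2))
        assert wear_coefficient(m, lo_cs, lo_x) <= \
            wear_coefficient(m, hi_cs, lo_x) + 1e-30
        assert wear_coefficient(m, lo_cs, lo_x) <= \
            wear_coefficient(m, lo_cs, hi_x) + 1e-30

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValueError):
            WearCoefficientModel(cs_rate=-1.0)


class TestWearLawAlgebra:
    def test_linear_wear_products(self):
        assert linear_wear(0.0, 1e-9) == 0.0
        assert linear_wear(56.0, 0.0) == 0.0
        assert linear_wear(56.0, 1e-9) == pytest.approx(5.6e-8)

    def test_volumetric_wear_products(self):
        assert volumetric_wear(19.6, 56.0, 1e-9) == pytest.approx(
            1.0976e-6, rel=1e-9)
        assert volumetric_wear(0.0, 56.0, 1e-9) == 0.0
        # identity W = A * delta
        assert volumetric_wear(19.6, 56.0, 1e-9) == pytest.approx(
            19.6 * linear_wear(56.0, 1e-9))

    def test_coefficient_inversion_round_trip(self):
        W = volumetric_wear(19.6, 56.0, 2.3e-9)
        assert coefficient_from_measurement(W, 19.6, 56.0) == \
            pytest.approx(2.3e-9, rel=1e-12)
        assert coefficient_from_measurement(0.0, 19.6, 56.0) == 0.0
        with pytest.raises(ValueError):
            coefficient_from_measurement(1.0, 0.0, 56.0)

    def test_cycle_bookkeeping_of_two_week_test(self):
        # 660,000 cycles at S per cycle must equal per-cycle computation
        s_cycle, cycles = 56.0, 660000.0
        c_true = 1.5e-9
        W_total = volumetric_wear(19.6, s_cycle * cycles, c_true)
        c_back = coefficient_from_measurement(W_total, 19.6,
                                              s_cycle * cycles)
        assert c_back == pytest.approx(c_true, rel=1e-12)

    def test_mass_to_volume(self):
        assert mass_to_volume(0.93) == pytest.approx(1.0)
        assert mass_to_volume(0.0) == 0.0
        assert mass_to_volume(1.86) == pytest.approx(2 * mass_to_volume(0.93))
        with pytest.raises(ValueError):
            mass_to_volume(1.0, rho=0.0)


class TestCoefficientFit:
    @staticmethod
    def _grid_observations(model, n=6):
        cs = np.linspace(0.01, 0.2, n)
        x = np.linspace(0.007, 0.15, n)
        CS, X = np.meshgrid(cs, x)
        c = wear_coefficient(model, CS.ravel(), X.ravel())
        return np.column_stack([CS.ravel(), X.ravel(), c])

    def test_recovers_stress_exponent_from_noise_free_samples(self,
                                                              wear_model):
        obs = self._grid_observations(wear_model)
        fitted, r2 = fit_coefficient_model(obs)
        assert fitted.stress_exp == pytest.approx(1.49, abs=1e-3)
        assert fitted.cs_rate == pytest.approx(116.21, rel=1e-3)
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_constant_cs_unidentifiable(self, wear_model):
        x = np.linspace(0.01, 0.1, 6)
        c = wear_coefficient(wear_model, 0.0, x)
        obs = np.column_stack([np.zeros(6), x, c])
        with pytest.raises(FitError, match="CS"):
            fit_coefficient_model(obs)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            fit_coefficient_model(np.zeros((3, 3)))

    def test_model_yaml_round_trip(self, wear_model, tmp_path):
        path = tmp_path / "model.yaml"
        wear_model.to_yaml(path)
        back = WearCoefficientModel.from_yaml(path)
        assert back == wear_model


class TestRSquared:
    def test_perfect_fit(self):
        assert r_squared([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == \
            pytest.approx(1.0)

    def test_published_validation_statistic(self):
        # predicted vs experimental activity wear rates [mm^3/mc]
        r2 = r_squared([4.5, 3.7, 5.6], [5.8, 3.5, 7.1])
        assert round(r2, 2) == 0.94

    def test_anticorrelation_symmetry(self):
        obs = [1.0, 2.5, 4.0]
        assert r_squared([1.0, 2.0, 3.0], obs) == pytest.approx(
            r_squared([-1.0, -2.0, -3.0], obs))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            r_squared([1.0], [1.0, 2.0])
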