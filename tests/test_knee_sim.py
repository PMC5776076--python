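import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from tkrwear import (ImplantParams, KinematicProfile, MaterialProperties,
                     WearCoefficientModel, make_femoral_surface,
                     make_insert_surface, make_primitive)
from tkrwear.knee_sim import (REPORTED_EXPERIMENTAL, REPORTED_PREDICTED,
                              SimulationConfig, ThicknessExhaustedError,
                              compare_activities, run_cycle, run_simulation)
from tkrwear.tribology import wear_coefficient


def small_cfg(**kw):
    defaults = dict(total_cycles=500_000, update_interval_cycles=500_000,
                    n_steps=16, medial_offset_fraction=0.07,
                    layer_thickness=10.0)
    defaults.update(kw)
    return SimulationConfig(**defaults)


def flat_pair(width=10.0, grid=21):
    insert = make_primitive("flat_plate", width=width, length=width,
                            grid=grid)
    insert.metadata["thickness"] = 10.0
    femoral = make_primitive("flat_plate", width=4 * width, length=4 * width,
                             grid=2 * grid + 1)
    return femoral, insert


def square_path_profile(dx, dz, load):
    """Rectangular sliding path: reciprocation along x with an orthogonal
    shear leg along z, giving every node the constant cross-shear ratio
    CS* = dz / (dx + dz)."""
    ap = np.array([0, .5, 1, 1, 1, .5, 0, 0, 0]) * dx
    ml = np.array([0, 0, 0, .5, 1, 1, 1, .5, 0]) * dz
    t = np.arange(9) / 8
    return KinematicProfile(t, np.full(9, load), np.zeros(9), ap,
                            np.zeros(9), ml_mm=ml)


class TestRunCycle:
    def test_zero_motion_profile_wears_nothing(self, mat, wear_model):
        femoral, insert = flat_pair()
        t = np.arange(9) / 8
        prof = KinematicProfile(t, np.full(9, 300.0), np.zeros(9),
                                np.zeros(9), np.zeros(9))
        depth, summary = run_cycle(femoral, insert, prof, mat, wear_model,
                                   small_cfg(n_steps=8,
                                             medial_offset_fraction=0.0))
        assert depth.sum() == 0.0
        assert summary.wear_rate_mm3_per_mc == 0.0

    def test_archard_limit_with_constant_cross_shear(self, mat, wear_model):
        # uniform flat contact at constant pressure and constant CS* must
        # reproduce the closed-form wear volume A * S * C(CS*, p/E)
        femoral, insert = flat_pair()
        F, dx, dz = 500.0, 4.0, 2.0
        prof = square_path_profile(dx, dz, F)
        depth, summary = run_cycle(femoral, insert, prof, mat, wear_model,
                                   small_cfg(n_steps=8,
                                             medial_offset_fraction=0.0))
        W = float((depth * insert.vertex_area).sum())
        A = insert.total_area
        cs_star = dz / (dx + dz)
        S = 2 * (dx + dz)
        W_exact = A * S * wear_coefficient(wear_model, cs_star,
                                           (F / A) / mat.E)
        assert abs(W - W_exact) / W_exact < 0.01
        assert summary.avg_cross_shear == pytest.approx(cs_star, rel=1e-9)

    def test_walking_on_synthetic_geometry_wears(self, femoral, insert, mat,
                                                 wear_model):
        from tkrwear import generate_profile
        prof = generate_profile("walking", 16)
        depth, summary = run_cycle(femoral, insert, prof, mat, wear_model,
                                   small_cfg())
        rate = summary.wear_rate_mm3_per_mc
        assert 0.0 < rate < np.inf
        assert summary.avg_contact_area > 0
        assert 0.0 <= summary.avg_cross_shear <= 0.5

    def test_volumetric_bookkeeping_exact(self, mat, wear_model):
        femoral, insert = flat_pair()
        prof = square_path_profile(3.0, 1.0, 400.0)
        depth, summary = run_cycle(femoral, insert, prof, mat, wear_model,
                                   small_cfg(n_steps=8,
                                             medial_offset_fraction=0.0))
        W = summary.wear_rate_mm3_per_mc / 1e6
        assert W == pytest.approx(float((depth * insert.vertex_area).sum()),
                                  rel=1e-9)
        assert summary.step_wear_fraction.sum() == pytest.approx(100.0,
                                                                 abs=1e-6)


def symmetric_profile(n=16):
    """IE waveform antisymmetric over the half cycle while load/FE/AP are
    half-cycle periodic, so mirror symmetry about the sagittal plane holds
    exactly over a full cycle."""
    t = np.arange(n + 1) / n
    load = 1000.0 + 1600.0 * np.sin(2 * np.pi * t) ** 2
    fe = 30.0 * np.sin(2 * np.pi * t) ** 2
    ap = -10.0 * np.sin(2 * np.pi * t) ** 2
    ie = 5.0 * np.sin(2 * np.pi * t)
    return KinematicProfile(t, load, fe, ap, ie)


class TestRunSimulation:
    def test_zero_scale_model_changes_nothing(self, femoral, insert, mat):
        model = WearCoefficientModel(scale=0.0)
        cfg = small_cfg()
        res = run_simulation(femoral, insert, mat, model, cfg,
                             profile=symmetric_profile())
        assert res.wear.total_volume == 0.0
        assert np.array_equal(res.worn_insert.vertices, insert.vertices)

    def test_doubling_scale_doubles_first_block(self, femoral, insert, mat):
        cfg = small_cfg()
        prof = symmetric_profile()
        r1 = run_simulation(femoral, insert, mat,
                            WearCoefficientModel(scale=1.47e-9), cfg,
                            profile=prof, update_geometry=False)
        r2 = run_simulation(femoral, insert, mat,
                            WearCoefficientModel(scale=2.94e-9), cfg,
                            profile=prof, update_geometry=False)
        assert r2.block_wear_rates[0] == pytest.approx(
            2 * r1.block_wear_rates[0], rel=1e-12)

    def test_medial_lateral_split_without_offset(self, mat, wear_model):
        params = ImplantParams(grid_resolution=40)
        femoral = make_femoral_surface(params)
        insert = make_insert_surface(params)
        cfg = small_cfg(medial_offset_fraction=0.0)
        res = run_simulation(femoral, insert, mat, wear_model, cfg,
                             profile=symmetric_profile())
        vol = res.wear.volumetric
        z = insert.vertices[:, 2]
        med, lat = vol[z > 0].sum(), vol[z < 0].sum()
        assert abs(med - lat) / (med + lat) < 0.02

    def test_update_frequency_convergence(self, mat, wear_model):
        femoral, insert = flat_pair()
        prof = square_path_profile(3.0, 1.0, 400.0)
        one = run_simulation(femoral, insert, mat, wear_model,
                             small_cfg(n_steps=8, total_cycles=1_000_000,
                                       update_interval_cycles=1_000_000,
                                       medial_offset_fraction=0.0),
                             profile=prof)
        two = run_simulation(femoral, insert, mat, wear_model,
                             small_cfg(n_steps=8, total_cycles=1_000_000,
                                       update_interval_cycles=500_000,
                                       medial_offset_fraction=0.0),
                             profile=prof)
        assert abs(one.wear.total_volume - two.wear.total_volume) \
            / two.wear.total_volume < 0.05

    def test_frame_independence_under_vertical_rotation(self, mat,
                                                        wear_model):
        params = ImplantParams(grid_resolution=32)
        femoral = make_femoral_surface(params)
        insert = make_insert_surface(params)
        cfg = small_cfg(n_steps=8, medial_offset_fraction=0.0)
        prof = symmetric_profile(8)
        base = run_cycle(femoral, insert, prof, mat, wear_model, cfg)
        rot = Rotation.from_euler("y", 30, degrees=True)
        fem_r = femoral.with_vertices(rot.apply(femoral.vertices))
        fem_r.metadata["flexion_axis_dir"] = tuple(
            rot.apply(np.array(femoral.metadata["flexion_axis_dir"])))
        fem_r.metadata["flexion_axis_point"] = tuple(
            rot.apply(np.array(femoral.metadata["flexion_axis_point"])))
        ins_r = insert.with_vertices(rot.apply(insert.vertices))
        ins_r.metadata["anterior_dir"] = tuple(rot.apply([1.0, 0, 0]))
        ins_r.metadata["medial_dir"] = tuple(rot.apply([0, 0, 1.0]))
        rotated = run_cycle(fem_r, ins_r, prof, mat, wear_model, cfg)
        assert rotated[1].wear_rate_mm3_per_mc == pytest.approx(
            base[1].wear_rate_mm3_per_mc, rel=5e-3)

    def test_thickness_exhaustion_raises(self, mat):
        femoral, insert = flat_pair()
        prof = square_path_profile(4.0, 2.0, 500.0)
        huge = WearCoefficientModel(scale=1.0)   # pathological scale
        with pytest.raises(ThicknessExhaustedError):
            run_simulation(femoral, insert, mat, huge,
                           small_cfg(n_steps=8,
                                     medial_offset_fraction=0.0),
                           profile=prof)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(total_cycles=900_000,
                             update_interval_cycles=500_000)
        with pytest.raises(ValueError):
            SimulationConfig(medial_offset_fraction=0.7)


class TestCompareActivities:
    def test_published_rates_give_094(self):
        df = compare_activities(REPORTED_PREDICTED, REPORTED_EXPERIMENTAL)
        assert round(df.attrs["r_squared"], 2) == 0.94

    def test_identical_columns_give_one(self):
        df = compare_activities(REPORTED_PREDICTED, REPORTED_PREDICTED)
        assert df.attrs["r_squared"] == pytest.approx(1.0)

    def test_report_preserves_activity_order(self):
        df = compare_activities(REPORTED_PREDICTED, REPORTED_EXPERIMENTAL)
        assert list(df["activity"]) == list(REPORTED_PREDICTED)
        assert {"predicted_mm3_per_mc",
                "experimental_mm3_per_mc"} <= set(df.columns)

    def test_missing_experimental_activity_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            compare_activities({"walking": 4.5}, {})
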