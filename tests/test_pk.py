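"""Synthetic exposure generator: closed forms, calibration, variability."""

import numpy as np
import pytest

from qtddi import fixtures
from qtddi.pk import (
    ConcentrationProfile,
    ExposureModifier,
    PKParams,
    apply_interaction,
    auc_infinity,
    calibrate_pk,
    cmax_tmax,
    pk_profile,
    sample_population,
)
from qtddi.units import ngml_to_um, um_to_ngml


BASE = PKParams(dose_mg=60.0, f_bio=1.0, ka_per_h=1.0, ke_per_h=0.1, v_L=600.0, mw_g_mol=471.7)
GRID = np.linspace(0.0, 120.0, 4001)


class TestProfile:
    def test_zero_at_time_zero(self):
        prof = pk_profile(BASE, GRID)
        assert prof.conc_ngml[0] == 0.0

    def test_auc_closed_form(self):
        # F·D/(ke·V) = 60 mg / (0.1/h * 600 L) = 1 mg/L·h = 1000 ng·h/ml
        assert auc_infinity(BASE) == pytest.approx(1000.0)

    def test_trapezoid_matches_closed_form(self):
        prof = pk_profile(BASE, GRID)
        assert prof.auc_trapezoid() == pytest.approx(auc_infinity(BASE), rel=0.005)

    def test_large_ka_approaches_bolus(self):
        fast = PKParams(dose_mg=60.0, f_bio=1.0, ka_per_h=500.0, ke_per_h=0.1,
                        v_L=600.0, mw_g_mol=471.7)
        cmax, _ = cmax_tmax(fast)
        bolus_cmax = fast.f_bio * fast.dose_mg / fast.v_L * 1000.0  # ng/ml
        assert cmax == pytest.approx(bolus_cmax, rel=0.02)

    def test_ka_equals_ke_analytic_limit(self):
        eq = PKParams(dose_mg=60.0, f_bio=1.0, ka_per_h=0.3, ke_per_h=0.3,
                      v_L=600.0, mw_g_mol=471.7)
        near = PKParams(dose_mg=60.0, f_bio=1.0, ka_per_h=0.3, ke_per_h=0.3 * (1 + 1e-7),
                        v_L=600.0, mw_g_mol=471.7)
        p_eq = pk_profile(eq, GRID).conc_ngml
        p_near = pk_profile(near, GRID).conc_ngml
        assert np.allclose(p_eq, p_near, rtol=1e-4)

    def test_cmax_tmax_match_grid_maximum(self):
        prof = pk_profile(BASE, GRID)
        cmax, tmax = cmax_tmax(BASE)
        assert prof.cmax_ngml == pytest.approx(cmax, rel=1e-4)
        assert prof.tmax_h == pytest.approx(tmax, abs=0.05)

    def test_profile_nonnegative_and_validated(self):
        prof = pk_profile(BASE, GRID)
        assert np.all(prof.conc_ngml >= 0.0)
        with pytest.raises(ValueError):
            pk_profile(BASE, np.array([-1.0, 0.0]))

    def test_unit_conversion_round_trip(self):
        c = np.array([0.0, 2.31, 49.3, 1e5])
        back = um_to_ngml(ngml_to_um(c, 471.7), 471.7)
        assert np.allclose(back, c, rtol=1e-12)


class TestCalibration:
    @pytest.mark.parametrize(
        "cmax, auc",
        [(2.31, 20.5), (2.48, 27.5), (2.3, 15.3)],  # printed predicted pairs
    )
    def test_round_trip_printed_pairs(self, cmax, auc):
        p = calibrate_pk(cmax, auc)
        assert cmax_tmax(p)[0] == pytest.approx(cmax, rel=0.01)
        assert auc_infinity(p) == pytest.approx(auc, rel=0.01)

    def test_round_trip_all_study_designs(self):
        # every bundled study's victim exposure target is recoverable
        for _, row in fixtures.study_designs().iterrows():
            p = calibrate_pk(float(row["victim_cmax_ngml"]), float(row["victim_auc_nghml"]))
            assert cmax_tmax(p)[0] == pytest.approx(float(row["victim_cmax_ngml"]), rel=0.01)
            assert auc_infinity(p) == pytest.approx(float(row["victim_auc_nghml"]), rel=0.01)

    def test_dose_linearity(self):
        p = calibrate_pk(2.31, 20.5, dose_mg=60.0)
        doubled = PKParams(dose_mg=120.0, f_bio=p.f_bio, ka_per_h=p.ka_per_h,
                           ke_per_h=p.ke_per_h, v_L=p.v_L, mw_g_mol=p.mw_g_mol)
        assert auc_infinity(doubled) == pytest.approx(2 * 20.5, rel=0.01)
        assert cmax_tmax(doubled)[0] == pytest.approx(2 * 2.31, rel=0.01)

    def test_infeasible_pair_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            calibrate_pk(100.0, 1.0)

    def test_deterministic(self):
        p1 = calibrate_pk(2.31, 20.5)
        p2 = calibrate_pk(2.31, 20.5)
        assert p1 == p2


class TestPopulation:
    def test_cv_zero_gives_identical_subjects(self):
        pop = sample_population(BASE, 5, 0.0, seed=1)
        assert all(p == BASE for p in pop)

    def test_seed_reproducibility(self):
        a = sample_population(BASE, 20, 0.3, seed=42)
        b = sample_population(BASE, 20, 0.3, seed=42)
        c = sample_population(BASE, 20, 0.3, seed=43)
        assert a == b
        assert a != c

    def test_cv_recovered_at_large_n(self):
        pop = sample_population(BASE, 10_000, 0.3, seed=7)
        ke = np.array([p.ke_per_h for p in pop])
        assert ke.std(ddof=1) / ke.mean() == pytest.approx(0.3, abs=0.02)

    def test_negative_cv_rejected(self):
        with pytest.raises(ValueError):
            sample_population(BASE, 3, -0.1, seed=0)


class TestInteractionModifier:
    def test_identity_modifier(self):
        prof = pk_profile(BASE, GRID)
        out = apply_interaction(prof, ExposureModifier(1.0, 1.0))
        assert np.array_equal(out.conc_ngml, prof.conc_ngml)
        assert out.arm == "T+I"

    def test_equal_multipliers_are_pure_amplitude_scaling(self):
        prof = pk_profile(BASE, GRID)
        out = apply_interaction(prof, ExposureModifier(auc_ratio=2.0, cmax_ratio=2.0))
        assert np.allclose(out.conc_ngml, 2.0 * prof.conc_ngml)

    def test_ketoconazole_study_cmax_ratio(self):
        # victim predicted Cmax ratio 19.67 / 2.23 from the bundled table
        ratio = 19.67 / 2.23
        prof = pk_profile(calibrate_pk(2.23, 27.3), GRID)
        out = apply_interaction(prof, ExposureModifier(auc_ratio=ratio, cmax_ratio=ratio))
        assert out.cmax_ngml / prof.cmax_ngml == pytest.approx(ratio, rel=0.01)

    def test_distinct_auc_and_cmax_ratios(self):
        prof = pk_profile(BASE, GRID)
        out = apply_interaction(prof, ExposureModifier(auc_ratio=1.341, cmax_ratio=1.074))
        assert out.cmax_ngml / prof.cmax_ngml == pytest.approx(1.074, rel=0.01)
        assert out.auc_trapezoid() / prof.auc_trapezoid() == pytest.approx(1.341, rel=0.01)

    def test_sub_unity_multiplier_rejected(self):
        with pytest.raises(ValueError):
            ExposureModifier(auc_ratio=0.9, cmax_ratio=1.0)
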