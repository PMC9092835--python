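"""Model 2: sigma exchange, three-compartment brain, kidney/urine/saliva."""

import numpy as np
import pytest

from s100b_pbpk import build_model2, integrate
from s100b_pbpk.core import ConfigurationError
from s100b_pbpk.model2 import (RenalParamsM2, SalivaParams, SigmaExchange,
                               brain_interstitium_rhs, brain_vascular_rhs,
                               kidney_rhs, saliva_rhs, sigma_exchange_fluxes,
                               urine_rhs)

RENAL = RenalParamsM2(gfr_ml_h=10.0, elimination_factor_per_h=100.0 * 60,
                      tissue_partition_per_h=0.1 * 60, urine_kf_per_h=1.0)


class TestBrainRhs:
    def test_vascular_decays_without_input(self):
        d = brain_vascular_rhs(c_vasc=1.0, c_arterial=0.0, c_interstitium=0.0,
                               v_vasc=67.0, v_int=130.0, bbb_index=0.0,
                               q_in=42000.0, q_out=42000.0)
        assert d == pytest.approx(-42000.0 / 67.0)

    def test_bbb_leakage_source_hand_arithmetic(self):
        """BBB_Index x c_int x V_int: 10 ng/ml x 130 ml -> 1300 x bbb ng/h."""
        for bbb in (0.25, 1.0):
            d = brain_vascular_rhs(0.0, 0.0, 10.0, 67.0, 130.0, bbb,
                                   42000.0, 42000.0)
            assert d * 67.0 == pytest.approx(1300.0 * bbb)

    def test_convective_equilibrium(self):
        d = brain_vascular_rhs(0.7, 0.7, 5.0, 67.0, 130.0, 0.0,
                               42000.0, 42000.0)
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_interstitium_constant_with_all_routes_closed(self):
        d = brain_interstitium_rhs(10.0, 50.0, 130.0, 200.0,
                                   trauma_index=0.0, glymphatics=0.0,
                                   bbb_index=0.0)
        assert d == 0.0

    def test_interstitium_glymphatic_decay_closed_form(self):
        """c_int(t) = 10 exp(-8.4 t / 130) under pure glymphatic drainage."""
        spec = build_model2()
        res = integrate(spec, 40.0, dt_out=0.5)
        expected = 10.0 * np.exp(-8.4 * res.times / 130.0)
        assert np.allclose(res.conc("Interstitium brain"), expected,
                           atol=1e-7)

    def test_trauma_source_magnitude(self):
        """Trauma_Index=1 releases c_glia x V_glia = 10,000 ng/h."""
        d = brain_interstitium_rhs(0.0, 50.0, 130.0, 200.0,
                                   trauma_index=1.0, glymphatics=0.0,
                                   bbb_index=0.0)
        assert d * 130.0 == pytest.approx(50.0 * 200.0)

    def test_trauma_sustains_venous_after_bbbd(self):
        """Astrocytic release prevents venous return to pre-disruption level."""
        def run(trauma):
            spec = build_model2()
            spec.params.controls.bbb_index = 1.0
            spec.params.controls.trauma_index = trauma
            return integrate(spec, 60.0, dt_out=0.5).conc("Venous blood")

        with_trauma, without = run(1.0), run(0.0)
        assert with_trauma[-1] > 10 * without[-1]


class TestSigmaExchange:
    def test_zero_state_gives_zero_fluxes(self):
        sx = SigmaExchange("gut", 0.05, 0.05, 0.8, 132.0)
        assert sigma_exchange_fluxes(0.0, 0.0, sx, 325.0, 61.0) == (0, 0, 0)

    def test_gut_efflux_hand_arithmetic(self):
        sx = SigmaExchange("gut", 0.05, 0.05, 0.8, 132.0)
        j_iv, j_vi, j_lymph = sigma_exchange_fluxes(0.18, 0.0, sx, 325.0, 61.0)
        assert j_iv == pytest.approx(2.925)
        assert j_vi == 0.0
        assert j_lymph == pytest.approx(0.8 * 132.0 * 0.18)

    def test_sigma_lymph_bounds_enforced(self):
        with pytest.raises(ConfigurationError):
            SigmaExchange("x", 0.05, 0.05, 1.5, 10.0)


class TestKidneyUrineSaliva:
    def test_kidney_zero_state_zero_derivative(self):
        assert kidney_rhs(0.0, 0.0, RENAL, 280.0, 66000.0, 66000.0) == 0.0

    def test_elimination_term_unit_conversion_oracle(self):
        """EliminationFactor and TissuePartition both print per minute; their
        ratio (1000) survives conversion, so the flux is 1000 x GFR x c."""
        d = kidney_rhs(0.25, 0.0, RENAL, 280.0, 0.0, 0.0)
        assert d * 280.0 == pytest.approx(-(100.0 / 0.1) * 10.0 * 0.25)

    def test_urine_zero_cases(self):
        assert urine_rhs(0.0, 0.0, RENAL, 200.0) == 0.0

    def test_urine_linear_growth_without_voiding(self):
        rp = RenalParamsM2(10.0, 6000.0, 6.0, urine_kf_per_h=0.0)
        d = urine_rhs(5.0, 0.25, rp, 200.0)
        assert d == pytest.approx(1000.0 * 10.0 * 0.25 / 200.0)

    def test_saliva_stays_empty_without_arterial_s100b(self):
        assert saliva_rhs(3.0, 0.0, SalivaParams(240.0), 10.0) == 0.0

    def test_saliva_has_no_return_path(self):
        d = saliva_rhs(100.0, 0.1, SalivaParams(240.0), 10.0)
        assert d == pytest.approx(240.0 * 0.1 / 10.0)   # independent of c_sal


class TestBuild:
    def test_glymphatic_edge_default(self, model2):
        glymph = [t for t in model2.edges() if t.kind == "glymphatic"]
        assert len(glymph) == 1
        assert glymph[0].coeff == pytest.approx(8.4)
        assert glymph[0].source == "Interstitium brain"
        assert glymph[0].target == "Central lymph"

    def test_initial_concentrations(self, model2):
        assert model2.compartments["Interstitium brain"].concentration == 10.0
        assert model2.compartments["Glia"].concentration == 50.0
        assert model2.compartments["Glia"].clamped
        assert model2.compartments["Venous blood"].concentration == 0.0
        assert model2.compartments["Central lymph"].concentration == 0.0

    def test_liter_rows_normalized_to_ml(self, model2):
        assert model2.compartments["Arterial blood"].volume == 1160.0
        assert model2.compartments["Interstitium muscle"].volume == 2800.0

    def test_low_interstitium_variant(self):
        spec = build_model2(c_interstitium_brain=1.0)
        assert spec.compartments["Interstitium brain"].concentration == 1.0

    def test_missing_row_is_load_error(self):
        from s100b_pbpk.config_io import load_config
        q = dict(load_config("model2").quantities)
        del q["Glymphatics"]
        with pytest.raises(ConfigurationError):
            build_model2(q)


class TestKinetics:
    def test_venous_stays_below_clinical_ceiling(self, model2):
        res = integrate(model2, 150.0, dt_out=0.25)
        assert res.conc("Venous blood").max() < 0.1

    def test_gfr_increase_lowers_venous_but_not_brain(self):
        def run(gfr):
            spec = build_model2()
            spec.params.renal.gfr_ml_h = gfr
            return integrate(spec, 25.0, dt_out=0.5)

        low, high = run(10.0), run(100.0)
        assert high.conc("Venous blood")[-1] < low.conc("Venous blood")[-1]
        assert np.allclose(high.conc("Interstitium brain"),
                           low.conc("Interstitium brain"), rtol=1e-9)

    def test_lower_interstitium_reduces_bbbd_response_everywhere(self):
        def run(c_int):
            spec = build_model2(c_interstitium_brain=c_int)
            spec.params.controls.bbb_index = 1.0
            return integrate(spec, 25.0, dt_out=0.5).conc("Venous blood")

        hi, lo = run(10.0), run(1.0)
        assert np.all(lo[1:] < hi[1:])

    def test_empty_organs_fill_from_glymphatic_route(self):
        spec = build_model2()
        for name in ("Interstitium muscle", "Vascular space muscle",
                     "Interstitium adipose", "Vascular space adipose",
                     "Interstitium gut", "Vascular space gut"):
            spec.compartments[name].concentration = 0.0
        res = integrate(spec, 100.0, dt_out=1.0)
        for name in ("Interstitium muscle", "Interstitium adipose",
                     "Interstitium gut"):
            assert res.conc(name)[-1] > 0.0
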