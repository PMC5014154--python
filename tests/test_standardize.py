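import pytest

from rubiscotemp import datasets, physchem
from rubiscotemp.standardize import (
    ATM,
    AssayConditions,
    AssayRecord,
    StandardizationError,
    co2_fraction,
    convert_phase,
    correct_kc,
    correct_ko,
    correct_sco,
    restandardize_sco_liquid,
    standardization_error,
    standardize_record,
)


class TestCO2Fraction:
    def test_equal_ph_and_pka_gives_half(self):
        assert co2_fraction(6.3, 6.3) == pytest.approx(0.5)

    def test_alkaline_assay_mostly_bicarbonate(self):
        assert co2_fraction(8.17, 6.112) < 0.01

    def test_ph_bounds(self):
        with pytest.raises(ValueError):
            co2_fraction(-1.0, 6.3)
        with pytest.raises(ValueError):
            co2_fraction(15.0, 6.3)


class TestKcCorrection:
    def test_pure_water_pka_at_35c_gives_1p78_fold(self):
        # classic worked case: assays that computed dissolved CO2 with the
        # pure-water pKa 6.32 at 35 degC and pH 8.17 overestimated Kc
        # 1.78-fold relative to the ionic-strength-corrected constant
        pka_c = physchem.pka_co2(308.15, 0.117)
        corrected = correct_kc(1.0, pH=8.17, pKa_used=6.32, pKa_corrected=pka_c)
        fold = 1.0 / corrected
        assert round(fold, 2) == 1.78

    def test_identity_when_constants_agree(self):
        assert correct_kc(41.0, 8.0, 6.112, 6.112) == pytest.approx(41.0)

    def test_missing_metadata_raises(self):
        with pytest.raises(StandardizationError):
            correct_kc(41.0, None, 6.32, 6.112)
        with pytest.raises(StandardizationError):
            correct_kc(41.0, 8.0, None, 6.112)


class TestKoCorrection:
    def test_typical_pure_water_constant_overestimates_by_4p9_pct(self):
        hu = datasets.TYPICAL_HENRY_O2_USED          # 80 040
        hc = datasets.HENRY_TABLE["O2"]["chloroplast"][1]  # 83 950 at 25 degC
        corrected = correct_ko(1.0, hu, hc)
        overestimate_pct = 100.0 * (1.0 / corrected - 1.0)
        assert round(overestimate_pct, 1) == 4.9

    def test_identity_and_missing(self):
        assert correct_ko(250.0, 83950.0, 83950.0) == pytest.approx(250.0)
        with pytest.raises(StandardizationError):
            correct_ko(250.0, None, 83950.0)


class TestScoCorrection:
    def test_combines_pka_and_henry_factors(self):
        pka_u, pka_c = 6.32, 6.067
        hu, hc = 80040.0, 83950.0
        got = correct_sco(100.0, 8.17, pka_u, pka_c, hu, hc)
        expected = (100.0
                    * co2_fraction(8.17, pka_u) / co2_fraction(8.17, pka_c)
                    * hu / hc)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_liquid_restandardization_uses_both_gas_pairs(self):
        got = restandardize_sco_liquid(90.0, 80040.0, 2982.0, 83950.0, 3041.0)
        assert got == pytest.approx(90.0 * (80040.0 * 3041.0)
                                    / (2982.0 * 83950.0), rel=1e-12)


class TestInversePairs:
    def test_kc_correction_is_self_inverse(self):
        v = correct_kc(41.0, 8.17, 6.32, 6.067)
        back = correct_kc(v, 8.17, 6.067, 6.32)
        assert back == pytest.approx(41.0, rel=1e-14)

    def test_sco_correction_is_self_inverse(self):
        v = correct_sco(100.0, 8.17, 6.32, 6.067, 80040.0, 83950.0)
        back = correct_sco(v, 8.17, 6.067, 6.32, 83950.0, 80040.0)
        assert back == pytest.approx(100.0, rel=1e-14)


class TestPhaseConversion:
    @pytest.mark.parametrize("trait", ["Kc", "Ko", "Sc/o"])
    def test_round_trip_identity(self, trait):
        v = 123.4
        there = convert_phase(trait, v, "gas->liquid", 298.15)
        back = convert_phase(trait, there, "liquid->gas", 298.15)
        assert back == pytest.approx(v, rel=1e-14)

    def test_kc_gas_to_liquid_magnitude(self):
        # 352 umol/mol of CO2 at 25 degC in chloroplast medium dissolves to
        # roughly 11.7 uM: x * P / H / 1000 (mol/L), here in matching units
        h = physchem.henry_constant("CO2", 298.15, 0.11)
        got = convert_phase("Kc", 352e-6, "gas->liquid", 298.15)
        assert got == pytest.approx(352e-6 * ATM / h / 1000.0, rel=1e-12)

    def test_sco_conversion_shrinks_value_30fold(self):
        # H_CO2/H_O2 ~ 1/27, so gas-basis Sc/o values are far larger
        liquid = convert_phase("Sc/o", 100.0, "gas->liquid", 298.15)
        assert 100.0 / liquid == pytest.approx(
            physchem.henry_constant("O2", 298.15, 0.11)
            / physchem.henry_constant("CO2", 298.15, 0.11), rel=1e-12)

    def test_kcat_has_no_phase(self):
        with pytest.raises(ValueError):
            convert_phase("kcat", 2.5, "gas->liquid", 298.15)

    def test_bad_direction_and_trait(self):
        with pytest.raises(ValueError):
            convert_phase("Kc", 1.0, "sideways", 298.15)
        with pytest.raises(ValueError):
            convert_phase("Km", 1.0, "gas->liquid", 298.15)


class TestRecordDispatch:
    def test_kcat_passes_through(self):
        rec = AssayRecord("X", "kcat", 298.15, 2.5)
        res = standardize_record(rec)
        assert res.standardized and res.value_corrected == 2.5 and res.factor == 1.0

    def test_gas_record_converted_to_liquid(self):
        rec = AssayRecord("X", "Kc", 298.15, 352e-6, phase="gas")
        res = standardize_record(rec)
        assert res.standardized
        assert res.value_corrected == pytest.approx(
            convert_phase("Kc", 352e-6, "gas->liquid", 298.15), rel=1e-12)

    def test_liquid_kc_with_metadata_is_corrected(self):
        rec = AssayRecord(
            "X", "Kc", 308.15, 41.0,
            conditions=AssayConditions(pH=8.17, pKa_used=6.32,
                                       ionic_strength=0.117))
        res = standardize_record(rec)
        assert res.standardized
        assert 1.0 / res.factor == pytest.approx(1.78, abs=0.01)

    def test_missing_metadata_flagged_not_silently_defaulted(self):
        rec = AssayRecord("X", "Kc", 308.15, 41.0)
        res = standardize_record(rec)
        assert not res.standardized
        assert res.value_corrected == 41.0 and res.factor == 1.0
        assert "unknown" in res.note

    def test_sco_liquid_henry_pair_path(self):
        rec = AssayRecord(
            "X", "Sc/o", 298.15, 90.0,
            conditions=AssayConditions(henry_used_O2=80040.0,
                                       henry_used_CO2=2982.0))
        res = standardize_record(rec)
        assert res.standardized
        h_o2 = physchem.henry_constant("O2", 298.15, 0.11)
        h_co2 = physchem.henry_constant("CO2", 298.15, 0.11)
        assert res.value_corrected == pytest.approx(
            restandardize_sco_liquid(90.0, 80040.0, 2982.0, h_o2, h_co2),
            rel=1e-12)


class TestValidation:
    def test_record_rejects_unknown_trait_phase_and_nonpositive_value(self):
        with pytest.raises(ValueError):
            AssayRecord("X", "Vmax", 298.15, 1.0)
        with pytest.raises(ValueError):
            AssayRecord("X", "Kc", 298.15, 1.0, phase="plasma")
        with pytest.raises(ValueError):
            AssayRecord("X", "Kc", 298.15, -1.0)

    def test_conditions_reject_implausible_pka_and_negative_henry(self):
        with pytest.raises(ValueError):
            AssayConditions(pKa_used=9.0)
        with pytest.raises(ValueError):
            AssayConditions(henry_used_O2=-5.0)

    def test_standardization_error_sign(self):
        assert standardization_error(95.0, 100.0) == pytest.approx(-5.0)
        with pytest.raises(ValueError):
            standardization_error(95.0, 0.0)
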