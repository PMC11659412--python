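"""Calibration, LOQ gating, chlorophyll/weight normalisation, and ddCt."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from npqkit.errors import NormalizationError
from npqkit.quant_assays import (
    CtRecord,
    DEFAULT_LIMITS,
    MetaboliteRecord,
    PigmentRecord,
    fit_calibration,
    normalize_metabolite,
    normalize_to_chlorophyll,
    quantify,
    relative_expression,
)


class TestCalibration:
    def test_exact_line(self):
        c = fit_calibration([(0, 0), (10, 100), (20, 200)])
        assert c.slope == pytest.approx(10.0)
        assert c.intercept == pytest.approx(0.0, abs=1e-10)
        assert c.r_squared == pytest.approx(1.0)

    def test_validated_limits_by_analyte(self):
        for analyte in ("zeaxanthin", "antheraxanthin", "lutein"):
            c = fit_calibration([(0, 0), (50, 500)], analyte=analyte)
            assert c.loq == 21.0 and c.lod == 21.0
        assert fit_calibration([(0, 0), (50, 500)], analyte="violaxanthin").loq == 20.0
        assert fit_calibration([(0, 0), (50, 500)], analyte="chlorophyll_a").loq == 35.0
        assert fit_calibration([(0, 0), (50, 500)], analyte="chlorophyll_b").loq == 25.0

    def test_zero_variance_concentrations_rejected(self):
        with pytest.raises(NormalizationError):
            fit_calibration([(5, 50), (5, 55)])

    def test_through_origin_variant(self):
        c = fit_calibration([(10, 110), (20, 210)], through_origin=True)
        assert c.intercept == 0.0

    def test_quantify_inverts_line(self):
        c = fit_calibration([(0, 0), (10, 100), (20, 200)])
        assert quantify(c, 150.0).concentration == pytest.approx(15.0)

    def test_round_trip_on_calibration_points(self):
        pts = [(0.0, 5.0), (10.0, 105.0), (20.0, 205.0)]  # exact with intercept 5
        c = fit_calibration(pts)
        for conc, resp in pts:
            assert quantify(c, resp).concentration == pytest.approx(conc, abs=1e-9)

    def test_below_loq_flag_at_printed_limit(self):
        c = fit_calibration([(0, 0), (50, 500)], analyte="zeaxanthin")
        q = quantify(c, 150.0)  # 15 µg/ml < 21
        assert q.concentration == pytest.approx(15.0)
        assert q.below_loq and q.below_lod
        assert not quantify(c, 250.0).below_loq  # 25 µg/ml

    def test_zero_and_negative_responses_clip_with_flags(self):
        c = fit_calibration([(0, 10), (10, 110)], analyte="zeaxanthin")
        q0 = quantify(c, 10.0)
        assert q0.concentration == 0.0 and q0.below_lod
        qn = quantify(c, 0.0)  # back-calculates negative, clipped
        assert qn.concentration == 0.0 and qn.below_lod


class TestChlorophyllNormalization:
    def _rec(self, **conc):
        return PigmentRecord(sample_id="s1", concentrations=conc,
                             chlorophyll_a=70.0, chlorophyll_b=30.0)

    def test_mass_ratio(self):
        out = normalize_to_chlorophyll(self._rec(zeaxanthin=10.0))
        assert out.normalized["zeaxanthin"] == pytest.approx(0.10)

    def test_pool_is_sum_of_components(self):
        out = normalize_to_chlorophyll(
            self._rec(violaxanthin=20.0, antheraxanthin=5.0, zeaxanthin=10.0))
        assert out.normalized_pool == pytest.approx(0.35)
        assert out.xanthophyll_pool == pytest.approx(35.0)

    def test_all_zero_pigments_normalize_to_zero(self):
        out = normalize_to_chlorophyll(
            self._rec(violaxanthin=0.0, antheraxanthin=0.0, zeaxanthin=0.0))
        assert out.normalized_pool == 0.0

    def test_zero_chlorophyll_rejected(self):
        rec = PigmentRecord(sample_id="s", concentrations={"zeaxanthin": 1.0},
                            chlorophyll_a=0.0, chlorophyll_b=0.0)
        with pytest.raises(NormalizationError):
            normalize_to_chlorophyll(rec)


class TestRelativeExpression:
    def _rec(self, ct_target, ct_ref1=20.0, ct_ref2=22.0, target="ZEP"):
        return CtRecord(sample_id="s", target=target, ct_target=ct_target,
                        ct_ref1=ct_ref1, ct_ref2=ct_ref2)

    def test_identity_for_equal_delta_ct(self):
        assert relative_expression(self._rec(24.0), self._rec(24.0)) == pytest.approx(1.0)

    def test_one_cycle_advantage_doubles_expression(self):
        sample = self._rec(24.0)               # dCt = 24 - 21 = 3
        calibrator = self._rec(25.0)           # dCt = 4
        assert relative_expression(sample, calibrator) == pytest.approx(2.0)

    def test_two_cycle_deficit_quarters_expression(self):
        assert relative_expression(self._rec(26.0), self._rec(24.0)) == pytest.approx(0.25)

    def test_mismatched_targets_rejected(self):
        with pytest.raises(ValueError):
            relative_expression(self._rec(24.0), self._rec(24.0, target="VDE"))

    @given(shift=st.floats(-10.0, 10.0))
    def test_invariant_to_uniform_ct_shift(self, shift):
        sample = self._rec(24.3, 19.7, 22.1)
        shifted = self._rec(24.3 + shift, 19.7 + shift, 22.1 + shift)
        calibrator = self._rec(25.0)
        # shifting target AND both references together leaves dCt unchanged
        assert relative_expression(shifted, calibrator) == pytest.approx(
            relative_expression(sample, calibrator), rel=1e-9)


class TestMetaboliteNormalization:
    def test_weight_and_volume_scaling(self):
        c = fit_calibration([(0, 0), (10, 100)], analyte="ascorbate")
        rec = MetaboliteRecord(sample_id="m", analyte="ascorbate",
                               peak_area=100.0, sample_weight_mg=25.0)
        amount, q = normalize_metabolite(rec, c)  # 10 units/ml * 0.05 ml / 25 mg
        assert amount == pytest.approx(0.02)

    def test_doubling_weight_halves_amount(self):
        c = fit_calibration([(0, 0), (10, 100)], analyte="ascorbate")
        a1, _ = normalize_metabolite(
            MetaboliteRecord("m", "ascorbate", 100.0, 20.0), c)
        a2, _ = normalize_metabolite(
            MetaboliteRecord("m", "ascorbate", 100.0, 40.0), c)
        assert a1 == pytest.approx(2.0 * a2)

    def test_zero_response_flagged(self):
        c = fit_calibration([(0, 0), (10, 100)], analyte="ascorbate")
        amount, q = normalize_metabolite(
            MetaboliteRecord("m", "ascorbate", 0.0, 25.0), c)
        assert amount == 0.0 and q.below_lod

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError):
            MetaboliteRecord("m", "ascorbate", 100.0, 0.0)
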