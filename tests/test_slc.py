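import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lignosurf.slc import (
    DEFAULT_REFERENCES,
    CorrectionReferences,
    Stoichiometry,
    corrected_oc,
    excess_carbon_fraction,
    lignin_mole_fraction,
    lignin_weight_fraction,
    mole_fraction_from_weight,
    slc_corrected,
    slc_legacy,
)

#: (measured, printed corrected) O/C pairs reported for degrading rice straw;
#: the day-0 pair (0.60 → 0.66) is irreproducible beyond display rounding and
#: is deliberately not part of this oracle.
MEASURED_TO_CORRECTED = [(0.40, 0.44), (0.64, 0.70), (0.85, 0.94)]


class TestLegacySLC:
    @pytest.mark.parametrize(
        "oc, expected", [(0.83, 0.0), (0.33, 100.0), (0.58, 50.0)]
    )
    def test_endmember_mixing(self, oc, expected):
        res = slc_legacy(oc)
        assert res.slc_percent == pytest.approx(expected)
        assert not res.out_of_range

    def test_out_of_range_flagged(self):
        # an O/C above the cellulose endmember gives negative coverage —
        # the failure mode motivating the corrected estimator
        res = slc_legacy(0.90)
        assert res.slc_percent < 0
        assert res.out_of_range

    def test_equal_endmembers_rejected(self):
        with pytest.raises(ValueError):
            slc_legacy(0.5, oc_lignin=0.8, oc_cellulose=0.8)


class TestStoichiometricFractions:
    def test_carbohydrate_endmember(self):
        st_ = Stoichiometry()
        assert lignin_mole_fraction(st_.oc_carbohydrate) == pytest.approx(0.0, abs=1e-12)

    def test_lignin_endmember(self):
        st_ = Stoichiometry()
        assert lignin_mole_fraction(st_.oc_lignin) == pytest.approx(1.0, abs=1e-12)

    def test_direct_evaluation(self):
        # (5 − 6·0.60)/(1.68 + 3.92·0.60) = 1.4/4.032, evaluated by hand
        assert lignin_mole_fraction(0.60) == pytest.approx(0.347222, abs=1e-6)

    @given(oc=st.floats(min_value=0.335, max_value=0.833))
    @settings(max_examples=50, deadline=None)
    def test_strictly_decreasing_in_oc(self, oc):
        assert lignin_mole_fraction(oc) > lignin_mole_fraction(oc + 1e-6)

    @pytest.mark.parametrize("s, expected", [(0.0, 0.0), (1.0, 1.0), (0.5, 0.53096)])
    def test_weight_fraction(self, s, expected):
        assert lignin_weight_fraction(s) == pytest.approx(expected, abs=1e-4)

    @given(s=st.floats(min_value=0.0, max_value=1.0))
    @settings(max_examples=50, deadline=None)
    def test_weight_fraction_round_trip(self, s):
        assert mole_fraction_from_weight(lignin_weight_fraction(s)) == pytest.approx(
            s, abs=1e-12
        )

    def test_out_of_range_mole_fraction_rejected(self):
        with pytest.raises(ValueError):
            lignin_weight_fraction(1.5)


class TestExcessCarbonCorrection:
    def test_default_k(self):
        # (0.833 − 0.74)/1.833 evaluated by hand
        assert excess_carbon_fraction() == pytest.approx(0.05074, abs=1e-5)

    def test_no_excess_when_references_equal(self):
        ref = CorrectionReferences(0.833, 0.833)
        assert excess_carbon_fraction(ref) == 0.0

    def test_limiting_case_vanishing_cellulose_reference(self):
        ref = CorrectionReferences(0.833, 1e-12)
        assert excess_carbon_fraction(ref) == pytest.approx(0.833 / 1.833, abs=1e-9)

    @pytest.mark.parametrize(
        "oc_measured, expected",
        [(0.64, 0.698), (0.85, 0.938)],
    )
    def test_corrected_oc_examples(self, oc_measured, expected):
        k = excess_carbon_fraction()
        assert corrected_oc(oc_measured, k) == pytest.approx(expected, abs=0.001)

    def test_identity_at_zero_k(self):
        assert corrected_oc(0.5, 0.0) == pytest.approx(0.5, rel=1e-12)

    @pytest.mark.parametrize("oc_measured, printed", MEASURED_TO_CORRECTED)
    def test_published_correction_table_reproduced(self, oc_measured, printed):
        k = excess_carbon_fraction()
        assert corrected_oc(oc_measured, k) == pytest.approx(printed, abs=0.01)

    @given(
        x=st.floats(min_value=0.2, max_value=0.9),
        k=st.floats(min_value=1e-6, max_value=0.15),
    )
    @settings(max_examples=60, deadline=None)
    def test_correction_raises_oc_and_is_monotone(self, x, k):
        corr = corrected_oc(x, k)
        assert corr > x
        assert corrected_oc(x, 0.0) == pytest.approx(x, rel=1e-12)  # equality iff k=0
        assert corrected_oc(x, k + 0.01) > corr  # increasing in k
        assert corrected_oc(x + 1e-4, k) > corr  # increasing in measured O/C

    def test_degenerate_correction_rejected(self):
        with pytest.raises(ValueError):
            corrected_oc(20.0, 0.5)  # (1−k)(1/x+1) ≤ 1


class TestSLCCorrected:
    def test_day9_lignin_contribution(self):
        res = slc_corrected(0.85)
        assert res.oc_lignin == pytest.approx(0.088, abs=0.001)

    def test_day6_full_chain(self):
        # chain evaluated independently: corr = 0.698086, lignin O/C = 0.058086,
        # SLC% = 100·0.058086/0.698086 = 8.321
        res = slc_corrected(0.64)
        assert res.oc_lignin == pytest.approx(0.0581, abs=0.0005)
        assert res.slc_percent == pytest.approx(8.321, abs=0.01)

    def test_zero_k_gives_zero_coverage(self):
        ref = CorrectionReferences(0.80, 0.80)
        res = slc_corrected(0.6, ref)
        assert res.oc_lignin == pytest.approx(0.0, abs=1e-12)
        assert res.slc_percent == pytest.approx(0.0, abs=1e-10)

    def test_invariant_corrected_at_least_measured(self):
        for oc in (0.3, 0.5, 0.7, 0.85):
            res = slc_corrected(oc)
            assert res.oc_corrected >= res.oc_measured
            assert res.oc_lignin >= 0

    def test_invalid_references_rejected(self):
        with pytest.raises(ValueError):
            CorrectionReferences(0.7, 0.8)  # rice-straw reference above theoretical
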