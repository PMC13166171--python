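import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lignosurf import synth
from lignosurf.core_io import AxisKind, Spectrum
from lignosurf.errors import SpectrumError
from lignosurf.xps import (
    DEFAULT_C1S_CENTERS,
    CarbonEnvelope,
    acid_base_balance,
    average_surveys,
    co_over_oxidized,
    elemental_ratios,
    fit_components,
    oxygenated_ratio,
)

# C1s envelopes with the relative contributions reported for a degrading
# rice-straw surface at the four sampling days.
ENVELOPE_DAY0 = CarbonEnvelope(29.41, 23.52, 7.35, 14.70)
ENVELOPE_DAY3 = CarbonEnvelope(14.35, 18.18, 9.09, 1.91)
ENVELOPE_DAY9 = CarbonEnvelope(16.21, 10.27, 16.21, 9.18)


class TestAverageSurveys:
    @staticmethod
    def _const(value, lo=280.0, hi=295.0, step=0.05):
        axis = np.arange(lo, hi + 1e-9, step)
        return Spectrum(AxisKind.BINDING_ENERGY_EV, axis, np.full(axis.size, float(value)))

    def test_idempotent_mean(self):
        a = self._const(10.0)
        avg = average_surveys(a, a)
        np.testing.assert_allclose(avg.intensity, a.intensity)

    def test_constant_mean(self):
        avg = average_surveys(self._const(10.0), self._const(30.0))
        np.testing.assert_allclose(avg.intensity, 20.0)

    def test_offset_grids_interpolated_on_intersection(self):
        # linear ramps: interpolation is exact, so the mean of y=x and y=2x is 1.5x
        axis_a = np.arange(280.0, 295.0 + 1e-9, 0.05)
        axis_b = axis_a + 0.025
        a = Spectrum(AxisKind.BINDING_ENERGY_EV, axis_a, axis_a)
        b = Spectrum(AxisKind.BINDING_ENERGY_EV, axis_b, 2.0 * axis_b)
        avg = average_surveys(a, b)
        mask = (axis_a >= axis_b[0]) & (axis_a <= axis_b[-1])
        assert len(avg) == int(mask.sum())
        np.testing.assert_allclose(avg.intensity, 1.5 * avg.axis, rtol=1e-12)

    def test_disjoint_ranges_rejected(self):
        with pytest.raises(SpectrumError, match="overlap"):
            average_surveys(self._const(1.0, 280, 290), self._const(1.0, 520, 540))


class TestFitComponents:
    def test_four_component_recovery_noiseless(self):
        shares = np.array([29.41, 23.52, 7.35, 14.70])
        shares = shares / shares.sum()
        comps = [(c, 0.55, float(s)) for c, s in zip(DEFAULT_C1S_CENTERS, shares)]
        region, _ = synth.make_xps_region(comps, background=(3.0, 50.0))
        fit = fit_components(region, [(c, 0.6) for c in DEFAULT_C1S_CENTERS])
        for got, true in zip(fit.shares_percent, 100 * shares):
            assert got == pytest.approx(true, abs=1.0)

    def test_shares_sum_to_100(self):
        shares = np.array([0.4, 0.3, 0.2, 0.1])
        comps = [(c, 0.5, float(s)) for c, s in zip(DEFAULT_C1S_CENTERS, shares)]
        region, _ = synth.make_xps_region(comps, noise_sd_frac=0.01, seed=5)
        fit = fit_components(region, [(c, 0.5) for c in DEFAULT_C1S_CENTERS])
        assert sum(fit.shares_percent) == pytest.approx(100.0, abs=1e-6)

    def test_single_component_is_100pct(self):
        region, _ = synth.make_xps_region([(284.8, 0.6, 1.0)])
        fit = fit_components(region, [(284.8, 0.6)])
        assert fit.shares_percent[0] == pytest.approx(100.0)

    def test_shirley_background_single_peak(self):
        region, _ = synth.make_xps_region([(284.8, 0.6, 1.0)], background=(0.0, 40.0))
        fit = fit_components(region, [(284.8, 0.6)], background="shirley")
        assert fit.components[0].center_ev == pytest.approx(284.8, abs=0.05)
        assert fit.shares_percent[0] == pytest.approx(100.0)

    def test_init_center_outside_region_rejected(self):
        region, _ = synth.make_xps_region([(284.8, 0.6, 1.0)])
        with pytest.raises(ValueError, match="outside"):
            fit_components(region, [(300.0, 0.6)])

    def test_too_many_components_rejected(self):
        region, _ = synth.make_xps_region([(284.8, 0.6, 1.0)])
        with pytest.raises(ValueError):
            fit_components(region, [(284.8, 0.6)] * 5)


class TestElementalRatios:
    @pytest.mark.parametrize(
        "c, o, n, oc, cn",
        [
            (51.89, 44.32, 3.78, 0.854, 13.73),
            (57.89, 37.36, 4.73, 0.645, 12.24),
            (50.0, 50.0, 50.0, 1.0, 1.0),
        ],
    )
    def test_reported_compositions(self, c, o, n, oc, cn):
        comp = elemental_ratios(c, o, n)
        assert comp.oc_ratio == pytest.approx(oc, abs=0.001)
        assert comp.cn_ratio == pytest.approx(cn, abs=0.01)

    def test_zero_denominators_rejected(self):
        with pytest.raises(ValueError):
            elemental_ratios(0.0, 50.0, 5.0)
        with pytest.raises(ValueError):
            elemental_ratios(50.0, 50.0, 0.0)


class TestEnvelopeRatios:
    @pytest.mark.parametrize(
        "env, expected",
        [(ENVELOPE_DAY0, 1.55), (ENVELOPE_DAY3, 2.03)],
    )
    def test_oxygenated_reported_values(self, env, expected):
        assert oxygenated_ratio(env) == pytest.approx(expected, abs=0.01)

    def test_oxygenated_trivial(self):
        assert oxygenated_ratio(CarbonEnvelope(10, 0, 0, 0)) == 0.0

    @pytest.mark.parametrize(
        "env, expected",
        [(ENVELOPE_DAY0, 1.04), (ENVELOPE_DAY9, 0.60)],
    )
    def test_acid_base_reported_values(self, env, expected):
        assert acid_base_balance(env) == pytest.approx(expected, abs=0.01)

    def test_acid_base_symmetry(self):
        assert acid_base_balance(CarbonEnvelope(20, 20, 5, 5)) == pytest.approx(1.0)

    def test_acid_base_simple_form_differs(self):
        # the bare C2/C1 variant does not reproduce the grouped value
        grouped = acid_base_balance(ENVELOPE_DAY0, form="grouped")
        simple = acid_base_balance(ENVELOPE_DAY0, form="simple")
        assert simple == pytest.approx(23.52 / 29.41, rel=1e-12)
        assert abs(simple - grouped) > 0.1

    @pytest.mark.parametrize(
        "env, expected",
        [(ENVELOPE_DAY3, 1.65), (ENVELOPE_DAY9, 0.405)],
    )
    def test_co_over_oxidized_reported_values(self, env, expected):
        assert co_over_oxidized(env) == pytest.approx(expected, abs=0.01)

    def test_co_over_oxidized_zero_numerator(self):
        assert co_over_oxidized(CarbonEnvelope(10, 0, 5, 5)) == 0.0

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=30, deadline=None)
    def test_rescaling_invariance(self, scale):
        env = ENVELOPE_DAY0
        scaled = CarbonEnvelope(env.c1 * scale, env.c2 * scale, env.c3 * scale, env.c4 * scale)
        assert oxygenated_ratio(scaled) == pytest.approx(oxygenated_ratio(env), rel=1e-9)
        assert acid_base_balance(scaled) == pytest.approx(acid_base_balance(env), rel=1e-9)
        assert co_over_oxidized(scaled) == pytest.approx(co_over_oxidized(env), rel=1e-9)

    def test_zero_denominator_errors(self):
        with pytest.raises(ValueError):
            oxygenated_ratio(CarbonEnvelope(0, 1, 1, 1))
        with pytest.raises(ValueError):
            co_over_oxidized(CarbonEnvelope(1, 1, 0, 0))
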