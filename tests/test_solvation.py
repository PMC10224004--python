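"""Mole-fraction conversion, van't Hoff regression and thermodynamic functions."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from partisol import (
    SolubilitySeries,
    VantHoffFit,
    VantHoffRegression,
    enthalpy_from_fit,
    fit_vant_hoff,
    gibbs_at,
    mole_fraction,
    thermo_functions,
    transfer_functions,
)
from partisol.errors import (
    DegenerateDesignError,
    InsufficientDataError,
    InvalidCompositionError,
)
from partisol.simulate import NoiseSpec, simulate_solubility_series
from partisol.solvation import thermo_uncertainties

from conftest import FIVE_TEMPS, HEXANE_AB, OCTANOL_AB


class TestMoleFraction:
    def test_octanol_hand_value(self, ipn, octanol):
        # single-line hand evaluation of the as-printed formula
        assert mole_fraction(0.686, ipn, octanol) == pytest.approx(0.1039, abs=1e-4)

    def test_hexane_hand_value_matches_fit_line(self, ipn, hexane):
        x2 = mole_fraction(0.00203, ipn, hexane)
        assert x2 == pytest.approx(2.67e-4, rel=5e-3)
        # cross-check against the printed hexane coefficients at 310.2 K
        a, b = HEXANE_AB
        assert x2 == pytest.approx(math.exp(a + b / 310.2), rel=0.10)

    def test_infinite_dilution_limit(self, ipn, octanol):
        assert mole_fraction(1e-12, ipn, octanol) == pytest.approx(0.0, abs=1e-10)

    def test_modes_diverge_by_sign_of_correction(self, ipn, octanol):
        printed = mole_fraction(0.686, ipn, octanol, mode="as_printed")
        balance = mole_fraction(0.686, ipn, octanol, mode="mass_balance")
        assert balance > printed  # smaller denominator
        assert abs(balance - printed) / printed < 0.09

    @given(st.floats(min_value=1e-6, max_value=2.0),
           st.floats(min_value=1e-6, max_value=2.0))
    def test_strictly_increasing_in_s2(self, s_lo, s_hi):
        from partisol import SoluteSpec, SolventSpec
        ipn = SoluteSpec("IPN", 179.22)
        octanol = SolventSpec("1-octanol", 130.23, 0.8262)
        if s_lo == s_hi:
            return
        lo, hi = sorted((s_lo, s_hi))
        for mode in ("as_printed", "mass_balance"):
            assert mole_fraction(lo, ipn, octanol, mode=mode) < \
                mole_fraction(hi, ipn, octanol, mode=mode)

    def test_invalid_composition_raises(self, ipn, octanol):
        with pytest.raises(InvalidCompositionError):
            mole_fraction(-1.0, ipn, octanol)
        with pytest.raises(InvalidCompositionError):
            # mass-balance denominator driven negative
            mole_fraction(20.0, ipn, octanol, mode="mass_balance")


class TestVantHoffRegression:
    @pytest.mark.parametrize("a_b", [OCTANOL_AB, HEXANE_AB])
    def test_recovers_generating_coefficients_exactly(self, a_b):
        a, b = a_b
        series = simulate_solubility_series(a, b, FIVE_TEMPS)
        fit = fit_vant_hoff(series)
        assert fit.A == pytest.approx(a, abs=1e-9)
        assert fit.B == pytest.approx(b, abs=1e-6)
        assert fit.rss == pytest.approx(0.0, abs=1e-20)
        assert abs(fit.r) == pytest.approx(1.0, abs=1e-12)

    def test_two_points_interpolate_exactly(self):
        series = simulate_solubility_series(3.0, -1500.0, [298.2, 310.2])
        fit = fit_vant_hoff(series)
        assert fit.rss == 0.0
        assert fit.n == 2
        assert fit.A == pytest.approx(3.0)
        assert fit.B == pytest.approx(-1500.0)

    def test_insufficient_and_degenerate_designs(self):
        with pytest.raises(InsufficientDataError):
            VantHoffRegression().fit([298.2], [0.1])
        with pytest.raises(DegenerateDesignError):
            VantHoffRegression().fit([298.2, 298.2], [0.1, 0.11])

    def test_estimator_is_sklearn_compatible(self):
        est = VantHoffRegression()
        assert est.get_params() == {}
        series = simulate_solubility_series(*OCTANOL_AB, FIVE_TEMPS)
        est.fit(series.temperatures, series.values)
        pred = est.predict(series.temperatures)
        np.testing.assert_allclose(pred, series.values, rtol=1e-12)

    def test_noisy_slope_ci_coverage(self):
        """95% CI on B from 2% multiplicative noise covers the truth >= 90%."""
        a, b = OCTANOL_AB
        hits = 0
        n_rep = 500
        tcrit = stats.t.ppf(0.975, len(FIVE_TEMPS) - 2)
        for seed in range(n_rep):
            noise = NoiseSpec("multiplicative_lognormal", 0.02, seed)
            series = simulate_solubility_series(a, b, FIVE_TEMPS, noise)
            fit = fit_vant_hoff(series)
            if abs(fit.B - b) <= tcrit * fit.se_B:
                hits += 1
        assert hits / n_rep >= 0.90


class TestThermoFunctions:
    def test_octanol_table_values(self):
        fit = fit_vant_hoff(simulate_solubility_series(*OCTANOL_AB, FIVE_TEMPS))
        assert enthalpy_from_fit(fit) / 1000 == pytest.approx(20.5, abs=0.1)
        assert gibbs_at(fit, 298.2) / 1000 == pytest.approx(6.2, abs=0.1)
        tf = thermo_functions(fit, 298.2)
        assert tf.TdS / 1000 == pytest.approx(14.3, abs=0.1)
        assert tf.zeta_h == pytest.approx(58.9, abs=0.2)

    def test_hexane_table_values(self):
        fit = fit_vant_hoff(simulate_solubility_series(*HEXANE_AB, FIVE_TEMPS))
        assert enthalpy_from_fit(fit) / 1000 == pytest.approx(40.0, abs=0.1)
        assert gibbs_at(fit, 310.2) / 1000 == pytest.approx(21.2, abs=0.1)
        assert thermo_functions(fit, 310.2).TdS / 1000 == pytest.approx(18.8, abs=0.1)

    def test_flat_line_gives_zero_enthalpy(self):
        fit = VantHoffFit(A=-2.0, B=0.0, se_A=0, se_B=0, r=0, rss=0, n=3)
        assert enthalpy_from_fit(fit) == 0.0

    def test_ideal_solubility_boundary(self):
        # A + B/T = 0 <=> X2 = 1 <=> dG = 0
        fit = VantHoffFit(A=10.0, B=-10.0 * 298.2, se_A=0, se_B=0, r=1, rss=0, n=2)
        assert gibbs_at(fit, 298.2) == pytest.approx(0.0, abs=1e-9)

    def test_identity_and_monotone_dg(self):
        fit = fit_vant_hoff(simulate_solubility_series(*OCTANOL_AB, FIVE_TEMPS))
        for t in (288.2, 298.2, 310.2, 320.2):
            tf = thermo_functions(fit, t)
            assert tf.dG == pytest.approx(tf.dH - tf.TdS, rel=1e-6)
        # positive entropy term (A > 0) => dG decreases with T
        assert gibbs_at(fit, 310.2) < gibbs_at(fit, 298.2)

    def test_pure_enthalpy_control(self):
        from partisol.solvation import zeta_enthalpy
        assert zeta_enthalpy(5000.0, 0.0) == 100.0

    def test_degenerate_zeta_warns_nan(self):
        from partisol.solvation import zeta_enthalpy
        with pytest.warns(UserWarning):
            assert math.isnan(zeta_enthalpy(0.0, 0.0))

    def test_uncertainty_propagation_orders(self):
        series = simulate_solubility_series(
            *OCTANOL_AB, FIVE_TEMPS,
            NoiseSpec("multiplicative_lognormal", 0.02, 7))
        fit = fit_vant_hoff(series)
        se = thermo_uncertainties(fit, 298.2)
        assert se["dH"] == pytest.approx(8.314 * fit.se_B, rel=1e-12)
        assert se["TdS"] == pytest.approx(8.314 * 298.2 * fit.se_A, rel=1e-12)
        assert 0 < se["dG"] < se["TdS"]  # A, B strongly anticorrelated


class TestTransfer:
    def _fits(self):
        return (fit_vant_hoff(simulate_solubility_series(*HEXANE_AB, FIVE_TEMPS)),
                fit_vant_hoff(simulate_solubility_series(*OCTANOL_AB, FIVE_TEMPS)))

    def test_hexane_to_octanol_table_values(self):
        hx, oc = self._fits()
        tr = transfer_functions(hx, oc, 298.2)
        assert tr.dG / 1000 == pytest.approx(-15.8, abs=0.1)
        assert tr.dH / 1000 == pytest.approx(-19.5, abs=0.1)
        assert tr.zeta_h == pytest.approx(84.1, abs=0.2)

    def test_self_transfer_is_zero(self):
        hx, _ = self._fits()
        with pytest.warns(UserWarning):  # zeta undefined for all-zero process
            tr = transfer_functions(hx, hx, 298.2)
        assert tr.dG == tr.dH == tr.TdS == 0.0

    def test_antisymmetry(self):
        hx, oc = self._fits()
        fwd = transfer_functions(hx, oc, 310.2)
        rev = transfer_functions(oc, hx, 310.2)
        assert fwd.dG == pytest.approx(-rev.dG, rel=1e-12)
        assert fwd.dH == pytest.approx(-rev.dH, rel=1e-12)
        assert fwd.TdS == pytest.approx(-rev.TdS, rel=1e-12)
        assert fwd.zeta_h == pytest.approx(rev.zeta_h, rel=1e-12)


def test_series_validation_and_sorting():
    s = SolubilitySeries("x", "y", [(310.2, 0.2, None), (298.2, 0.1, None)])
    assert list(s.temperatures) == [298.2, 310.2]
    with pytest.raises(ValueError):
        SolubilitySeries("x", "y", [(298.2, -0.1, None)])
    with pytest.raises(ValueError):
        SolubilitySeries("x", "y", [(-5.0, 0.1, None)])
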