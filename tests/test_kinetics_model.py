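"""Rate law, progress-curve simulation, mass-action limit and the
fast-binding diagnostic."""

import numpy as np
import pytest

import bchekit as bk
from bchekit.exceptions import ConfigurationError, InputError
from bchekit.kinetics import linearity_diagnostic


class TestInstantaneousRate:
    def test_half_saturation_michaelis_menten_limit(self):
        p = bk.KineticParams(Km=25.0, kcat=10.0, Kp=50.0, Ki=10.0, Kii=40.0)
        v = bk.instantaneous_rate(S=25.0, P=0.0, I=0.0, params=p,
                                  scheme=bk.MIXED_SCHEME, E0=0.5)
        assert v == pytest.approx(10.0 * 0.5e-3 / 2)

    def test_competitive_denominator_doubles_at_I_equals_Ki(self):
        p = bk.KineticParams(Km=25.0, kcat=10.0, Ki=10.0)
        scheme = bk.SchemeSpec(True, False, False)
        S = 0.01  # S << Km
        v0 = bk.instantaneous_rate(S, 0.0, 0.0, p, scheme, E0=0.5)
        vi = bk.instantaneous_rate(S, 0.0, 10.0, p, scheme, E0=0.5)
        assert vi == pytest.approx(v0 / 2, rel=1e-3)

    def test_mixed_denominator_hand_evaluation(self):
        # denominator 25*(1+20/10) + 50*(1+20/40) = 150 -> kcat*E0/3
        p = bk.KineticParams(Km=25.0, kcat=10.0, Ki=10.0, Kii=40.0)
        scheme = bk.SchemeSpec(True, True, False)
        v = bk.instantaneous_rate(S=50.0, P=0.0, I=20.0, params=p, scheme=scheme, E0=0.5)
        assert v == pytest.approx(10.0 * 0.5e-3 / 3)
        assert v == pytest.approx(1.667e-3, rel=1e-3)  # 1.667 nM/s in uM/s

    def test_zero_substrate_gives_zero_rate(self, toy_params):
        assert bk.instantaneous_rate(0.0, 10.0, 50.0, toy_params, bk.MIXED_SCHEME, 0.5) == 0.0

    def test_rate_strictly_decreasing_in_inhibitor(self, toy_params):
        rates = [bk.instantaneous_rate(50.0, 0.0, I, toy_params, bk.MIXED_SCHEME, 0.5)
                 for I in (0.0, 5.0, 20.0, 100.0)]
        assert all(a > b for a, b in zip(rates, rates[1:]))

    def test_negative_concentration_rejected(self, toy_params):
        with pytest.raises(InputError):
            bk.instantaneous_rate(-1.0, 0.0, 0.0, toy_params, bk.MIXED_SCHEME, 0.5)

    def test_missing_branch_constant_rejected(self):
        p = bk.KineticParams(Km=25.0, kcat=10.0, Kp=50.0, Ki=10.0)  # no Kii
        with pytest.raises(ConfigurationError):
            bk.instantaneous_rate(50.0, 0.0, 10.0, p, bk.MIXED_SCHEME, 0.5)


class TestSimulateProgress:
    def test_uninhibited_curve_reaches_complete_hydrolysis(self, conditions, t_grid):
        params = bk.TRUTH_SETS["r-minus-3-purified"]
        curve = bk.simulate_progress(params, bk.MIXED_SCHEME, conditions, 0.0, t_grid)
        assert curve.product[0] == 0.0
        assert np.all(np.diff(curve.product) >= -1e-12)
        assert np.all(curve.product <= conditions.S0 + 1e-9)
        assert curve.product[-1] == pytest.approx(conditions.S0, rel=5e-3)

    def test_saturating_inhibitor_freezes_reaction(self, toy_params, conditions, coarse_grid):
        curve = bk.simulate_progress(toy_params, bk.MIXED_SCHEME, conditions, 1e9, coarse_grid)
        assert np.all(curve.product < 0.05 * conditions.S0)

    def test_half_hydrolysis_time_matches_euler_oracle(self, toy_params, conditions, t_grid):
        """Independent fine-grid explicit-Euler integration of the same rate law."""
        S0, E0 = conditions.S0, conditions.E0
        dt = 0.001
        P, t, t_half = 0.0, 0.0, None
        while t < t_grid[-1]:
            P += dt * bk.instantaneous_rate(S0 - P, P, 0.0, toy_params, bk.MIXED_SCHEME, E0)
            t += dt
            if t_half is None and P >= S0 / 2:
                t_half = t
                break
        curve = bk.simulate_progress(toy_params, bk.MIXED_SCHEME, conditions, 0.0, t_grid)
        t_half_ivp = np.interp(S0 / 2, curve.product, curve.times)
        assert t_half_ivp == pytest.approx(t_half, rel=5e-3)

    def test_bad_grid_rejected(self, toy_params, conditions):
        with pytest.raises(InputError):
            bk.simulate_progress(toy_params, bk.MIXED_SCHEME, conditions, 0.0, [1.0, 2.0])


MA_SCHEME = bk.SchemeSpec(True, True, True, binding_mode="explicit-association")


class TestMassAction:

    def test_enzyme_conservation(self, toy_params, conditions, coarse_grid):
        p = toy_params.replace(k_on=10.0)
        _curve, species = bk.simulate_mass_action(
            p, MA_SCHEME, conditions, 50.0, coarse_grid, return_species=True)
        total = sum(species[n] for n in ("E", "ES", "EI", "ESI", "EP"))
        E0_uM = conditions.E0 * 1e-3
        assert np.max(np.abs(total - E0_uM)) <= 1e-6 * E0_uM + 1e-9

    def test_substrate_plus_product_conserved(self, toy_params, conditions, coarse_grid):
        p = toy_params.replace(k_on=10.0)
        _curve, species = bk.simulate_mass_action(
            p, MA_SCHEME, conditions, 50.0, coarse_grid, return_species=True)
        total = species["S"] + species["P"] + species["ES"] + species["ESI"] + species["EP"]
        assert np.max(np.abs(total - conditions.S0)) < 1e-4 * conditions.S0

    def test_fast_binding_limit_matches_rapid_equilibrium(
            self, toy_params, conditions, coarse_grid):
        re_curve = bk.simulate_progress(toy_params, bk.MIXED_SCHEME, conditions, 50.0, coarse_grid)
        errs = []
        for k_on in (1e-3, 1e-2, 1e-1):
            ma = bk.simulate_mass_action(
                toy_params.replace(k_on=k_on), MA_SCHEME, conditions, 50.0, coarse_grid,
                fast_rate=2000.0)
            errs.append(np.max(np.abs(ma.product - re_curve.product)))
        assert errs[0] > errs[1] > errs[2]          # monotone convergence
        assert errs[-1] < 0.01 * conditions.S0      # within 1% at large k_on

    def test_slow_binding_flagged_by_linearity_diagnostic(
            self, toy_params, conditions):
        t = np.arange(0.0, 601.0, 2.0)
        slow = bk.simulate_mass_action(
            toy_params.replace(k_on=1e-4), MA_SCHEME, conditions, 200.0, t)
        out = linearity_diagnostic(slow, S0=conditions.S0)
        assert out["label"] == "slow-binding-suspect"


class TestAbsorbance:
    def test_beer_lambert_scaling(self, conditions):
        t = np.arange(6.0)
        curve = bk.ProgressCurve(times=t, product=np.array([0, 10, 20, 30, 40, 50.0]))
        out = bk.product_to_absorbance(curve, conditions)
        assert out.absorbance[0] == 0.0
        # doubling product doubles absorbance
        assert out.absorbance[2] == pytest.approx(2 * out.absorbance[1])
        # 14150 M^-1 cm^-1 * 0.05 cm * 50 uM = 0.0354 AU
        assert out.absorbance[-1] == pytest.approx(0.0354, abs=2e-4)

    def test_missing_epsilon_rejected(self):
        cond = bk.AssayConditions()
        object.__setattr__(cond, "epsilon", -1.0)
        curve = bk.ProgressCurve(times=np.arange(3.0), product=np.zeros(3))
        with pytest.raises(ConfigurationError):
            bk.product_to_absorbance(curve, cond)


class TestLinearityDiagnostic:
    def test_exactly_linear_curve_is_fast_binding(self):
        t = np.arange(0.0, 100.0, 1.0)
        curve = bk.ProgressCurve(times=t, product=0.01 * t)
        out = linearity_diagnostic(curve)
        assert out["statistic"] == pytest.approx(0.0, abs=1e-10)
        assert out["label"] == "fast-binding"

    def test_reference_design_curves_all_fast_binding(self, conditions, t_grid):
        params = bk.TRUTH_SETS["r-minus-3-purified"]
        for I in bk.FIG_DESIGN_INHIBITOR_NM:
            curve = bk.simulate_progress(params, bk.MIXED_SCHEME, conditions, I, t_grid)
            out = linearity_diagnostic(curve, S0=conditions.S0)
            assert out["label"] == "fast-binding", f"I={I}: stat {out['statistic']}"

    def test_too_few_points_rejected(self):
        t = np.arange(0.0, 5.0)
        curve = bk.ProgressCurve(times=t, product=0.01 * t)
        with pytest.raises(InputError):
            linearity_diagnostic(curve)
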