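"""Global progress-curve fitting: recovery, scheme selection, uncertainty."""

import numpy as np
import pytest

import bchekit as bk
from bchekit import fitting, synthetic
from bchekit.exceptions import InputError
from bchekit.fitting import FitConfig, confidence_intervals, fit_progress_set

NO_PRODUCT_SCHEME = bk.SchemeSpec(True, True, False)


@pytest.fixture(scope="module")
def no_product_set(conditions):
    """Noiseless family from a scheme without product inhibition (fully identifiable)."""
    params = bk.TRUTH_SETS["toy"].replace(Kp=None)
    return params, synthetic.generate_progress_set(
        params, NO_PRODUCT_SCHEME, conditions, replicates=1)


def test_noiseless_recovery_all_free(no_product_set):
    """Refitting the model's own noiseless output recovers every generating
    constant to well under 0.1% when all parameters are identifiable."""
    params, cs = no_product_set
    res = fit_progress_set(cs, NO_PRODUCT_SCHEME, FitConfig(multistart=1))
    assert res.converged
    for name in ("Km", "kcat", "Ki", "Kii"):
        est = res.estimates.as_dict()[name]
        truth = params.as_dict()[name]
        assert abs(est / truth - 1) < 1e-3, name


def test_noiseless_recovery_with_product_inhibition_km_known(conditions):
    """With product inhibition on, Km must be known (single-S0 design);
    the remaining constants are then recovered essentially exactly."""
    truth = bk.TRUTH_SETS["toy"]
    cs = synthetic.generate_progress_set(truth, bk.MIXED_SCHEME, conditions, replicates=1)
    res = fit_progress_set(
        cs, bk.MIXED_SCHEME,
        FitConfig(free_parameters=("kcat", "Kp", "Ki", "Kii"), multistart=1),
        fixed_params={"Km": truth.Km})
    for name in ("kcat", "Kp", "Ki", "Kii"):
        assert abs(res.estimates.as_dict()[name] / truth.as_dict()[name] - 1) < 1e-3, name


def test_all_free_fit_with_product_inhibition_flags_degeneracy(conditions):
    """Fitting all five constants at a single S0 leaves one flat direction,
    which the fit must flag as unidentifiable."""
    truth = bk.TRUTH_SETS["toy"]
    cs = synthetic.generate_progress_set(truth, bk.MIXED_SCHEME, conditions, replicates=1)
    res = fit_progress_set(cs, bk.MIXED_SCHEME, FitConfig(multistart=1))
    assert any("unidentifiable" in w for w in res.warnings)


def test_global_objective_equals_brute_force_rss(no_product_set, conditions):
    """The fit's RSS equals the curve-by-curve sum of squared deviations."""
    params, _ = no_product_set
    rng = np.random.default_rng(7)
    t = np.arange(0.0, 601.0, 20.0)
    curves = []
    for I in (0.0, 50.0):
        c = bk.simulate_progress(params, NO_PRODUCT_SCHEME, conditions, I, t)
        curves.append(bk.ProgressCurve(times=t, product=c.product + rng.normal(0, 0.3, t.size),
                                       inhibitor_conc=I, is_noisy=True))
    cs = bk.ProgressCurveSet(conditions=conditions, curves=curves)
    res = fit_progress_set(cs, NO_PRODUCT_SCHEME, FitConfig(multistart=1))
    brute = 0.0
    for c in curves:
        pred = bk.simulate_progress(res.estimates, NO_PRODUCT_SCHEME, conditions,
                                    c.inhibitor_conc, c.times)
        brute += float(np.sum((c.product - pred.product) ** 2))
    assert res.rss == pytest.approx(brute, rel=1e-6)


def test_noisy_design_recovers_ki_within_tolerance(conditions):
    """Duplicate noisy curves at the reference design recover Ki closely."""
    truth = bk.TRUTH_SETS["r-minus-3-purified"]
    cs = synthetic.generate_progress_set(
        truth, bk.MIXED_SCHEME, conditions, replicates=2,
        noise=synthetic.NoiseSpec(sigma=synthetic.default_kinetics_sigma(conditions), seed=11))
    res = fit_progress_set(
        cs, bk.MIXED_SCHEME,
        FitConfig(free_parameters=("kcat", "Kp", "Ki", "Kii"), multistart=2, seed=11),
        fixed_params={"Km": truth.Km})
    assert abs(res.estimates.Ki / truth.Ki - 1) < 0.10


def test_median_ki_bias_small_across_seeds(conditions):
    """Median relative bias of Ki across simulated datasets stays below 5%."""
    truth = bk.TRUTH_SETS["toy"]
    sigma = synthetic.default_kinetics_sigma(conditions)
    biases = []
    for seed in range(8):
        cs = synthetic.generate_progress_set(
            truth, bk.MIXED_SCHEME, conditions, replicates=1,
            noise=synthetic.NoiseSpec(sigma=sigma, seed=seed), dt=5.0)
        res = fit_progress_set(
            cs, bk.MIXED_SCHEME,
            FitConfig(free_parameters=("kcat", "Kp", "Ki", "Kii"), multistart=1),
            fixed_params={"Km": truth.Km})
        biases.append(res.estimates.Ki / truth.Ki - 1)
    assert abs(np.median(biases)) < 0.05


class TestCompareSchemes:
    def test_single_candidate_selected(self, no_product_set):
        _params, cs = no_product_set
        table, selected = fitting.compare_schemes(cs, [NO_PRODUCT_SCHEME],
                                                  FitConfig(multistart=1))
        assert selected == NO_PRODUCT_SCHEME
        assert table[0]["delta_aicc"] == 0.0

    def test_mixed_generative_model_beats_single_branch_schemes(self, conditions):
        truth = bk.TRUTH_SETS["toy"].replace(Kp=None)  # distinct Ki=10, Kii=40
        cs = synthetic.generate_progress_set(
            truth, NO_PRODUCT_SCHEME, conditions, replicates=2,
            noise=synthetic.NoiseSpec(sigma=0.25, seed=3), dt=5.0)
        candidates = [
            NO_PRODUCT_SCHEME,
            bk.SchemeSpec(True, False, False),   # competitive-only
            bk.SchemeSpec(False, True, False),   # uncompetitive-only
        ]
        table, selected = fitting.compare_schemes(cs, candidates, FitConfig(multistart=1))
        assert selected == NO_PRODUCT_SCHEME
        assert table[0]["scheme"] == NO_PRODUCT_SCHEME

    def test_parsimony_tie_break_prefers_competitive_for_competitive_data(self, conditions):
        truth = bk.KineticParams(Km=25.0, kcat=500.0, Ki=10.0)
        comp = bk.SchemeSpec(True, False, False)
        cs = synthetic.generate_progress_set(
            truth, comp, conditions, replicates=2,
            noise=synthetic.NoiseSpec(sigma=0.25, seed=4), dt=5.0)
        table, selected = fitting.compare_schemes(
            cs, [NO_PRODUCT_SCHEME, comp], FitConfig(multistart=1))
        assert selected == comp

    def test_superfluous_uncompetitive_branch_is_negligible(self, conditions):
        """Fitting the mixed scheme to competitive-only data leaves the ES-complex
        branch with no measurable contribution."""
        truth = bk.KineticParams(Km=25.0, kcat=500.0, Ki=10.0)
        comp = bk.SchemeSpec(True, False, False)
        cs = synthetic.generate_progress_set(
            truth, comp, conditions, replicates=1,
            noise=synthetic.NoiseSpec(sigma=0.25, seed=5), dt=5.0)
        res_mixed = fit_progress_set(cs, NO_PRODUCT_SCHEME, FitConfig(multistart=1))
        res_comp = fit_progress_set(cs, comp, FitConfig(multistart=1))
        at_upper_bound = res_mixed.estimates.Kii > 100 * truth.Ki
        rss_change = abs(res_comp.rss - res_mixed.rss) / res_comp.rss
        assert at_upper_bound or rss_change < 0.005


class TestUnidentifiability:
    def test_control_only_data_flags_inhibition_constants(self, conditions):
        truth = bk.TRUTH_SETS["toy"].replace(Kp=None)
        t = np.arange(0.0, 601.0, 10.0)
        curve = bk.simulate_progress(truth, NO_PRODUCT_SCHEME, conditions, 0.0, t)
        cs = bk.ProgressCurveSet(conditions=conditions, curves=[curve])
        res = fit_progress_set(cs, NO_PRODUCT_SCHEME, FitConfig(multistart=1))
        assert any("unidentifiable" in w for w in res.warnings)


@pytest.fixture(scope="module")
def small_noisy_fit(conditions):
    truth = bk.TRUTH_SETS["toy"]
    cs = synthetic.generate_progress_set(
        truth, bk.MIXED_SCHEME, conditions, inhibitor_concs=(0.0, 20.0),
        replicates=1, noise=synthetic.NoiseSpec(sigma=0.25, seed=21), dt=30.0)
    cfg = FitConfig(free_parameters=("kcat", "Ki"), multistart=1)
    fixed = {"Km": truth.Km, "Kp": truth.Kp, "Kii": truth.Kii}
    fit = fit_progress_set(cs, bk.MIXED_SCHEME, cfg, fixed_params=fixed)
    return truth, cs, fit


class TestConfidenceIntervals:
    def test_bootstrap_reproducible_under_seed_and_contains_estimate(self, small_noisy_fit):
        _truth, cs, fit = small_noisy_fit
        ci1 = confidence_intervals(cs, bk.MIXED_SCHEME, fit, B=100, seed=5)
        ci2 = confidence_intervals(cs, bk.MIXED_SCHEME, fit, B=100, seed=5)
        assert ci1 == ci2
        for name, (lo, hi) in ci1.items():
            assert lo <= fit.estimates.as_dict()[name] <= hi

    def test_noiseless_interval_width_vanishes(self, conditions):
        truth = bk.TRUTH_SETS["toy"]
        cs = synthetic.generate_progress_set(
            truth, bk.MIXED_SCHEME, conditions, inhibitor_concs=(0.0, 20.0),
            replicates=1, dt=30.0)
        cfg = FitConfig(free_parameters=("kcat", "Ki"), multistart=1)
        fixed = {"Km": truth.Km, "Kp": truth.Kp, "Kii": truth.Kii}
        fit = fit_progress_set(cs, bk.MIXED_SCHEME, cfg, fixed_params=fixed)
        ci = confidence_intervals(cs, bk.MIXED_SCHEME, fit, B=100, seed=1)
        lo, hi = ci["Ki"]
        assert (hi - lo) / fit.estimates.Ki < 1e-3

    def test_small_B_rejected(self, small_noisy_fit):
        _truth, cs, fit = small_noisy_fit
        with pytest.raises(InputError):
            confidence_intervals(cs, bk.MIXED_SCHEME, fit, B=10, seed=0)
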