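"""Mono-exponential fitting and cumulated-activity integration."""
import math

import numpy as np
import pytest
from scipy.integrate import quad

import biodosim as bd
from biodosim.errors import ConfigError, FitError, InvalidInputError
from conftest import make_study, monoexp_tac


class TestFitMonoexp:
    def test_exact_generative_recovery(self, lu177):
        tac = monoexp_tac(lu177, 10.0, 0.1, [1, 5, 10, 20, 40])
        fit = bd.fit_monoexp(tac)
        assert fit.a0 == pytest.approx(10.0, rel=1e-9)
        assert fit.lambda_bio_raw == pytest.approx(0.1, rel=1e-9)
        assert not fit.accumulating

    def test_two_point_closed_form(self, lu177):
        tac = bd.TimeActivityCurve(organ="x", times_h=[1.0, 3.0], values=[8.0, 2.0],
                                   nuclide=lu177)
        fit = bd.fit_monoexp(tac)
        assert fit.lambda_bio_raw == pytest.approx(math.log(4) / 2, rel=1e-9)
        assert fit.a0 == pytest.approx(16.0, rel=1e-9)

    def test_flat_curve_gives_zero_rate(self, lu177):
        tac = bd.TimeActivityCurve(organ="x", times_h=[2, 24, 48], values=[5, 5, 5],
                                   nuclide=lu177)
        assert bd.fit_monoexp(tac).lambda_bio_raw == pytest.approx(0.0, abs=1e-12)

    def test_accumulating_curve_clamped(self, lu177):
        tac = bd.TimeActivityCurve(organ="Tumor", times_h=[2, 24, 168],
                                   values=[2.5, 11.4, 20.6], nuclide=lu177)
        fit = bd.fit_monoexp(tac)
        assert fit.lambda_bio_raw < 0           # raw diagnostic kept
        assert fit.accumulating
        assert fit.lambda_bio == 0.0            # clamped for integration
        assert fit.lambda_eff == pytest.approx(lu177.lambda_phys)

    def test_nlls_refines_loglinear(self, lu177):
        rng = np.random.default_rng(7)
        t = np.array([2.0, 24, 48, 96, 168])
        y = 12 * np.exp(-0.02 * t) * rng.lognormal(0, 0.05, t.size)
        tac = bd.TimeActivityCurve(organ="x", times_h=t, values=y, nuclide=lu177)
        fit = bd.fit_monoexp(tac, method="nlls")
        assert fit.method == "nlls"
        assert fit.lambda_bio_raw == pytest.approx(0.02, rel=0.2)

    def test_too_few_positive_points(self, lu177):
        tac = bd.TimeActivityCurve(organ="x", times_h=[1, 2, 3],
                                   values=[4.0, 0.0, 0.0], nuclide=lu177)
        with pytest.raises(FitError):
            bd.fit_monoexp(tac)


class TestCumulatedMonoexp:
    def test_decay_only_residence_is_half_life_over_ln2(self, lu177):
        fit = bd.MonoExpFit(organ="wb", a0=100.0, lambda_bio_raw=0.0, nuclide=lu177)
        ca = bd.cumulated_activity_monoexp(fit, injected_mbq=3.7)
        assert ca.residence_time_h == pytest.approx(lu177.half_life_h / math.log(2),
                                                    rel=1e-9)

    def test_point_five_over_point_two(self, lu177):
        lam_bio = 0.2 - lu177.lambda_phys
        fit = bd.MonoExpFit(organ="x", a0=50.0, lambda_bio_raw=lam_bio, nuclide=lu177)
        ca = bd.cumulated_activity_monoexp(fit, injected_mbq=1.0)
        assert ca.residence_time_h == pytest.approx(2.5, rel=1e-12)

    def test_linearity_in_injected(self, lu177):
        fit = bd.MonoExpFit(organ="x", a0=20.0, lambda_bio_raw=0.01, nuclide=lu177)
        ca1 = bd.cumulated_activity_monoexp(fit, 1.0)
        ca2 = bd.cumulated_activity_monoexp(fit, 2.0)
        assert ca2.value_mbq_h == pytest.approx(2 * ca1.value_mbq_h, rel=1e-12)
        assert ca2.residence_time_h == pytest.approx(ca1.residence_time_h, rel=1e-12)

    @pytest.mark.parametrize("a0,lam_bio", [(100.0, 0.0), (20.0, 0.01), (3.0, 0.2)])
    def test_closed_form_matches_fine_grid_quadrature(self, lu177, a0, lam_bio):
        fit = bd.MonoExpFit(organ="x", a0=a0, lambda_bio_raw=lam_bio, nuclide=lu177)
        ca = bd.cumulated_activity_monoexp(fit, 1.0)
        numeric, _ = quad(lambda t: a0 / 100 * math.exp(-fit.lambda_eff * t),
                          0, np.inf)
        assert ca.value_mbq_h == pytest.approx(numeric, rel=1e-3 * 0.1)


class TestCumulatedHybrid:
    def test_agrees_with_monoexp_on_single_compartment(self, lu177):
        # >= 6 points over 3 effective half-lives
        lam_bio = 0.01
        lam_eff = lam_bio + lu177.lambda_phys
        horizon = 3 * math.log(2) / lam_eff
        times = np.linspace(horizon / 12, horizon, 8)
        tac = monoexp_tac(lu177, 10.0, lam_bio, times)
        hybrid = bd.cumulated_activity_hybrid(tac, 1.0, tail="fitted",
                                              t0_mode="extrapolate")
        fit = bd.fit_monoexp(tac)
        closed = bd.cumulated_activity_monoexp(fit, 1.0)
        assert hybrid.value_mbq_h == pytest.approx(closed.value_mbq_h, rel=0.02)

    def test_physical_tail_equals_analytic_remainder(self, lu177):
        # curve that is exactly a0*exp(-lambda_phys t): biological rate zero
        times = np.linspace(0, 300, 400)
        tac = monoexp_tac(lu177, 10.0, 0.0, times)
        ca = bd.cumulated_activity_hybrid(tac, 1.0, tail="physical")
        exact = 10.0 / 100.0 / lu177.lambda_phys
        assert ca.value_mbq_h == pytest.approx(exact, rel=1e-4)

    def test_all_zero_curve_integrates_to_zero(self, lu177):
        tac = bd.TimeActivityCurve(organ="x", times_h=[1, 2, 3], values=[0, 0, 0],
                                   nuclide=lu177)
        ca = bd.cumulated_activity_hybrid(tac, 1.0)
        assert ca.value_mbq_h == 0.0

    def test_unknown_tail_label(self, lu177):
        tac = monoexp_tac(lu177, 5.0, 0.01, [1, 2, 4])
        with pytest.raises(ConfigError):
            bd.cumulated_activity_hybrid(tac, 1.0, tail="bogus")

    def test_fitted_tail_floored_at_physical(self, lu177):
        # terminal slope shallower than physical decay cannot happen for a
        # decay-inclusive curve unless noise; flooring keeps the tail finite
        tac = bd.TimeActivityCurve(organ="x", times_h=[10, 100, 300],
                                   values=[5.0, 5.0, 5.0], nuclide=lu177,
                                   decay_corrected=False)
        ca = bd.cumulated_activity_hybrid(tac, 1.0, tail="fitted")
        tail_used = ca.value_mbq_h - np.trapezoid([0, 5, 5, 5],
                                                  [0, 10, 100, 300]) / 100.0
        assert tail_used == pytest.approx(5.0 / 100 / lu177.lambda_phys, rel=1e-9)


def test_residence_sum_respects_physical_bound(lu177):
    """Total recovered activity <= 100 %ID keeps the tau sum below T1/2/ln2."""
    cfg = bd.SyntheticConfig(
        nuclide=lu177, injected_mbq=1.0, timepoints_h=(2, 24, 72, 168, 336),
        organs={"A": bd.MonoExpKinetics(40.0, 0.002),
                "B": bd.MonoExpKinetics(30.0, 0.01),
                "C": bd.MonoExpKinetics(20.0, 0.0)},
        n_per_timepoint=2, cv=0.0, seed=1)
    study, _ = bd.generate_study(cfg)
    total = 0.0
    for organ in study.organs:
        ca, _ = bd.cumulated_activity_auto(bd.tac_from_study(study, organ), 1.0)
        total += ca.residence_time_h
    assert total <= bd.residence_time_bound_h(lu177)


def test_parameter_recovery_smoke(lu177):
    """Median lambda_bio error over 50 noisy replicates stays small."""
    truth = bd.MonoExpKinetics(15.0, 0.01)
    errors = []
    for seed in range(50):
        cfg = bd.SyntheticConfig(
            nuclide=lu177, injected_mbq=1.0,
            timepoints_h=(2, 24, 72, 120, 168, 336),
            organs={"Liver": truth}, n_per_timepoint=4, cv=0.10, seed=seed)
        study, _ = bd.generate_study(cfg)
        fit = bd.fit_monoexp(bd.tac_from_study(study, "Liver"))
        errors.append(abs(fit.lambda_bio_raw - truth.lambda_bio) / truth.lambda_bio)
    assert np.median(errors) < 0.05


def test_tac_from_study_orders_and_averages(lu177):
    study = make_study(lu177, [
        ("Liver", "a1", 24.0, 6.0), ("Liver", "a2", 24.0, 8.0),
        ("Liver", "b1", 2.0, 10.0), ("Liver", "b2", 2.0, 12.0),
    ])
    tac = bd.tac_from_study(study, "Liver")
    assert list(tac.times_h) == [2.0, 24.0]
    assert list(tac.values) == [11.0, 7.0]
    assert list(tac.n) == [2, 2]


def test_curve_validation(lu177):
    with pytest.raises(InvalidInputError):
        bd.TimeActivityCurve(organ="x", times_h=[2, 1], values=[1, 2], nuclide=lu177)
    with pytest.raises(InvalidInputError):
        bd.TimeActivityCurve(organ="x", times_h=[1], values=[1], nuclide=lu177)
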