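"""FU and FU+A likelihoods: hand-computed contributions, structural
identities, ML fitting, and test calibration on null-simulated cohorts."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from jointsurv import (
    FitResult,
    GompertzGenoModel,
    SimulationDesign,
    fit_mle,
    loglik_fu,
    loglik_fua,
    simulate_cohort,
    test_gamma,
)


def one_record(g=1, entry=70.0, exit_=74.0, event=1):
    return pd.DataFrame(
        [{"g": g, "entry_age": entry, "exit_age": exit_, "event": event}]
    )


def test_fu_single_record_hand_computed():
    # delta*ln mu(74|1) - (H(74|1) - H(70|1)) at log_a=-9, b=0.08, gamma=0.4,
    # summed by hand with the closed forms
    ll = loglik_fu(one_record(), log_a=-9.0, b=0.08, gamma=0.4)
    assert ll == pytest.approx(-2.9147010723301747, rel=1e-12)


def test_fu_censored_contribution_is_negative():
    ll = loglik_fu(one_record(event=0, exit_=76.0), log_a=-9.0, b=0.08, gamma=0.4)
    assert ll < 0  # pure exposure term -(H(x)-H(u))


def test_fu_gamma_ignores_noncarriers():
    cohort = pd.DataFrame(
        [
            {"g": 0, "entry_age": 60.0, "exit_age": 63.0, "event": 1},
            {"g": 0, "entry_age": 80.0, "exit_age": 86.0, "event": 0},
        ]
    )
    assert loglik_fu(cohort, -9.0, 0.08, 0.0) == loglik_fu(cohort, -9.0, 0.08, 0.9)


def test_fua_reduces_to_fu_plus_binomial_under_null(rng, null_model):
    d = SimulationDesign(model=null_model, n_sample=500)
    c = simulate_cohort(d, rng)
    n1 = int(c.g.sum())
    n0 = len(c) - n1
    p0 = 0.3
    expected = loglik_fu(c, -9.0, 0.08, 0.0) + n1 * np.log(p0) + n0 * np.log1p(-p0)
    assert loglik_fua(c, -9.0, 0.08, 0.0, p0) == pytest.approx(expected, rel=1e-12)


def test_fua_increment_single_carrier_at_80():
    # ln pi_1(80) under gamma=0.4, p0=0.25, from quadrature-verified survival
    c = one_record(g=1, entry=80.0, exit_=83.0, event=1)
    inc = loglik_fua(c, -9.0, 0.08, 0.4, 0.25) - loglik_fu(c, -9.0, 0.08, 0.4)
    assert inc == pytest.approx(-1.746168029403565, rel=1e-10)


def test_fua_increment_ignores_exit_data(reference_design, rng):
    """The age-structure term depends only on (g, entry_age)."""
    d = SimulationDesign(model=reference_design.model, n_sample=300)
    c = simulate_cohort(d, rng)
    args = (-9.1, 0.075, 0.3, 0.22)
    inc = loglik_fua(c, *args) - loglik_fu(c, *args[:3])
    c2 = c.copy()
    c2["exit_age"] = c2["entry_age"] + 1.0
    c2["event"] = 1
    inc2 = loglik_fua(c2, *args) - loglik_fu(c2, *args[:3])
    assert inc == pytest.approx(inc2, rel=1e-12)


def test_parameter_validation(reference_design, rng):
    c = simulate_cohort(SimulationDesign(model=reference_design.model, n_sample=50), rng)
    with pytest.raises(ValueError):
        loglik_fu(c, -9.0, -0.08, 0.0)
    with pytest.raises(ValueError):
        loglik_fua(c, -9.0, 0.08, 0.0, 1.2)
    with pytest.raises(ValueError):
        loglik_fu(c.iloc[:0], -9.0, 0.08, 0.0)


def test_fit_recovers_generating_parameters(reference_design):
    c = simulate_cohort(reference_design, np.random.default_rng(42))
    for method in ("FU", "FUA"):
        fit = fit_mle(c, method)
        assert fit.converged
        assert fit.n_used == 4500
        se = fit.std_errors["gamma"]
        assert se > 0
        assert abs(fit.estimates["gamma"] - 0.4) < 3 * se
        if method == "FUA":
            assert abs(fit.estimates["p0"] - 0.25) < 3 * fit.std_errors["p0"]
            assert set(fit.estimates) == {"log_a", "b", "gamma", "p0"}
        else:
            assert set(fit.estimates) == {"log_a", "b", "gamma"}


def test_fit_is_order_invariant(reference_design):
    c = simulate_cohort(reference_design, np.random.default_rng(3))
    f1 = fit_mle(c, "FUA")
    f2 = fit_mle(c.sample(frac=1, random_state=0).reset_index(drop=True), "FUA")
    for k in f1.estimates:
        assert f1.estimates[k] == pytest.approx(f2.estimates[k], abs=1e-5)


def test_degenerate_cohorts_rejected(rng, frailty_model):
    c = simulate_cohort(SimulationDesign(model=frailty_model, n_sample=200), rng)
    no_events = c.assign(event=0, exit_age=c.entry_age + 6.0)
    with pytest.raises(ValueError, match="event"):
        fit_mle(no_events, "FU")
    single_geno = c.assign(g=0)
    with pytest.raises(ValueError, match="genotype"):
        fit_mle(single_geno, "FU")


def test_profile_fit_matches_joint_fit(frailty_model):
    """Maximizing over gamma with the nuisance parameters pinned at the
    joint fit reproduces the joint gamma estimate; pinning at truth on a
    large cohort agrees within sampling tolerance."""
    d = SimulationDesign(model=frailty_model, n_sample=50_000)
    c = simulate_cohort(d, np.random.default_rng(9))
    fit = fit_mle(c, "FUA")
    est = fit.estimates

    def neg_profile(gamma, log_a, b, p0):
        return -loglik_fua(c, log_a, b, gamma, p0)

    at_fit = optimize.minimize_scalar(
        neg_profile, bounds=(-1, 1), method="bounded",
        args=(est["log_a"], est["b"], est["p0"]),
        options={"xatol": 1e-10},
    )
    assert at_fit.x == pytest.approx(est["gamma"], abs=1e-5)

    at_truth = optimize.minimize_scalar(
        neg_profile, bounds=(-1, 1), method="bounded",
        args=(-9.0, 0.08, 0.25), options={"xatol": 1e-10},
    )
    assert at_truth.x == pytest.approx(est["gamma"], abs=3 * fit.std_errors["gamma"])


def test_wald_trivial_values():
    fit = FitResult(method="FU", estimates={"gamma": 0.0}, std_errors={"gamma": 0.1})
    z, p = test_gamma(fit, kind="wald")
    assert z == 0.0 and p == 1.0


def test_lrt_critical_value():
    fit = FitResult(method="FU", loglik=-100.0)
    null = FitResult(method="FU", loglik=-101.92)
    lam, p = test_gamma(fit, null, kind="lrt")
    assert lam == pytest.approx(3.84)
    assert p == pytest.approx(0.05, abs=1e-3)


def test_lrt_method_mismatch():
    with pytest.raises(ValueError, match="mismatch"):
        test_gamma(FitResult(method="FUA"), FitResult(method="FU"), kind="lrt")


def test_null_calibration_and_test_agreement(null_model):
    """Under gamma = 0 the Wald type-I error sits at the nominal level and
    Wald/LRT decisions almost always coincide."""
    d = SimulationDesign(model=null_model, n_sample=1000)
    n_reps, agree, rej_wald = 200, 0, 0
    for r in range(n_reps):
        c = simulate_cohort(d, np.random.default_rng([55, r]))
        fit = fit_mle(c, "FU")
        _, p_w = test_gamma(fit, kind="wald")
        null_fit = fit_mle(c, "FU", fix_gamma=0.0)
        _, p_l = test_gamma(fit, null_fit, kind="lrt")
        rej_wald += p_w < 0.05
        agree += (p_w < 0.05) == (p_l < 0.05)
    rate = rej_wald / n_reps
    se = np.sqrt(0.05 * 0.95 / n_reps)
    assert abs(rate - 0.05) < 3 * se
    assert agree / n_reps >= 0.95
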