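"""Simulation-based power comparison of the FU and FU+A estimators.

Runs a grid of effect sizes, fits both likelihoods to every replicate
cohort, and summarizes the sampling SD of the gamma estimate and the
empirical power of the Wald test per scenario.  The empirical power
curves are then fitted by the power function of a two-sided one-sample
Z-test of the mean,

    w(gamma; sigma, alpha) = Phi(-z_{1-alpha/2} + gamma/sigma)
                           + Phi(-z_{1-alpha/2} - gamma/sigma),

yielding a single best-fit SD per method, from which level-of-test
curves (the alpha needed for power 0.8 as a function of effect size)
follow analytically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cohort import SimulationDesign, simulate_cohort
from .likelihood import fit_mle, test_gamma

__all__ = [
    "ScenarioResult",
    "PowerCurveFit",
    "run_scenario",
    "run_grid",
    "default_gamma_grid",
    "z_test_power",
    "fit_power_curve",
    "alpha_for_power",
    "estimate_distribution_summary",
    "results_to_frame",
]

METHODS = ("FU", "FUA")


def default_gamma_grid() -> np.ndarray:
    """Effect sizes -0.5 to 0.5 in steps of 0.05 (21 scenarios)."""
    return np.round(np.arange(-10, 11) * 0.05, 2)


@dataclass
class ScenarioResult:
    """Per-effect-size summary across replicates, keyed by method."""

    gamma_true: float
    n_reps: int
    alpha: float
    mean_gamma: dict = field(default_factory=dict)
    sd_gamma: dict = field(default_factory=dict)
    power_hat: dict = field(default_factory=dict)
    power_lrt: dict = field(default_factory=dict)
    n_nonconverged: dict = field(default_factory=dict)
    gamma_estimates: dict = field(default_factory=dict)  # per-method arrays


@dataclass
class PowerCurveFit:
    """Z-test SD giving the best least-squares fit to an empirical power curve."""

    method: str
    sigma_fit: float
    alpha: float

    def __post_init__(self) -> None:
        if self.sigma_fit <= 0:
            raise ValueError("sigma_fit must be positive")


def _replicate_rng(master_seed: int, gamma_true: float, rep: int) -> np.random.Generator:
    """Deterministic per-replicate stream: any replicate is reproducible alone."""
    scen_key = int(round(gamma_true * 1000)) % (2**31)
    return np.random.default_rng(np.random.SeedSequence([master_seed, scen_key, rep]))


def run_scenario(
    design: SimulationDesign,
    gamma_true: float,
    n_reps: int,
    alpha: float = 0.05,
    master_seed: int = 0,
    include_lrt: bool = False,
) -> ScenarioResult:
    """Simulate ``n_reps`` cohorts at one effect size and fit both methods.

    Non-converged fits are dropped from the summaries and counted; more
    than 5% of them for either method raises, since at these sample
    sizes the likelihoods are smooth and failures signal a defect rather
    than noise.  ``include_lrt`` additionally refits each method with
    gamma fixed at 0 to report likelihood-ratio-test power alongside the
    Wald power.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    scen_design = SimulationDesign(
        model=design.model.with_(gamma=gamma_true),
        n_sample=design.n_sample,
        entry_ages=design.entry_ages,
        followup_years=design.followup_years,
        mode=design.mode,
        population_size=design.population_size,
    )
    est: dict = {m: [] for m in METHODS}
    rej: dict = {m: [] for m in METHODS}
    rej_lrt: dict = {m: [] for m in METHODS}
    bad = {m: 0 for m in METHODS}
    for r in range(n_reps):
        rng = _replicate_rng(master_seed, gamma_true, r)
        cohort = simulate_cohort(scen_design, rng)
        for m in METHODS:
            fit = fit_mle(cohort, method=m)
            if not fit.converged:
                bad[m] += 1
                continue
            est[m].append(fit.estimates["gamma"])
            _, p = test_gamma(fit, kind="wald")
            rej[m].append(p < alpha)
            if include_lrt:
                null_fit = fit_mle(cohort, method=m, fix_gamma=0.0)
                _, p_lrt = test_gamma(fit, null_fit, kind="lrt")
                rej_lrt[m].append(p_lrt < alpha)
    for m in METHODS:
        if bad[m] > 0.05 * n_reps:
            raise RuntimeError(
                f"{bad[m]}/{n_reps} replicates failed to converge for {m}; "
                "this indicates a modelling or optimization defect"
            )
    out = ScenarioResult(gamma_true=float(gamma_true), n_reps=n_reps, alpha=alpha)
    for m in METHODS:
        e = np.asarray(est[m])
        out.gamma_estimates[m] = e
        out.mean_gamma[m] = float(np.mean(e))
        out.sd_gamma[m] = float(np.std(e, ddof=1))
        out.power_hat[m] = float(np.mean(rej[m]))
        if include_lrt:
            out.power_lrt[m] = float(np.mean(rej_lrt[m]))
        out.n_nonconverged[m] = bad[m]
    return out


def run_grid(
    design: SimulationDesign,
    gamma_values=None,
    n_reps: int = 1000,
    alpha: float = 0.05,
    master_seed: int = 0,
    include_lrt: bool = False,
    progress=None,
) -> list[ScenarioResult]:
    """One scenario per effect size; seeds derive deterministically per scenario."""
    gamma_values = (
        default_gamma_grid() if gamma_values is None else np.asarray(gamma_values, float)
    )
    if gamma_values.size == 0:
        raise ValueError("gamma grid must be non-empty")
    results = []
    for gamma_true in gamma_values:
        res = run_scenario(
            design, float(gamma_true), n_reps, alpha, master_seed, include_lrt
        )
        results.append(res)
        if progress is not None:
            progress(res)
    return results


def z_test_power(gamma: float, sigma: float, alpha: float) -> float:
    """Power of the two-sided one-sample Z-test at effect gamma and SD sigma."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    zc = stats.norm.isf(alpha / 2.0)
    r = gamma / sigma
    return float(stats.norm.cdf(-zc + r) + stats.norm.cdf(-zc - r))


def fit_power_curve(results: list[ScenarioResult], method: str) -> PowerCurveFit:
    """Best-fit Z-test SD for a method's empirical power curve.

    Minimizes the unweighted sum of squared deviations between empirical
    power and the Z-test power over sigma > 0.  Scenarios at gamma = 0
    carry no information about sigma but are harmless to include.
    """
    gammas = np.array([r.gamma_true for r in results])
    power = np.array([r.power_hat[method] for r in results])
    alpha = results[0].alpha
    if np.count_nonzero(gammas) < 3:
        raise ValueError("need at least 3 scenarios with non-zero gamma")
    if np.all(power <= alpha + 1e-12) or np.all(power >= 1 - 1e-12):
        raise ValueError("degenerate power curve; sigma is not identified")

    def sse(sigma):
        fitted = np.array([z_test_power(g, sigma, alpha) for g in gammas])
        return float(np.sum((power - fitted) ** 2))

    res = optimize.minimize_scalar(sse, bounds=(1e-4, 10.0), method="bounded",
                                   options={"xatol": 1e-8})
    return PowerCurveFit(method=method, sigma_fit=float(res.x), alpha=alpha)


def alpha_for_power(gamma: float, sigma: float, target_power: float) -> float:
    """The test level alpha at which the Z-test reaches ``target_power``.

    z_test_power is strictly increasing in alpha, so the solution is
    found by monotone root finding on log10(alpha).
    """
    if not 0.0 < target_power < 1.0:
        raise ValueError("target_power must lie in (0, 1)")
    if gamma == 0:
        raise ValueError("gamma must be non-zero (power equals alpha at gamma = 0)")
    if sigma <= 0:
        raise ValueError("sigma must be positive")

    def f(log10_alpha):
        return z_test_power(gamma, sigma, 10.0 ** log10_alpha) - target_power

    lo, hi = -300.0, np.log10(1 - 1e-12)
    if f(lo) > 0:
        raise ValueError(
            "target power reached even at alpha = 1e-300; no solution in (0, 1)"
        )
    sol = optimize.brentq(f, lo, hi, xtol=1e-13)
    return float(10.0 ** sol)


def estimate_distribution_summary(
    result: ScenarioResult, bins: int = 20
) -> dict:
    """Histogram + normal fit + normality diagnostic of the gamma estimates.

    Returns, per method: bin counts and edges, the fitted normal mean
    and SD (identical to the scenario's mean/SD of gamma), and a
    Shapiro–Wilk p-value.  The normality p-value is a descriptive
    diagnostic of estimator behaviour, not a pass/fail surface.
    """
    out = {}
    for m, est in result.gamma_estimates.items():
        est = np.asarray(est)
        if est.size < 20:
            raise ValueError("need at least 20 replicate estimates")
        counts, edges = np.histogram(est, bins=bins)
        sw_stat, sw_p = stats.shapiro(est)
        out[m] = {
            "counts": counts,
            "edges": edges,
            "mean": float(np.mean(est)),
            "sd": float(np.std(est, ddof=1)),
            "shapiro_p": float(sw_p),
        }
    return out


def results_to_frame(results: list[ScenarioResult]) -> pd.DataFrame:
    """Long table: one row per (scenario, method)."""
    rows = []
    for r in results:
        for m in METHODS:
            rows.append(
                {
                    "gamma_true": r.gamma_true,
                    "method": m,
                    "n_reps": r.n_reps,
                    "mean_gamma": r.mean_gamma[m],
                    "sd_gamma": r.sd_gamma[m],
                    "power_hat": r.power_hat[m],
                    "power_lrt": r.power_lrt.get(m, np.nan),
                    "n_nonconverged": r.n_nonconverged[m],
                    "alpha": r.alpha,
                }
            )
    return pd.DataFrame(rows)
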