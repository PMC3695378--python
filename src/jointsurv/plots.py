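"""Figure analogues: power curves, level-of-test curves, estimate histograms."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from scipy import stats

from .power import (
    PowerCurveFit,
    ScenarioResult,
    alpha_for_power,
    z_test_power,
)

__all__ = ["plot_power_curves", "plot_alpha_for_power", "plot_estimate_histograms"]

_STYLE = {"FU": dict(color="tab:red", ls="--"), "FUA": dict(color="tab:blue", ls="-")}
_LABEL = {"FU": "FU (follow-up only)", "FUA": "FU + A (joint)"}


def plot_power_curves(
    results: list[ScenarioResult], fits: dict[str, PowerCurveFit], path
) -> None:
    """Empirical power per scenario with the fitted Z-test power curves."""
    fig, ax = plt.subplots(figsize=(6, 4.5))
    gam = np.array([r.gamma_true for r in results])
    order = np.argsort(gam)
    grid = np.linspace(gam.min(), gam.max(), 301)
    for m, fit in fits.items():
        emp = np.array([r.power_hat[m] for r in results])
        ax.plot(gam[order], emp[order], "o", color=_STYLE[m]["color"], ms=4,
                label=f"{_LABEL[m]}, empirical")
        ax.plot(grid, [z_test_power(g, fit.sigma_fit, fit.alpha) for g in grid],
                label=rf"{_LABEL[m]}, Z-test fit ($\sigma$={fit.sigma_fit:.3f})",
                **_STYLE[m])
    ax.set_xlabel(r"effect size $\gamma$ (log hazard ratio)")
    ax.set_ylabel(f"power at $\\alpha$ = {results[0].alpha:g}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_alpha_for_power(
    fits: dict[str, PowerCurveFit], path, target_power: float = 0.8,
    gamma_range=(0.05, 0.5),
) -> None:
    """-log10 of the test level achieving the target power vs effect size."""
    fig, ax = plt.subplots(figsize=(6, 4.5))
    grid = np.linspace(*gamma_range, 200)
    for m, fit in fits.items():
        neglog = [-np.log10(alpha_for_power(g, fit.sigma_fit, target_power))
                  for g in grid]
        ax.plot(grid, neglog, label=_LABEL[m], **_STYLE[m])
    ax.set_xlabel(r"effect size $\gamma$ (log hazard ratio)")
    ax.set_ylabel(rf"$-\log_{{10}}(\alpha)$ for power {target_power:g}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_estimate_histograms(result: ScenarioResult, path, bins: int = 20) -> None:
    """Histograms of the gamma estimates with their normal fits."""
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for m, est in result.gamma_estimates.items():
        est = np.asarray(est)
        ax.hist(est, bins=bins, density=True, alpha=0.35,
                color=_STYLE[m]["color"], label=_LABEL[m])
        mu, sd = est.mean(), est.std(ddof=1)
        grid = np.linspace(est.min(), est.max(), 200)
        ax.plot(grid, stats.norm.pdf(grid, mu, sd), **_STYLE[m])
    ax.axvline(result.gamma_true, color="k", lw=1, ls=":",
               label=rf"true $\gamma$ = {result.gamma_true:g}")
    ax.set_xlabel(r"$\hat\gamma$")
    ax.set_ylabel("density")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
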