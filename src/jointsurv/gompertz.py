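"""Genotype-stratified Gompertz proportional-hazards model.

The mortality rate of an individual of age ``x`` carrying ``g`` copies
(0 or 1) of an index allele is

    mu(x | g) = exp(log_a + b * x + gamma * g),

i.e. a Gompertz baseline ``mu0(x) = a * exp(b * x)`` acting
proportionally through the log hazard ratio ``gamma``.  ``p0`` is the
carrier proportion at birth, before mortality selection has acted.
Everything downstream — cohort simulation, both likelihoods, the power
study — is expressed in terms of the closed forms here.

All operations accept scalars or numpy arrays for ``x`` and ``g`` and
broadcast as numpy does.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "GompertzGenoModel",
    "hazard",
    "cumulative_hazard",
    "survival",
    "quantile",
    "sample_lifespan",
    "survivor_carrier_frequency",
]

# beyond this, exp(b*x) overflows float64; compute the cumulative hazard
# in log space instead (irrelevant at human parameter values, but the
# optimizer may wander)
_EXP_OVERFLOW = 700.0


@dataclass(frozen=True)
class GompertzGenoModel:
    """Parameters of the two-group Gompertz proportional-hazards model.

    Parameters
    ----------
    log_a : float
        Natural log of the baseline mortality rate at age 0 (per year).
    b : float
        Rate of exponential mortality increase with age (per year); > 0.
    gamma : float
        Log hazard ratio of carriers (g = 1) versus non-carriers (g = 0).
    p0 : float
        Carrier proportion at birth, in (0, 1).
    """

    log_a: float
    b: float
    gamma: float
    p0: float

    def __post_init__(self) -> None:
        for name in ("log_a", "b", "gamma", "p0"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.b <= 0:
            raise ValueError(f"b must be positive, got {self.b}")
        if not 0.0 < self.p0 < 1.0:
            raise ValueError(f"p0 must lie in (0, 1), got {self.p0}")

    def with_(self, **kwargs) -> "GompertzGenoModel":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def _check_age(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or not np.all(np.isfinite(x)):
        raise ValueError("ages must be finite and non-negative")
    return x


def _check_genotype(g) -> np.ndarray:
    g = np.asarray(g)
    if not np.all(np.isin(g, (0, 1))):
        raise ValueError("genotype must be 0 or 1")
    return g.astype(float)


def hazard(model: GompertzGenoModel, x, g):
    """Mortality rate mu(x | g) = exp(log_a + b*x + gamma*g), per year."""
    x = _check_age(x)
    g = _check_genotype(g)
    return np.exp(model.log_a + model.b * x + model.gamma * g)


def cumulative_hazard(model: GompertzGenoModel, x, g):
    """Integrated hazard H(x | g) = exp(log_a + gamma*g)/b * (e^{bx} - 1)."""
    x = _check_age(x)
    g = _check_genotype(g)
    bx = model.b * x
    log_rate = model.log_a + model.gamma * g
    with np.errstate(over="ignore"):
        out = np.exp(log_rate) / model.b * np.expm1(bx)
    big = bx > _EXP_OVERFLOW
    if np.any(big):
        out = np.where(big, np.exp(log_rate - np.log(model.b) + bx), out)
    return out


def survival(model: GompertzGenoModel, x, g):
    """S(x | g) = exp(-H(x | g)), the probability of surviving past age x."""
    return np.exp(-cumulative_hazard(model, x, g))


def quantile(model: GompertzGenoModel, p, g):
    """Age x at which S(x | g) = p, for p in (0, 1].

    Closed-form inverse of the Gompertz survival function:
    x = (1/b) * ln(1 - b * ln(p) / exp(log_a + gamma*g)).
    """
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("survival probability must lie in (0, 1]")
    g = _check_genotype(g)
    rate = np.exp(model.log_a + model.gamma * g)
    return np.log1p(-model.b * np.log(p) / rate) / model.b


def sample_lifespan(model: GompertzGenoModel, g, rng: np.random.Generator, size=None):
    """Draw lifespans with P(T > x) = survival(model, x, g) by exact inversion.

    ``g`` may be a scalar (with ``size`` giving the number of draws) or an
    array, in which case one lifespan is drawn per element.
    """
    g = np.asarray(g)
    if size is None and g.ndim > 0:
        size = g.shape
    u = rng.random(size)
    # U ~ Uniform(0,1) plays the role of the survival probability; u=0 has
    # probability zero but would give an infinite lifespan, so nudge it.
    u = np.where(u == 0.0, np.finfo(float).tiny, u)
    return quantile(model, u, g)


def survivor_carrier_frequency(model: GompertzGenoModel, u):
    """P(G = 1 | alive at age u): carrier frequency after mortality selection.

    pi1(u) = p0*S(u|1) / (p0*S(u|1) + (1-p0)*S(u|0)).  Decreasing in u for
    deleterious alleles (gamma > 0), increasing for protective ones
    (gamma < 0), constant at p0 when gamma = 0.  This age pattern is the
    information the joint likelihood adds on top of follow-up data.
    """
    u = _check_age(u)
    # log-space for numerical safety at extreme ages
    log_num = np.log(model.p0) - cumulative_hazard(model, u, np.ones_like(u))
    log_den0 = np.log1p(-model.p0) - cumulative_hazard(model, u, np.zeros_like(u))
    return np.exp(log_num - np.logaddexp(log_num, log_den0))
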