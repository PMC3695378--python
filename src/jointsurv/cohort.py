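"""Simulation and I/O of genotyped prospective cohorts.

Emulates the design of family-based longevity cohorts such as the Long
Life Family Study: genotype is assigned at birth with carrier proportion
``p0``, a lifespan is drawn from the genotype-specific Gompertz law, an
entry age (= age at biospecimen collection) is drawn from a discrete
uniform distribution, and only individuals alive at their entry age are
enrolled.  Follow-up ends ``followup_years`` after entry, when survivors
are administratively censored.

A cohort is a pandas DataFrame with columns

    g          genotype, 0 or 1
    entry_age  age at study entry / biospecimen collection (years)
    exit_age   age at death or censoring (years)
    event      1 if the death was observed, 0 if censored

satisfying exit_age > entry_age and, for censored rows,
exit_age = entry_age + followup_years exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gompertz import GompertzGenoModel, sample_lifespan, survival

__all__ = [
    "SimulationDesign",
    "COHORT_COLUMNS",
    "simulate_cohort",
    "acceptance_probability",
    "write_cohort",
    "read_cohort",
    "validate_cohort",
]

COHORT_COLUMNS = ("g", "entry_age", "exit_age", "event")

_DEFAULT_MODEL = GompertzGenoModel(log_a=-9.0, b=0.08, gamma=0.0, p0=0.25)


def _default_entry_ages() -> np.ndarray:
    # integers 40..100 inclusive, equiprobable
    return np.arange(40, 101, dtype=float)


@dataclass
class SimulationDesign:
    """Generating model plus the sampling scheme of the study.

    Defaults reproduce the reference design: Gompertz baseline
    ln a = -9, b = 0.08, carrier proportion 0.25, 4500 enrolled
    survivors with integer entry ages uniform on 40..100 and 6 years of
    follow-up.
    """

    model: GompertzGenoModel = _DEFAULT_MODEL
    n_sample: int = 4500
    entry_ages: np.ndarray = field(default_factory=_default_entry_ages)
    followup_years: float = 6.0
    mode: str = "rejection"
    population_size: int = 10_000_000

    def __post_init__(self) -> None:
        self.entry_ages = np.asarray(self.entry_ages, dtype=float)
        if self.n_sample < 1:
            raise ValueError("n_sample must be >= 1")
        if self.followup_years <= 0:
            raise ValueError("followup_years must be positive")
        if self.entry_ages.size == 0:
            raise ValueError("entry_ages must be non-empty")
        if np.any(self.entry_ages < 0):
            raise ValueError("entry ages must be non-negative")
        if self.mode not in ("rejection", "population"):
            raise ValueError(f"mode must be 'rejection' or 'population', got {self.mode!r}")
        if self.population_size < 1:
            raise ValueError("population_size must be >= 1")


def acceptance_probability(design: SimulationDesign) -> float:
    """Expected fraction of generated individuals alive at their entry age.

    Averages the genotype-mixed survival p0*S(u|1) + (1-p0)*S(u|0) over
    the (equiprobable) entry ages.  Diagnostic for the rejection sampler
    and the population-mode survivor count.
    """
    m = design.model
    u = design.entry_ages
    mix = m.p0 * survival(m, u, 1) + (1.0 - m.p0) * survival(m, u, 0)
    return float(np.mean(mix))


def _draw_triples(design: SimulationDesign, n: int, rng: np.random.Generator):
    m = design.model
    g = (rng.random(n) < m.p0).astype(np.int64)
    u = rng.choice(design.entry_ages, size=n, replace=True)
    t = sample_lifespan(m, g, rng)
    return g, u, t


def _finalize(design: SimulationDesign, g, u, t) -> pd.DataFrame:
    cens_age = u + design.followup_years
    event = (t <= cens_age).astype(np.int64)  # a tie (probability 0) is a death
    exit_age = np.minimum(t, cens_age)
    return pd.DataFrame(
        {"g": g, "entry_age": u, "exit_age": exit_age, "event": event}
    )


def simulate_cohort(design: SimulationDesign, rng: np.random.Generator) -> pd.DataFrame:
    """Generate one cohort of exactly ``design.n_sample`` enrolled survivors.

    Rejection mode draws (genotype, entry age, lifespan) triples and
    keeps those with lifespan strictly exceeding the entry age until the
    target size is reached.  Population mode materializes
    ``population_size`` triples once, filters survivors, and takes a
    uniform random subsample; for i.i.d. individuals the two schemes are
    distributionally identical.
    """
    p_acc = acceptance_probability(design)
    if design.mode == "rejection":
        if p_acc < 1e-9:
            raise RuntimeError(
                f"acceptance probability {p_acc:.3g} too small for rejection sampling"
            )
        parts = []
        remaining = design.n_sample
        while remaining > 0:
            batch = max(1024, int(remaining / p_acc * 1.2))
            g, u, t = _draw_triples(design, batch, rng)
            keep = t > u
            if keep.any():
                take = min(remaining, int(keep.sum()))
                idx = np.flatnonzero(keep)[:take]
                parts.append((g[idx], u[idx], t[idx]))
                remaining -= take
        g = np.concatenate([p[0] for p in parts])
        u = np.concatenate([p[1] for p in parts])
        t = np.concatenate([p[2] for p in parts])
        return _finalize(design, g, u, t)

    # population mode
    g, u, t = _draw_triples(design, design.population_size, rng)
    keep = np.flatnonzero(t > u)
    if keep.size < design.n_sample:
        raise RuntimeError(
            f"only {keep.size} of {design.population_size} generated individuals "
            f"survived to entry; cannot draw a sample of {design.n_sample}"
        )
    idx = rng.choice(keep, size=design.n_sample, replace=False)
    return _finalize(design, g[idx], u[idx], t[idx])


def validate_cohort(df: pd.DataFrame, followup_years: float | None = None) -> pd.DataFrame:
    """Check cohort invariants; raise ValueError naming offending rows.

    Row numbers in messages are 1-based positions in the table (header
    excluded), matching what a user sees in the file.
    """
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort is missing required columns: {', '.join(missing)}")
    df = df.loc[:, list(COHORT_COLUMNS)].reset_index(drop=True)

    def _bad_rows(mask) -> str:
        rows = (np.flatnonzero(np.asarray(mask)) + 1)[:10]
        return ", ".join(map(str, rows))

    for col in ("g", "event"):
        vals = df[col]
        bad = ~vals.isin((0, 1)) | vals.isna()
        if bad.any():
            raise ValueError(f"column {col!r} must be 0 or 1; bad rows: {_bad_rows(bad)}")
    for col in ("entry_age", "exit_age"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | ~np.isfinite(vals) | (vals < 0)
        if bad.any():
            raise ValueError(
                f"column {col!r} must be a non-negative number; bad rows: {_bad_rows(bad)}"
            )
        df[col] = vals
    bad = df["exit_age"] <= df["entry_age"]
    if bad.any():
        raise ValueError(
            f"exit_age must strictly exceed entry_age; bad rows: {_bad_rows(bad)}"
        )
    if followup_years is not None:
        horizon = df["entry_age"] + followup_years
        bad = ((df["event"] == 0) & ~np.isclose(df["exit_age"], horizon)) | (
            (df["event"] == 1) & (df["exit_age"] > horizon + 1e-9)
        )
        if bad.any():
            raise ValueError(
                "censoring at entry_age + followup_years violated; "
                f"bad rows: {_bad_rows(bad)}"
            )
    df["g"] = df["g"].astype(np.int64)
    df["event"] = df["event"].astype(np.int64)
    return df


def write_cohort(df: pd.DataFrame, path, sep: str = ",") -> None:
    validate_cohort(df).to_csv(path, sep=sep, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read a delimited cohort table (comma default, tab accepted)."""
    df = pd.read_csv(path, sep=None, engine="python")
    return validate_cohort(df)
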