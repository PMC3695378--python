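"""Run configuration: defaults, YAML round trip, and hashing.

An empty config file reproduces the reference experiment end to end;
every field can be overridden in the file or from the command line.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .cohort import SimulationDesign
from .gompertz import GompertzGenoModel
from .power import default_gamma_grid

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Everything needed to rerun the full power experiment."""

    design: SimulationDesign = field(default_factory=SimulationDesign)
    gamma_grid: np.ndarray = field(default_factory=default_gamma_grid)
    n_reps: int = 1000
    alpha: float = 0.05
    master_seed: int = 0
    output_dir: Path = Path("jointsurv-results")

    def __post_init__(self) -> None:
        self.gamma_grid = np.asarray(self.gamma_grid, dtype=float)
        self.output_dir = Path(self.output_dir)
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        m = self.design.model
        return {
            "model": {"log_a": m.log_a, "b": m.b, "gamma": m.gamma, "p0": m.p0},
            "design": {
                "n_sample": self.design.n_sample,
                "entry_age_min": float(self.design.entry_ages.min()),
                "entry_age_max": float(self.design.entry_ages.max()),
                "followup_years": self.design.followup_years,
                "mode": self.design.mode,
                "population_size": self.design.population_size,
            },
            "gamma_grid": [float(g) for g in self.gamma_grid],
            "n_reps": self.n_reps,
            "alpha": self.alpha,
            "master_seed": self.master_seed,
            "output_dir": str(self.output_dir),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d or {})
        md = d.get("model", {})
        model = GompertzGenoModel(
            log_a=float(md.get("log_a", -9.0)),
            b=float(md.get("b", 0.08)),
            gamma=float(md.get("gamma", 0.0)),
            p0=float(md.get("p0", 0.25)),
        )
        dd = d.get("design", {})
        lo = int(dd.get("entry_age_min", 40))
        hi = int(dd.get("entry_age_max", 100))
        design = SimulationDesign(
            model=model,
            n_sample=int(dd.get("n_sample", 4500)),
            entry_ages=np.arange(lo, hi + 1, dtype=float),
            followup_years=float(dd.get("followup_years", 6.0)),
            mode=str(dd.get("mode", "rejection")),
            population_size=int(dd.get("population_size", 10_000_000)),
        )
        return cls(
            design=design,
            gamma_grid=np.asarray(d.get("gamma_grid", default_gamma_grid()), float),
            n_reps=int(d.get("n_reps", 1000)),
            alpha=float(d.get("alpha", 0.05)),
            master_seed=int(d.get("master_seed", 0)),
            output_dir=Path(d.get("output_dir", "jointsurv-results")),
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        return cls.from_dict(yaml.safe_load(text) or {})

    def hash(self) -> str:
        """Short digest of the canonical config, stamped into every output.

        The output directory is excluded: it does not affect any result.
        """
        d = self.to_dict()
        d.pop("output_dir", None)
        canon = yaml.safe_dump(d, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]
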