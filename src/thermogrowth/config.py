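"""Configuration objects for the simulator and the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import numpy as np

# default trait targets: broad-sense heritabilities and trait-vs-winter-
# temperature correlations of the three growth parameters in the panel the
# generator emulates (initial size, growth rate at 16C, growth rate at 6C)
DEFAULT_H2 = {"M0": 0.41, "r16": 0.57, "r6": 0.32}
DEFAULT_CLIMATE_R = {"M0": -0.39, "r16": 0.33, "r6": 0.28}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults mirror the structure of the phenotyping panel being emulated:
    ~249 naturally inbred accessions drawn from admixture groups spread along
    a winter-temperature gradient, grown as 5 replicate plants per accession
    per experiment in 3 independent experiments at two treatment
    temperatures, photographed twice a day for 21 treatment days.
    """

    n_accessions: int = 249
    n_pops: int = 6
    fst: float = 0.15
    n_snps: int = 2000
    winter_temp_range: tuple[float, float] = (-11.0, 5.0)
    target_h2: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_H2))
    target_climate_r: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLIMATE_R)
    )
    seed_climate_r: float = -0.75
    seed_m0_r: float = 0.28
    beta_true: float = 0.9
    phi_true: float = 0.6
    sigma_meas: float = 4.0
    n_reps: int = 5
    n_experiments: int = 3
    n_temps: int = 2
    timepoints: tuple[float, ...] = field(
        # two photographs per day: 1 h after lights-on and 1 h before
        # lights-off of a 9 h photoperiod, ~0.42 d apart, for 21 days
        default_factory=lambda: tuple(
            float(d) + off for d in range(21) for off in (0.0, 0.42)
        )
    )
    artifact_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_accessions < 2 or self.n_snps < 1 or self.n_pops < 1:
            raise ValueError("n_accessions, n_snps, n_pops must be positive")
        if not (0.0 <= self.fst < 1.0):
            raise ValueError(f"fst must lie in [0, 1), got {self.fst}")
        if not (0.0 <= self.phi_true < 1.0):
            raise ValueError(f"phi_true must lie in [0, 1), got {self.phi_true}")
        if not (0.0 < self.beta_true <= 1.0):
            raise ValueError(f"beta_true must lie in (0, 1], got {self.beta_true}")
        if not (0.0 <= self.artifact_rate < 1.0):
            raise ValueError("artifact_rate must lie in [0, 1)")
        for name, h2 in self.target_h2.items():
            if not (0.0 < h2 < 1.0):
                raise ValueError(f"target_h2[{name}] must lie in (0, 1), got {h2}")
        for name, r in self.target_climate_r.items():
            if not (-1.0 < r < 1.0):
                raise ValueError(f"target_climate_r[{name}] out of (-1, 1): {r}")
        tp = np.asarray(self.timepoints, dtype=float)
        if tp.size < 2 or np.any(np.diff(tp) <= 0):
            raise ValueError("timepoints must be strictly increasing, length >= 2")

    @classmethod
    def desk_scale(cls, seed: int = 0, **overrides: Any) -> "SimConfig":
        """A reduced configuration for fast parameter-recovery benchmarks:
        50 accessions, 1 plant per accession per experiment, 3 experiments,
        2 temperatures, 20 timepoints over 21 days."""
        kw: dict[str, Any] = dict(
            n_accessions=50,
            n_pops=4,
            n_snps=500,
            n_reps=1,
            n_experiments=3,
            timepoints=tuple(np.linspace(0.0, 21.0, 20)),
            seed=seed,
        )
        kw.update(overrides)
        return cls(**kw)

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["target_h2"] = dict(self.target_h2)
        d["target_climate_r"] = dict(self.target_climate_r)
        d["timepoints"] = list(self.timepoints)
        return d


@dataclass
class PipelineConfig:
    """Paths and options steering the end-to-end pipeline."""

    outdir: Path
    phenotypes: Path | None = None
    genotypes: Path | None = None
    climate: Path | None = None
    seed_size: Path | None = None
    sim: SimConfig | None = None
    model_kind: str = "powerlaw"
    car1: bool = True
    exact_lmm: bool = False
    n_tested_pcs: int = 10
    maf_threshold: float = 0.10
    alpha: float = 0.05
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        for attr in ("phenotypes", "genotypes", "climate", "seed_size"):
            v = getattr(self, attr)
            if v is not None:
                setattr(self, attr, Path(v))
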