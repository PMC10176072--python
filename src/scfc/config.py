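"""Simulation configuration for synthetic coupled-network cohorts.

The configuration fixes every free parameter of the generator: network
topology (block structure, edge probabilities, streamline-count weights),
the latent per-subject coupling strength kappa, the functional run length,
outcome models, item-level missingness, and the two-timepoint design.
A :class:`SimulationConfig` plus a seed is a complete, reproducible
description of a cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .errors import ConfigError

#: Outcomes carried by every subject. Apathy and depression are generated on
#: a positive raw scale (their linear model lives on the natural-log scale)
#: so that the log transform applied before modelling is always defined.
OUTCOMES = ("cognition", "processing_speed", "apathy", "depression")
LOG_SCALE_OUTCOMES = frozenset({"apathy", "depression"})


@dataclass(frozen=True)
class OutcomeModel:
    """Linear-Gaussian outcome model: ``intercept + b_k*kappa + b_a*age + b_s*sex + noise``.

    For log-scale outcomes (apathy, depression) the linear predictor is the
    natural log of the raw score; the generator exponentiates it.
    """

    intercept: float
    beta_kappa: float
    beta_age: float
    beta_sex: float
    noise_sd: float

    def linear_predictor(self, kappa: float, age: float, sex: float) -> float:
        return (
            self.intercept
            + self.beta_kappa * kappa
            + self.beta_age * age
            + self.beta_sex * sex
        )


def _default_outcome_betas() -> dict[str, OutcomeModel]:
    # Intercepts chosen so cohort means at (kappa=0.3, age=67.8) sit near the
    # marginals the cohort emulates: cognition ~0.2 (SD 0.7), processing
    # speed ~-1.1 (SD 0.7), log-apathy ~3.2 (SD 0.2), log-depression ~2.7
    # (SD 0.3). Depression has no coupling effect by default: it is the
    # specificity control.
    return {
        "cognition": OutcomeModel(1.08, 1.5, -0.02, 0.05, 0.65),
        "processing_speed": OutcomeModel(-0.40, 2.2, -0.02, 0.0, 0.60),
        "apathy": OutcomeModel(3.11, -0.83, 0.005, 0.0, 0.18),
        "depression": OutcomeModel(2.56, 0.0, 0.002, 0.02, 0.28),
    }


def _default_missing_rates() -> dict[str, float]:
    # Item-level missingness emulating 2/262 cognition, 5/262 processing
    # speed, 10/262 apathy, 4/262 depression.
    return {
        "cognition": 2 / 262,
        "processing_speed": 5 / 262,
        "apathy": 10 / 262,
        "depression": 4 / 262,
    }


def default_community_sizes(n_nodes: int, n_communities: int = 5) -> list[int]:
    """Near-equal block sizes summing to ``n_nodes`` (larger blocks first)."""
    base = n_nodes // n_communities
    extra = n_nodes % n_communities
    return [base + (1 if i < extra else 0) for i in range(n_communities)]


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort generator.

    Defaults describe the reference cohort: 262 subjects, 162-node networks
    in five near-equal communities, a latent coupling kappa ~ N(0.30, 0.07)
    clamped to [0, 1], and a two-wave design with ~19% attrition. The
    structural-correlation scale and run length are calibrated so measured
    whole-brain coupling is centred near 0.22 with SD near 0.04.
    """

    n_subjects: int = 262
    n_nodes: int = 162
    community_sizes: list[int] | None = None
    p_intra: float = 0.95
    p_inter: float = 0.10
    #: mean natural-log streamline count on intra-community edges; the
    #: inter-community mean is half of this.
    weight_scale: float = 4.0
    #: SD of the natural-log streamline count (heavy-tailed counts).
    weight_sigma: float = 1.0
    kappa_mean: float = 0.30
    kappa_sd: float = 0.07
    #: peak off-diagonal entry of the structure-derived correlation target.
    structural_corr_max: float = 0.6
    n_timepoints_ts: int = 200
    outcome_betas: dict[str, OutcomeModel] = field(default_factory=_default_outcome_betas)
    missing_rates: dict[str, float] = field(default_factory=_default_missing_rates)
    #: mean decline in kappa between waves (0 = stable coupling).
    longitudinal_delta: float = 0.0
    longitudinal_noise: float = 0.02
    attrition_fraction: float = 50 / 262
    follow_up_years: float = 4.0
    age_mean: float = 67.8
    age_sd: float = 8.0
    female_fraction: float = 0.435
    seed: int = 0

    def __post_init__(self) -> None:
        if self.community_sizes is None:
            self.community_sizes = default_community_sizes(self.n_nodes)
        self.validate()

    # -- validation -----------------------------------------------------

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if self.n_nodes < 2:
            raise ConfigError("n_nodes must be >= 2")
        if sum(self.community_sizes) != self.n_nodes:
            raise ConfigError(
                f"community_sizes sum to {sum(self.community_sizes)}, "
                f"expected n_nodes={self.n_nodes}"
            )
        if any(s < 1 for s in self.community_sizes):
            raise ConfigError("community_sizes must all be >= 1")
        for name, p in (("p_intra", self.p_intra), ("p_inter", self.p_inter),
                        ("attrition_fraction", self.attrition_fraction),
                        ("female_fraction", self.female_fraction)):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        for name, rate in self.missing_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"missing rate for {name} must be in [0, 1]")
        if self.weight_scale <= 0:
            raise ConfigError("weight_scale must be positive")
        if not 0.0 < self.structural_corr_max < 1.0:
            raise ConfigError("structural_corr_max must be in (0, 1)")
        if self.n_timepoints_ts < 2:
            raise ConfigError("n_timepoints_ts must be >= 2")
        missing = set(OUTCOMES) - set(self.outcome_betas)
        if missing:
            raise ConfigError(f"outcome_betas missing entries for {sorted(missing)}")

    # -- node/community bookkeeping -------------------------------------

    @property
    def node_labels(self) -> list[str]:
        width = len(str(self.n_nodes))
        return [f"roi_{i + 1:0{width}d}" for i in range(self.n_nodes)]

    def block_labels(self) -> "list[int]":
        """Planted community label (1-based) per node."""
        labels: list[int] = []
        for c, size in enumerate(self.community_sizes, start=1):
            labels.extend([c] * size)
        return labels

    # -- serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["outcome_betas"] = {k: asdict(v) for k, v in self.outcome_betas.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "outcome_betas" in d:
            d["outcome_betas"] = {
                k: v if isinstance(v, OutcomeModel) else OutcomeModel(**v)
                for k, v in d["outcome_betas"].items()
            }
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
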