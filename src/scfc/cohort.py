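"""Synthetic cohorts of paired structural/functional brain networks.

The generator emulates the statistical structure the coupling analysis
assumes, not the biophysics that produces it:

* Structural networks are stochastic block models over the configured
  communities: edges appear with probability ``p_intra`` within and
  ``p_inter`` between blocks, and present edges carry log-normal
  streamline counts (heavier within blocks).
* Each subject has a latent coupling strength ``kappa`` in [0, 1]. The
  functional run is drawn from a zero-mean Gaussian whose correlation
  matrix is a convex blend — weight kappa on a correlation target derived
  from the subject's own (degree-normalised, positive-definite-projected)
  structural weights, weight 1 - kappa on an unstructured identity
  baseline. Only second-order statistics feed the downstream analysis, so
  nothing richer than the covariance is modelled.
* Outcomes are linear-Gaussian in (kappa, age, sex); apathy and depression
  are generated on a positive raw scale (exp of a Gaussian log-scale
  model), so higher raw scores mean more severe symptoms and the natural
  log used in modelling is always defined.
* Missingness is MCAR per outcome at configured rates; a second timepoint
  drifts kappa by ``longitudinal_delta`` (plus noise, clamped to [0, 1])
  and drops an attrition fraction of subjects.

Cohort generation is a pure function of (config, seed): the same pair
reproduces the cohort byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .config import OUTCOMES, LOG_SCALE_OUTCOMES, SimulationConfig
from .errors import ConfigError, InputError

__all__ = [
    "Subject",
    "Cohort",
    "generate_structural",
    "structural_correlation_target",
    "generate_timeseries",
    "generate_outcomes",
    "apply_missingness",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

#: eigenvalue floor used when projecting the structural correlation target
#: to the nearest positive-definite matrix.
EIG_FLOOR = 1e-8


@dataclass
class Subject:
    """One subject-timepoint record of the synthetic cohort."""

    subject_id: str
    age: float
    sex: int  # 0 = male, 1 = female
    timepoint: int  # 1 or 2
    kappa_true: float
    streamline_matrix: np.ndarray
    timeseries: np.ndarray  # time-by-node
    outcomes: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = self.streamline_matrix
        if m is not None:
            if not np.array_equal(m, m.T):
                raise InputError("streamline matrix must be symmetric")
            if np.any(np.diag(m) != 0):
                raise InputError("streamline matrix must have zero diagonal")
            if np.any(m < 0):
                raise InputError("streamline counts must be nonnegative")
        if self.timeseries is not None and self.timeseries.shape[0] < 2:
            raise InputError("timeseries needs at least 2 samples")


@dataclass
class Cohort:
    """A list of subject-timepoint records plus the config that produced it."""

    subjects: list[Subject]
    config: SimulationConfig

    def __iter__(self):
        return iter(self.subjects)

    def __len__(self) -> int:
        return len(self.subjects)

    def at_timepoint(self, timepoint: int) -> list[Subject]:
        return [s for s in self.subjects if s.timepoint == timepoint]

    def metadata(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            row = {
                "subject_id": s.subject_id,
                "timepoint": s.timepoint,
                "age": s.age,
                "sex": s.sex,
                "kappa_true": s.kappa_true,
            }
            row.update({k: s.outcomes.get(k, np.nan) for k in OUTCOMES})
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Structural networks

def generate_structural(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw one symmetric nonnegative-integer streamline-count matrix.

    Block-structured: within-community edges appear with ``p_intra`` and
    carry log-normal counts with log-mean ``weight_scale``; between-community
    edges appear with ``p_inter`` and log-mean ``weight_scale / 2``.
    """
    n = config.n_nodes
    if sum(config.community_sizes) != n:
        raise ConfigError("community_sizes inconsistent with n_nodes")
    block = np.asarray(config.block_labels())
    iu, ju = np.triu_indices(n, k=1)
    intra = block[iu] == block[ju]
    p_edge = np.where(intra, config.p_intra, config.p_inter)
    present = rng.random(len(iu)) < p_edge
    log_mean = np.where(intra, config.weight_scale, config.weight_scale / 2.0)
    log_counts = rng.normal(log_mean, config.weight_sigma)
    counts = np.maximum(np.rint(np.exp(log_counts)), 1.0)
    counts = np.where(present, counts, 0.0)
    out = np.zeros((n, n))
    out[iu, ju] = counts
    out = out + out.T
    return out.astype(np.int64)


def _nearest_correlation(c: np.ndarray) -> np.ndarray:
    """Clip eigenvalues at a small floor, then rescale to unit diagonal."""
    w, v = np.linalg.eigh((c + c.T) / 2.0)
    w = np.maximum(w, EIG_FLOOR)
    c = (v * w) @ v.T
    d = np.sqrt(np.diag(c))
    c = c / np.outer(d, d)
    np.fill_diagonal(c, 1.0)
    return (c + c.T) / 2.0


def structural_correlation_target(streamline_matrix: np.ndarray,
                                  config: SimulationConfig) -> np.ndarray:
    """Correlation matrix encoding a subject's structural topology.

    Log(count+1) weights are degree-normalised (D^-1/2 W D^-1/2), scaled so
    the largest off-diagonal entry equals ``structural_corr_max``, given a
    unit diagonal, and projected to the nearest positive-definite
    correlation matrix.
    """
    w = np.log1p(np.asarray(streamline_matrix, dtype=float))
    deg = w.sum(axis=1)
    deg[deg == 0] = 1.0
    norm = w / np.sqrt(np.outer(deg, deg))
    peak = norm.max()
    if peak > 0:
        norm = norm * (config.structural_corr_max / peak)
    np.fill_diagonal(norm, 1.0)
    return _nearest_correlation(norm)


def generate_timeseries(streamline_matrix: np.ndarray, kappa: float,
                        config: SimulationConfig,
                        rng: np.random.Generator) -> np.ndarray:
    """Sample a functional run whose correlations blend structure and noise.

    The target correlation matrix is ``kappa * C_struct + (1 - kappa) * I``:
    at kappa=1 node-pair correlations track the structural topology, at
    kappa=0 they are pure sampling noise around independence.
    """
    if not 0.0 <= kappa <= 1.0:
        raise InputError(f"kappa must be in [0, 1], got {kappa}")
    c_struct = structural_correlation_target(streamline_matrix, config)
    n = c_struct.shape[0]
    target = kappa * c_struct + (1.0 - kappa) * np.eye(n)
    try:
        chol = np.linalg.cholesky(target)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - PD by construction
        raise RuntimeError(
            "blended covariance not positive definite after projection "
            f"(kappa={kappa}, min eig={np.linalg.eigvalsh(target).min():.3e})"
        ) from exc
    draws = rng.standard_normal((config.n_timepoints_ts, n))
    return draws @ chol.T


# ---------------------------------------------------------------------------
# Outcomes and missingness

def generate_outcomes(kappa: float, age: float, sex: int,
                      config: SimulationConfig,
                      rng: np.random.Generator) -> dict[str, float]:
    """Draw the four outcomes; apathy/depression on their positive raw scale."""
    missing = set(OUTCOMES) - set(config.outcome_betas)
    if missing:
        raise ConfigError(f"outcome_betas missing entries for {sorted(missing)}")
    out: dict[str, float] = {}
    for name in OUTCOMES:
        model = config.outcome_betas[name]
        value = model.linear_predictor(kappa, age, sex)
        if model.noise_sd > 0:
            value += rng.normal(0.0, model.noise_sd)
        if name in LOG_SCALE_OUTCOMES:
            value = float(np.exp(value))
        out[name] = float(value)
    return out


def apply_missingness(cohort: Cohort, missing_rates: Mapping[str, float],
                      rng: np.random.Generator) -> Cohort:
    """Mask outcomes completely at random at the configured per-outcome rates."""
    for name, rate in missing_rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ConfigError(f"missing rate for {name} must be in [0, 1]")
    for subject in cohort.subjects:
        for name, rate in missing_rates.items():
            if name in subject.outcomes and rng.random() < rate:
                subject.outcomes[name] = float("nan")
    return cohort


# ---------------------------------------------------------------------------
# Whole-cohort generation

def _clamp01(x: float) -> float:
    return float(min(1.0, max(0.0, x)))


def generate_cohort(config: SimulationConfig, seed: int | None = None) -> Cohort:
    """Generate the full two-timepoint cohort.

    Per subject: a streamline matrix (shared across waves — the anatomical
    network is treated as stable over the follow-up), a latent kappa per
    wave with configured drift, a functional run per wave, outcomes, and
    MCAR missingness. Deterministic given (config, seed); ``seed`` defaults
    to ``config.seed``.
    """
    seed = config.seed if seed is None else seed
    root = np.random.SeedSequence(seed)
    subject_seeds = root.spawn(config.n_subjects)
    attrition_rng = np.random.default_rng(root.spawn(1)[0])

    n_keep = int(round((1.0 - config.attrition_fraction) * config.n_subjects))
    retained = set(attrition_rng.choice(config.n_subjects, size=n_keep, replace=False))

    subjects: list[Subject] = []
    width = len(str(config.n_subjects))
    for i in range(config.n_subjects):
        rng = np.random.default_rng(subject_seeds[i])
        sid = f"sub-{i + 1:0{width}d}"
        age = float(np.clip(rng.normal(config.age_mean, config.age_sd), 50.0, 85.0))
        sex = int(rng.random() < config.female_fraction)
        kappa1 = _clamp01(rng.normal(config.kappa_mean, config.kappa_sd))
        sc = generate_structural(config, rng)
        ts1 = generate_timeseries(sc, kappa1, config, rng)
        out1 = generate_outcomes(kappa1, age, sex, config, rng)
        subjects.append(Subject(sid, age, sex, 1, kappa1, sc, ts1, out1))
        if i in retained:
            kappa2 = _clamp01(kappa1 - config.longitudinal_delta
                              + (rng.normal(0.0, config.longitudinal_noise)
                                 if config.longitudinal_noise > 0 else 0.0))
            age2 = age + config.follow_up_years
            ts2 = generate_timeseries(sc, kappa2, config, rng)
            out2 = generate_outcomes(kappa2, age2, sex, config, rng)
            subjects.append(Subject(sid, age2, sex, 2, kappa2, sc, ts2, out2))

    cohort = Cohort(subjects, config)
    rates_rng = np.random.default_rng(root.spawn(2)[1])
    return apply_missingness(cohort, config.missing_rates, rates_rng)


# ---------------------------------------------------------------------------
# On-disk layout: one adjacency TSV and one time-series TSV per
# subject-timepoint, cohort.csv metadata, config.yaml echo.

def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels = cohort.config.node_labels
    for s in cohort.subjects:
        stem = f"{s.subject_id}_t{s.timepoint}"
        pd.DataFrame(s.streamline_matrix, index=labels, columns=labels).to_csv(
            out / f"{stem}_sc.tsv", sep="\t")
        pd.DataFrame(s.timeseries, columns=labels).to_csv(
            out / f"{stem}_ts.tsv", sep="\t", index=False)
    cohort.metadata().to_csv(out / "cohort.csv", index=False)
    cohort.config.to_yaml(out / "config.yaml")
    return out


def read_cohort(in_dir: str | Path) -> Cohort:
    """Load a cohort previously written by :func:`write_cohort`."""
    in_dir = Path(in_dir)
    config = SimulationConfig.from_yaml(in_dir / "config.yaml")
    meta = pd.read_csv(in_dir / "cohort.csv")
    subjects: list[Subject] = []
    for _, row in meta.iterrows():
        stem = f"{row.subject_id}_t{int(row.timepoint)}"
        sc = pd.read_csv(in_dir / f"{stem}_sc.tsv", sep="\t", index_col=0)
        ts = pd.read_csv(in_dir / f"{stem}_ts.tsv", sep="\t")
        outcomes = {k: float(row[k]) for k in OUTCOMES}
        subjects.append(Subject(
            str(row.subject_id), float(row.age), int(row.sex),
            int(row.timepoint), float(row.kappa_true),
            sc.to_numpy(dtype=np.int64), ts.to_numpy(dtype=float), outcomes))
    return Cohort(subjects, config)
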