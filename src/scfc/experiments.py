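"""Simulation studies over the synthetic cohort.

These are the package's validation experiments: they exercise the whole
pipeline on generated cohorts and measure how well the analysis recovers
what the generator planted — the coupling dial (measured coupling as a
function of the latent kappa), the calibration of the default cohort,
consensus-partition recovery of the planted communities, statistical power
for planted outcome effects, and the type-I error of the null outcome.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .cohort import generate_cohort, generate_outcomes, generate_structural, \
    generate_timeseries
from .community import agreement, consensus, louvain
from .config import SimulationConfig
from .coupling import cohort_coupling_table, coupling_coefficient, coupling_profile
from .netbuild import build_fcn, build_scn, group_average_fcn, prevalence_mask, \
    proportional_threshold
from .stats import build_analysis_table, fdr_adjust, fit_linear, pmm_impute, \
    pool_rubin

__all__ = [
    "coupling_dial",
    "cohort_coupling_summary",
    "planted_partition_recovery",
    "effect_recovery",
    "null_type1_error",
]


def coupling_dial(config: SimulationConfig | None = None,
                  kappas: Sequence[float] = tuple(np.round(np.arange(0.1, 1.0, 0.1), 1)),
                  n_per_level: int = 50, seed: int = 0) -> pd.DataFrame:
    """Mean measured whole-brain coupling at each latent kappa level.

    Returns a frame with columns kappa, mean_r, sd_r plus the Spearman rank
    correlation (attribute ``spearman``) between kappa and mean coupling.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    structurals = [generate_structural(config, rng) for _ in range(n_per_level)]
    mask = prevalence_mask(structurals)
    scns = [build_scn(sc, mask).values for sc in structurals]
    rows = []
    for kappa in kappas:
        rs = []
        for sc, scn in zip(structurals, scns):
            ts = generate_timeseries(sc, float(kappa), config, rng)
            rs.append(coupling_coefficient(scn, build_fcn(ts).values, mask))
        rows.append({"kappa": float(kappa), "mean_r": float(np.mean(rs)),
                     "sd_r": float(np.std(rs))})
    out = pd.DataFrame(rows)
    out.attrs["spearman"] = float(spearmanr(out["kappa"], out["mean_r"]).statistic)
    return out


def cohort_coupling_summary(config: SimulationConfig | None = None,
                            seed: int = 0) -> dict[str, float]:
    """Whole-brain coupling mean/SD of a default cohort at wave 1, and the
    correlation of measured coupling with the latent kappa."""
    config = config or SimulationConfig()
    cohort = generate_cohort(config, seed=seed)
    wave1 = cohort.at_timepoint(1)
    mask = prevalence_mask([s.streamline_matrix for s in wave1])
    rs, kappas = [], []
    for s in wave1:
        scn = build_scn(s.streamline_matrix, mask).values
        fcn = build_fcn(s.timeseries).values
        rs.append(coupling_coefficient(scn, fcn, mask))
        kappas.append(s.kappa_true)
    rs = np.asarray(rs)
    return {
        "mean_r": float(np.mean(rs)),
        "sd_r": float(np.std(rs)),
        "corr_r_kappa": float(np.corrcoef(rs, kappas)[0, 1]),
        "n": len(rs),
    }


def planted_partition_recovery(n_runs: int = 10, n_subjects: int = 15,
                               reps: int = 100, density: float = 0.10,
                               config: SimulationConfig | None = None,
                               seed: int = 0) -> pd.DataFrame:
    """Consensus-partition recovery of the planted community labels.

    Each run simulates a fresh group-average FCN, thresholds it, and runs
    repeated Louvain plus consensus. Returns one row per run with the
    adjusted Rand index against the planted labels, the number of consensus
    communities, and the partition's modularity on the thresholded group
    FCN.
    """
    from sklearn.metrics import adjusted_rand_score

    base = config or SimulationConfig()
    rows = []
    for run in range(n_runs):
        cfg = replace_seed(base, seed + 1000 + run, n_subjects=n_subjects,
                           attrition_fraction=1.0)
        cohort = generate_cohort(cfg, seed=cfg.seed)
        fcns = [build_fcn(s.timeseries) for s in cohort.at_timepoint(1)]
        group = proportional_threshold(group_average_fcn(fcns), density)
        ss = np.random.SeedSequence(seed + run)
        run_seeds = [int(s.generate_state(1)[0]) % (2**31) for s in ss.spawn(reps)]
        runs = [louvain(group, seed=s) for s in run_seeds]
        part = consensus(agreement(runs), reps=reps, seed=seed + run,
                         modularity_matrix=group)
        rows.append({
            "ari": float(adjusted_rand_score(cfg.block_labels(), part.assignment)),
            "n_communities": part.n_communities,
            "q": part.q,
        })
    return pd.DataFrame(rows)


def replace_seed(config: SimulationConfig, seed: int,
                 **overrides) -> SimulationConfig:
    """Copy a config with a new seed (and optional field overrides)."""
    d = config.to_dict()
    d["seed"] = seed
    d.update(overrides)
    return SimulationConfig.from_dict(d)


def _single_wave_config(base: SimulationConfig, n_subjects: int,
                        seed: int) -> SimulationConfig:
    return replace_seed(base, seed, n_subjects=n_subjects,
                        attrition_fraction=1.0)


OUTCOME_COLUMNS = {"cognition": "cognition",
                   "processing_speed": "processing_speed",
                   "apathy": "log_apathy",
                   "depression": "log_depression"}


def effect_recovery(n_replicates: int = 50, n_subjects: int = 250,
                    m: int = 5, config: SimulationConfig | None = None,
                    seed: int = 0, alpha: float = 0.05) -> pd.DataFrame:
    """Power/type-I of the pipeline's whole-brain outcome tests.

    Each replicate simulates a fresh single-wave cohort, measures coupling,
    imputes the outcomes, regresses each outcome on whole-brain coupling
    (age, sex, global efficiency adjusted), pools by Rubin's rules, and
    applies BH-FDR over the four outcomes. Returns per-outcome FDR and raw
    rejection rates and the mean pooled beta.
    """
    base = config or SimulationConfig()
    outcomes = list(OUTCOME_COLUMNS.values())
    hits_fdr = {o: 0 for o in outcomes}
    hits_raw = {o: 0 for o in outcomes}
    betas = {o: [] for o in outcomes}
    for rep in range(n_replicates):
        cfg = _single_wave_config(base, n_subjects, seed + 5000 + rep)
        cohort = generate_cohort(cfg, seed=cfg.seed)
        mask = prevalence_mask([s.streamline_matrix for s in cohort])
        profiles = [coupling_profile(s.subject_id, s.timepoint,
                                     build_scn(s.streamline_matrix, mask),
                                     build_fcn(s.timeseries), mask)
                    for s in cohort]
        table = build_analysis_table(cohort.metadata(),
                                     cohort_coupling_table(profiles),
                                     follow_up_years=cfg.follow_up_years)
        impute_cols = ["whole_brain_r", "age", "sex", "global_efficiency",
                       *outcomes]
        completed = pmm_impute(table, m=m, rng=seed + rep, columns=impute_cols)
        ps, pooled_betas = [], {}
        for outcome in outcomes:
            per_imp = []
            df_com = np.inf
            for t in completed:
                beta, var, df_com = fit_linear(t, outcome, "whole_brain_r")[
                    "whole_brain_r"]
                per_imp.append((beta, var))
            pooled = pool_rubin(per_imp, m=m, df_com=df_com)
            ps.append(pooled.p_two_sided)
            pooled_betas[outcome] = pooled.beta
        adjusted = fdr_adjust(ps)
        for outcome, p_raw, p_adj in zip(outcomes, ps, adjusted):
            hits_raw[outcome] += p_raw < alpha
            hits_fdr[outcome] += p_adj < alpha
            betas[outcome].append(pooled_betas[outcome])
    return pd.DataFrame({
        "outcome": outcomes,
        "power_fdr": [hits_fdr[o] / n_replicates for o in outcomes],
        "power_raw": [hits_raw[o] / n_replicates for o in outcomes],
        "mean_beta": [float(np.mean(betas[o])) for o in outcomes],
    })


def null_type1_error(n_replicates: int = 200, n_subjects: int = 250,
                     m: int = 5, config: SimulationConfig | None = None,
                     seed: int = 0, alpha: float = 0.05) -> float:
    """Type-I error of the depression test (null coupling effect by default).

    The cohort's measured design (coupling, age, sex, efficiency) is
    simulated once and held fixed; each replicate redraws the null
    depression outcome and its missingness, imputes, fits, and tests.
    Conditioning on the design keeps the replicate loop at outcome-model
    cost while still exercising imputation and inference end to end.
    """
    base = config or SimulationConfig()
    if base.outcome_betas["depression"].beta_kappa != 0.0:
        raise ValueError("null_type1_error expects a null depression effect")
    cfg = _single_wave_config(base, n_subjects, seed + 9000)
    cohort = generate_cohort(cfg, seed=cfg.seed)
    mask = prevalence_mask([s.streamline_matrix for s in cohort])
    profiles = [coupling_profile(s.subject_id, s.timepoint,
                                 build_scn(s.streamline_matrix, mask),
                                 build_fcn(s.timeseries), mask)
                for s in cohort]
    table = build_analysis_table(cohort.metadata(),
                                 cohort_coupling_table(profiles),
                                 follow_up_years=cfg.follow_up_years)
    rng = np.random.default_rng(seed + 9001)
    model = cfg.outcome_betas["depression"]
    rate = cfg.missing_rates.get("depression", 0.0)
    hits = 0
    impute_cols = ["whole_brain_r", "age", "sex", "global_efficiency",
                   "log_depression"]
    for _ in range(n_replicates):
        work = table.copy()
        draws = [generate_outcomes(k, a, s, cfg, rng)["depression"]
                 for k, a, s in zip(work["kappa_true"], work["age"], work["sex"])]
        work["log_depression"] = np.log(draws)
        work.loc[rng.random(len(work)) < rate, "log_depression"] = np.nan
        completed = pmm_impute(work, m=m, rng=rng, columns=impute_cols)
        per_imp = []
        df_com = np.inf
        for t in completed:
            beta, var, df_com = fit_linear(t, "log_depression",
                                           "whole_brain_r")["whole_brain_r"]
            per_imp.append((beta, var))
        pooled = pool_rubin(per_imp, m=m, df_com=df_com)
        hits += pooled.p_two_sided < alpha
    return hits / n_replicates
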