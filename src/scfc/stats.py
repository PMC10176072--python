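"""Outcome modelling with multiple imputation.

Implements the analysis layer: composite z-scoring of raw test batteries,
chained-equation multiple imputation with predictive mean matching (PMM),
covariate-adjusted linear models (cross-sectional) and random-intercept
linear mixed models (longitudinal), Rubin's-rules pooling across
imputations with Barnard-Rubin degrees of freedom, and Benjamini-Hochberg
FDR correction per results table.

PMM never invents values: each missing entry is filled with an observed
donor value whose model-predicted mean is closest to the missing case's
prediction, so imputations respect the observed support (binary variables
stay binary, positive variables stay positive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ConvergenceError, InputError

__all__ = [
    "PooledEstimate",
    "composite_z",
    "pmm_impute",
    "fit_linear",
    "fit_lmm",
    "pool_rubin",
    "fdr_adjust",
    "build_analysis_table",
    "run_model_table",
]

DEFAULT_COVARIATES = ("age", "sex", "global_efficiency")


# ---------------------------------------------------------------------------
# Composite scoring

def composite_z(raw_scores: Mapping[str, float],
                reference: Mapping[str, tuple[float, float]]) -> float:
    """Mean of per-test z-scores against reference (mean, sd) pairs."""
    if not raw_scores:
        raise InputError("composite_z needs at least one test score")
    zs = []
    for test, raw in raw_scores.items():
        if test not in reference:
            raise InputError(f"no reference (mean, sd) for test {test!r}")
        mean, sd = reference[test]
        if sd <= 0:
            raise InputError(f"reference sd for test {test!r} must be positive")
        zs.append((raw - mean) / sd)
    return float(np.mean(zs))


# ---------------------------------------------------------------------------
# Predictive mean matching (chained equations)

def _pmm_one_variable(y: np.ndarray, x: np.ndarray, obs: np.ndarray,
                      mis: np.ndarray, rng: np.random.Generator,
                      donors: int) -> np.ndarray:
    """Impute one variable by type-1 PMM (posterior-draw predictions for
    the missing cases, least-squares predictions for the donors)."""
    x_obs, x_mis = x[obs], x[mis]
    y_obs = y[obs]
    n_obs, p = x_obs.shape
    xtx = x_obs.T @ x_obs + 1e-8 * np.eye(p)
    xty = x_obs.T @ y_obs
    beta_hat = np.linalg.solve(xtx, xty)
    resid = y_obs - x_obs @ beta_hat
    df = max(n_obs - p, 1)
    sigma2 = float(resid @ resid) / rng.chisquare(df)
    # posterior draw of the coefficients
    cov = sigma2 * np.linalg.inv(xtx)
    beta_star = rng.multivariate_normal(beta_hat, (cov + cov.T) / 2.0,
                                        method="cholesky")
    pred_obs = x_obs @ beta_hat
    pred_mis = x_mis @ beta_star
    k = min(donors, n_obs)
    filled = np.empty(len(pred_mis))
    for i, pm in enumerate(pred_mis):
        gaps = np.abs(pred_obs - pm)
        pool = np.argpartition(gaps, k - 1)[:k]
        filled[i] = y_obs[pool[rng.integers(k)]]
    return filled


def pmm_impute(table: pd.DataFrame, m: int = 20,
               rng: np.random.Generator | int | None = None,
               sweeps: int = 10, donors: int = 5,
               columns: Sequence[str] | None = None) -> list[pd.DataFrame]:
    """Multiple imputation by chained equations with predictive mean matching.

    Parameters
    ----------
    table
        Numeric analysis table; NaN marks missing entries.
    m
        Number of completed tables to return.
    sweeps
        Chained-equation cycles per imputation.
    donors
        Donor pool size (k nearest predicted means).
    columns
        Columns participating in the imputation model; defaults to all
        numeric columns. Non-participating columns are passed through.

    Returns the list of m completed copies of ``table``. With no missing
    data all copies equal the input.
    """
    if m < 1:
        raise InputError("m must be >= 1")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    cols = list(columns) if columns is not None else [
        c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    data = table[cols].to_numpy(dtype=float)
    miss = np.isnan(data)
    for j, c in enumerate(cols):
        if miss[:, j].all():
            raise InputError(f"column {c!r} is 100% missing; cannot impute")
    incomplete = [j for j in range(len(cols)) if miss[:, j].any()]
    # visit least-missing first, the conventional chained-equations order
    incomplete.sort(key=lambda j: miss[:, j].sum())

    completed: list[pd.DataFrame] = []
    for _ in range(m):
        filled = data.copy()
        for j in incomplete:  # initial fill: random observed draws
            obs_vals = data[~miss[:, j], j]
            filled[miss[:, j], j] = rng.choice(obs_vals, size=miss[:, j].sum())
        for _ in range(sweeps if incomplete else 0):
            for j in incomplete:
                obs = ~miss[:, j]
                other = [k for k in range(len(cols)) if k != j]
                x = np.column_stack([np.ones(len(filled)), filled[:, other]])
                filled[miss[:, j], j] = _pmm_one_variable(
                    filled[:, j], x, obs, miss[:, j], rng, donors)
        out = table.copy()
        out[cols] = filled
        completed.append(out)
    return completed


# ---------------------------------------------------------------------------
# Models

def _design(table: pd.DataFrame, terms: Sequence[str]) -> pd.DataFrame:
    x = table[list(terms)].astype(float)
    x = sm.add_constant(x, has_constant="add")
    rank = np.linalg.matrix_rank(x.to_numpy())
    if rank < x.shape[1]:
        # name the offending columns: those whose removal restores full rank
        bad = [c for c in x.columns if c != "const" and
               np.linalg.matrix_rank(x.drop(columns=c).to_numpy())
               == np.linalg.matrix_rank(x.to_numpy())]
        raise InputError(f"rank-deficient design; collinear columns: {bad}")
    return x


def fit_linear(table: pd.DataFrame, outcome: str, exposure: str,
               covariates: Sequence[str] = DEFAULT_COVARIATES
               ) -> dict[str, tuple[float, float, float]]:
    """OLS of ``outcome`` on ``exposure`` plus covariates.

    Returns ``{term: (beta, sampling variance, residual df)}`` with
    unstandardised coefficients.
    """
    terms = [exposure, *covariates]
    data = table[[outcome, *terms]].dropna()
    x = _design(data, terms)
    if len(data) <= x.shape[1]:
        raise InputError("too few rows for the requested model")
    fit = sm.OLS(data[outcome].astype(float), x).fit()
    return {t: (float(fit.params[t]), float(fit.bse[t]) ** 2, float(fit.df_resid))
            for t in x.columns}


@dataclass
class RandomInterceptFit:
    """Profiled-REML fit of ``y = X beta + u_subject + e``."""

    terms: dict[str, tuple[float, float, float]]  # term -> (beta, var, df)
    sigma_u2: float  # between-subject (random intercept) variance
    sigma_e2: float  # residual variance
    theta: float  # variance ratio sigma_u2 / sigma_e2
    n_obs: int
    n_groups: int


def _gls_random_intercept(y_groups, x_groups, theta: float):
    """Closed-form GLS for V_g = I + theta * 11' per group; returns
    (beta, xtvix, rss_gls, logdet_v, logdet_xtvix)."""
    p = x_groups[0].shape[1]
    xtvix = np.zeros((p, p))
    xtviy = np.zeros(p)
    logdet_v = 0.0
    for y_g, x_g in zip(y_groups, x_groups):
        n_g = len(y_g)
        shrink = theta / (1.0 + n_g * theta)
        xs, ys = x_g.sum(axis=0), y_g.sum()
        xtvix += x_g.T @ x_g - shrink * np.outer(xs, xs)
        xtviy += x_g.T @ y_g - shrink * xs * ys
        logdet_v += np.log1p(n_g * theta)
    beta = np.linalg.solve(xtvix, xtviy)
    rss = 0.0
    for y_g, x_g in zip(y_groups, x_groups):
        r = y_g - x_g @ beta
        n_g = len(r)
        shrink = theta / (1.0 + n_g * theta)
        rss += r @ r - shrink * r.sum() ** 2
    sign, logdet_x = np.linalg.slogdet(xtvix)
    return beta, xtvix, float(rss), float(logdet_v), float(logdet_x)


def fit_random_intercept(table: pd.DataFrame, outcome: str, exposure: str,
                         covariates: Sequence[str] = DEFAULT_COVARIATES,
                         time: str | None = "time_since_baseline",
                         group: str = "subject_id") -> RandomInterceptFit:
    """Random-intercept linear mixed model by profiled REML.

    The variance ratio theta = sigma_u^2 / sigma_e^2 is profiled: at each
    candidate the fixed effects have a closed-form GLS solution (the
    per-group inverse of I + theta*11' is analytic), and the REML
    log-likelihood is maximised over log(theta) by scalar optimisation.
    At theta = 0 the fit reduces exactly to OLS.
    """
    from scipy.optimize import minimize_scalar

    terms = [exposure, *covariates] + ([time] if time is not None else [])
    data = table[[outcome, group, *terms]].dropna()
    x = _design(data, terms)
    if len(data) <= x.shape[1]:
        raise InputError("too few rows for the requested mixed model")
    xcols = list(x.columns)
    xv = x.to_numpy(dtype=float)
    yv = data[outcome].to_numpy(dtype=float)
    codes = pd.factorize(data[group])[0]
    order = np.argsort(codes, kind="stable")
    xv, yv, codes = xv[order], yv[order], codes[order]
    splits = np.flatnonzero(np.diff(codes)) + 1
    x_groups = np.split(xv, splits)
    y_groups = np.split(yv, splits)
    n, p = xv.shape

    def neg_reml(log_theta: float) -> float:
        theta = np.exp(log_theta)
        _, _, rss, logdet_v, logdet_x = _gls_random_intercept(
            y_groups, x_groups, theta)
        sigma_e2 = rss / (n - p)
        return 0.5 * ((n - p) * np.log(sigma_e2) + logdet_v + logdet_x
                      + (n - p))

    res = minimize_scalar(neg_reml, bounds=(np.log(1e-10), np.log(1e6)),
                          method="bounded",
                          options={"xatol": 1e-10, "maxiter": 500})
    if not res.success:
        raise ConvergenceError(
            f"profiled REML failed to converge: {res.message}")
    theta = float(np.exp(res.x))
    # boundary handling: an essentially-zero ratio is exactly OLS
    if neg_reml(np.log(1e-12)) <= res.fun + 1e-10:
        theta = 0.0
    beta, xtvix, rss, _, _ = _gls_random_intercept(y_groups, x_groups, theta)
    sigma_e2 = rss / (n - p)
    cov = sigma_e2 * np.linalg.inv(xtvix)
    df = float(n - p)
    terms_out = {c: (float(beta[j]), float(cov[j, j]), df)
                 for j, c in enumerate(xcols)}
    return RandomInterceptFit(terms=terms_out, sigma_u2=theta * sigma_e2,
                              sigma_e2=float(sigma_e2), theta=theta,
                              n_obs=n, n_groups=len(x_groups))


def fit_lmm(table: pd.DataFrame, outcome: str, exposure: str,
            covariates: Sequence[str] = DEFAULT_COVARIATES,
            time: str = "time_since_baseline",
            group: str = "subject_id") -> dict[str, tuple[float, float, float]]:
    """Fixed-effect estimates of the random-intercept model (see
    :func:`fit_random_intercept`): ``{term: (beta, variance, df)}``."""
    return fit_random_intercept(table, outcome, exposure, covariates,
                                time, group).terms


# ---------------------------------------------------------------------------
# Pooling and multiplicity

@dataclass
class PooledEstimate:
    """One coefficient pooled over imputations by Rubin's rules."""

    term: str
    beta: float
    within_var: float
    between_var: float
    total_var: float
    se: float
    df: float
    p_two_sided: float
    p_fdr: float = float("nan")
    m: int = 1

    def __post_init__(self) -> None:
        if self.total_var < self.within_var - 1e-12:
            raise InputError("total variance cannot fall below within variance")


def pool_rubin(estimates: Sequence[tuple[float, float]], m: int | None = None,
               term: str = "", df_com: float = np.inf) -> PooledEstimate:
    """Pool per-imputation (beta, variance) pairs by Rubin's rules.

    Total variance T = W + (1 + 1/m) B with W the mean within-imputation
    variance and B the between-imputation sample variance of the betas.
    Degrees of freedom follow Barnard-Rubin when a finite complete-data df
    is supplied, else the classic large-sample formula; the two-sided p is
    from the t distribution.
    """
    if len(estimates) == 0:
        raise InputError("pool_rubin needs at least one estimate")
    m = len(estimates) if m is None else m
    if m != len(estimates):
        raise InputError("m does not match the number of estimates")
    betas = np.array([e[0] for e in estimates], dtype=float)
    vars_ = np.array([e[1] for e in estimates], dtype=float)
    beta = float(betas.mean())
    w = float(vars_.mean())
    if m == 1:
        warnings.warn("pool_rubin with m=1: between-imputation variance "
                      "is unidentified; total variance equals within variance")
        b = 0.0
    else:
        b = float(betas.var(ddof=1))
    t = w + (1.0 + 1.0 / m) * b
    se = float(np.sqrt(t))
    if b == 0.0 or m == 1:
        df = df_com if np.isfinite(df_com) else 1e8
    else:
        lam = (1.0 + 1.0 / m) * b / t
        df_old = (m - 1) / lam**2
        if np.isfinite(df_com):
            df_obs = ((df_com + 1.0) / (df_com + 3.0)) * df_com * (1.0 - lam)
            df = 1.0 / (1.0 / df_old + 1.0 / df_obs)
        else:
            df = df_old
    if se > 0:
        p = float(2.0 * sps.t.sf(abs(beta) / se, df))
    else:
        p = float("nan") if beta == 0 else 0.0
    return PooledEstimate(term=term, beta=beta, within_var=w, between_var=b,
                          total_var=t, se=se, df=float(df), p_two_sided=p, m=m)


def fdr_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


# ---------------------------------------------------------------------------
# Analysis drivers

def build_analysis_table(metadata: pd.DataFrame, coupling_table: pd.DataFrame,
                         follow_up_years: float = 4.0) -> pd.DataFrame:
    """Merge cohort metadata with coupling profiles into the modelling table.

    Apathy and depression raw scores are natural-log transformed (observed
    non-positive raws are a contract violation and raise). Adds
    ``time_since_baseline`` (0 at wave 1).
    """
    table = metadata.merge(coupling_table, on=["subject_id", "timepoint"],
                           how="inner")
    for raw, logged in (("apathy", "log_apathy"), ("depression", "log_depression")):
        if raw in table:
            vals = table[raw].to_numpy(dtype=float)
            bad = (vals <= 0) & ~np.isnan(vals)
            if bad.any():
                raise InputError(
                    f"{raw} has non-positive raw scores; log transform undefined")
            table[logged] = np.log(vals)
    table["time_since_baseline"] = np.where(
        table["timepoint"] == 1, 0.0, follow_up_years)
    return table


def run_model_table(table: pd.DataFrame, design: str,
                    networks: Sequence[str],
                    outcomes: Sequence[str],
                    covariates: Sequence[str] = DEFAULT_COVARIATES,
                    m: int = 20, seed: int | None = None,
                    sweeps: int = 10) -> pd.DataFrame:
    """One results table: every network x outcome association, pooled + FDR.

    ``design`` is ``"cross"`` (OLS on wave-1 rows) or ``"long"``
    (random-intercept mixed model on all rows). Imputation runs once on the
    full table (all networks, outcomes and covariates as predictors of each
    other); each model is then fit on each completed table and pooled by
    Rubin's rules. FDR adjustment treats the whole table as one family.
    """
    if design not in ("cross", "long"):
        raise InputError("design must be 'cross' or 'long'")
    work = table.loc[table["timepoint"] == 1] if design == "cross" else table
    # undefined coupling (too few eligible edges) is a structural flag, not a
    # missing outcome: networks with no defined values at all are skipped,
    # remaining rows with undefined predictors are excluded rather than imputed
    networks = list(networks)
    for nw in list(networks):
        if nw not in work.columns or work[nw].isna().all():
            warnings.warn(f"network {nw!r} has no defined coupling values; "
                          "skipped from the results table")
            networks.remove(nw)
    predictor_cols = [c for c in {*networks, *covariates, "time_since_baseline"}
                      if c in work.columns]
    work = work.dropna(subset=predictor_cols).reset_index(drop=True)
    impute_cols = [c for c in [*predictor_cols, *outcomes]
                   if c in work.columns and pd.api.types.is_numeric_dtype(work[c])]
    imputed = pmm_impute(work, m=m, rng=seed, sweeps=sweeps, columns=impute_cols)

    rows = []
    for network in networks:
        for outcome in outcomes:
            per_imp = []
            df_com = np.inf
            for completed in imputed:
                if design == "cross":
                    fit = fit_linear(completed, outcome, network, covariates)
                else:
                    fit = fit_lmm(completed, outcome, network, covariates)
                beta, var, df_com = fit[network]
                per_imp.append((beta, var))
            pooled = pool_rubin(per_imp, m=m, term=network, df_com=df_com)
            rows.append({
                "network": network, "outcome": outcome,
                "beta": pooled.beta, "se": pooled.se,
                "p": pooled.p_two_sided, "n": int(len(work)), "m": m,
            })
    result = pd.DataFrame(rows)
    result["p_fdr"] = fdr_adjust(result["p"].tolist())
    return result[["network", "outcome", "beta", "se", "p", "p_fdr", "n", "m"]]
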