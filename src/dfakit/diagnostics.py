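"""Post-hoc diagnostics: goodness of fit, residuals and environmental
correlations with autocorrelation-adjusted degrees of freedom.

Correlations between autocorrelated time series overstate their effective
sample size; the modified Chelton correction (restricted to lag 1)
deflates N before the t-test on Spearman's rho:

    1/N* = 1/N + (2/N) * r_x(1) * r_y(1)

capped at N when the correction would exceed it and floored at 3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dfa import DFAFit, fitted_values

__all__ = [
    "CorrelationResult",
    "DiagnosticsReport",
    "r_squared",
    "strong_loadings",
    "lag1_autocorrelation",
    "effective_n",
    "spearman_adjusted",
    "trend_climate_correlations",
    "residual_env_correlations",
    "residual_diagnostics",
]

log = logging.getLogger(__name__)


@dataclass
class CorrelationResult:
    """Spearman rho with autocorrelation-adjusted significance."""

    rho: float
    N: int
    n_eff: float
    p: float


def _panel_array(panel):
    if hasattr(panel, "to_array"):
        return panel.to_array()
    return np.asarray(panel, dtype=float)


def r_squared(fit: DFAFit, panel, covariates=None):
    """Per-series and overall r^2 = 1 - SSE/SST over non-missing cells.

    SST is taken about each series' own mean of the z-scored data (the
    overall value pools cells across series).  Values below zero are
    possible for a poorly fitting series and are reported as-is.
    """
    Y = _panel_array(panel)
    pred = fitted_values(fit, covariates)
    obs = ~np.isnan(Y)
    n = Y.shape[0]
    per_series = np.empty(n)
    sse_total = sst_total = 0.0
    for i in range(n):
        o = obs[i]
        y = Y[i, o]
        sse = float(np.sum((y - pred[i, o]) ** 2))
        sst = float(np.sum((y - y.mean()) ** 2))
        if sst == 0:
            raise ValueError(f"series {i} has zero variance; r^2 undefined")
        per_series[i] = 1.0 - sse / sst
        sse_total += sse
        sst_total += sst
    return per_series, 1.0 - sse_total / sst_total


def strong_loadings(Z: np.ndarray, threshold: float = 0.2) -> np.ndarray:
    """Mask of loadings treated as interpretable: strictly |z| > threshold."""
    return np.abs(np.asarray(Z, dtype=float)) > threshold


def lag1_autocorrelation(series, flag_bound: float = 1.96):
    """Sample lag-1 autocorrelation over consecutively observed pairs.

    Returns ``(r1, significant)`` where the flag tests |r1| against
    ``flag_bound / sqrt(N)`` with N the number of non-missing values.
    Requires at least 4 observations; a constant series is undefined.
    """
    x = np.asarray(series, dtype=float)
    obs = ~np.isnan(x)
    N = int(obs.sum())
    if N < 4:
        raise ValueError("lag-1 autocorrelation needs at least 4 observations")
    c = x - np.nanmean(x)
    denom = float(np.nansum(c[obs] ** 2))
    if denom == 0:
        raise ValueError("constant series: autocorrelation undefined")
    pairs = obs[:-1] & obs[1:]
    num = float(np.nansum(np.where(pairs, c[:-1] * c[1:], 0.0)))
    r1 = num / denom
    return r1, bool(abs(r1) > flag_bound / np.sqrt(N))


def effective_n(x, y) -> float:
    """Autocorrelation-adjusted effective sample size for a correlation.

    Uses lag-1 autocorrelations of the two (overlap-restricted) series:
    1/N* = 1/N + (2/N) r_x(1) r_y(1).  N* is capped at N when the product
    is negative and floored at 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    overlap = ~np.isnan(x) & ~np.isnan(y)
    N = int(overlap.sum())
    if N < 4:
        raise ValueError("effective_n needs at least 4 overlapping observations")
    xo = np.where(overlap, x, np.nan)
    yo = np.where(overlap, y, np.nan)
    rx, _ = lag1_autocorrelation(xo)
    ry, _ = lag1_autocorrelation(yo)
    denom = 1.0 + 2.0 * rx * ry
    if denom <= 0:
        return float(N)
    return float(np.clip(N / denom, 3.0, N))


def spearman_adjusted(x, y) -> CorrelationResult:
    """Spearman rank correlation with effective-df significance.

    rho uses average ranks for ties; the two-sided p-value comes from a
    t-statistic with N_eff - 2 degrees of freedom, N_eff from
    :func:`effective_n`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    overlap = ~np.isnan(x) & ~np.isnan(y)
    N = int(overlap.sum())
    if N < 4:
        raise ValueError("spearman_adjusted needs at least 4 overlapping observations")
    xs, ys = x[overlap], y[overlap]
    if np.all(xs == xs[0]) or np.all(ys == ys[0]):
        raise ValueError("constant input: correlation undefined")
    rho = float(stats.spearmanr(xs, ys).statistic)
    n_eff = effective_n(np.where(overlap, x, np.nan), np.where(overlap, y, np.nan))
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n_eff - 2.0) / (1.0 - rho**2))
        p = float(2.0 * stats.t.sf(abs(t), df=n_eff - 2.0))
    return CorrelationResult(rho=rho, N=N, n_eff=n_eff, p=p)


def trend_climate_correlations(
    trends: np.ndarray, climate: dict[str, np.ndarray]
) -> pd.DataFrame:
    """Correlate each (rotated) trend with each regional climate index."""
    trends = np.atleast_2d(trends)
    rows = []
    for j in range(trends.shape[0]):
        for name, series in climate.items():
            res = spearman_adjusted(trends[j], np.asarray(series, dtype=float))
            rows.append(
                {
                    "trend": j + 1,
                    "variable": name,
                    "rho": res.rho,
                    "N": res.N,
                    "n_eff": res.n_eff,
                    "p": res.p,
                }
            )
    return pd.DataFrame(rows)


def residual_env_correlations(
    fit: DFAFit, panel, env: pd.DataFrame, covariates=None
) -> pd.DataFrame:
    """Correlate each series' residuals with its station environment.

    ``env`` is long-format (station, year, variable columns); stations
    without environmental data are skipped with a log entry.  Pairs with
    no overlapping years are recorded with NaN results.
    """
    Y = _panel_array(panel)
    resid = Y - fitted_values(fit, covariates)
    meta = panel.meta
    years = panel.years
    env_vars = [c for c in env.columns if c not in ("station", "year")]
    rows = []
    for i, (sid, srow) in enumerate(meta.iterrows()):
        station = srow["station"]
        st_env = env[env["station"] == station]
        if st_env.empty:
            log.info("no environmental data for station %s; skipped", station)
            continue
        st_env = st_env.set_index("year").reindex(years)
        for var in env_vars:
            e = st_env[var].to_numpy(dtype=float)
            try:
                res = spearman_adjusted(resid[i], e)
                rows.append(
                    {
                        "series": sid,
                        "station": station,
                        "class": srow.get("class", ""),
                        "variable": var,
                        "rho": res.rho,
                        "N": res.N,
                        "n_eff": res.n_eff,
                        "p": res.p,
                    }
                )
            except ValueError as exc:
                log.info("correlation undefined for %s/%s: %s", sid, var, exc)
                rows.append(
                    {
                        "series": sid,
                        "station": station,
                        "class": srow.get("class", ""),
                        "variable": var,
                        "rho": np.nan,
                        "N": 0,
                        "n_eff": np.nan,
                        "p": np.nan,
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class DiagnosticsReport:
    """Residual and goodness-of-fit summary for a fitted model."""

    per_series: pd.DataFrame  # r2, lag1, lag1_flag, normality_p, homogeneity_rho
    overall_r2: float
    residuals: np.ndarray
    strong_loading_mask: np.ndarray
    n_lag1_flagged: int
    n_nonnormal: int


def residual_diagnostics(
    fit: DFAFit, panel, covariates=None, alpha: float = 0.05
) -> DiagnosticsReport:
    """Assemble per-series residual diagnostics into one report.

    Normality per series via the D'Agostino-Pearson omnibus test (NaN when
    fewer than 8 residuals); homogeneity summarized descriptively as the
    Spearman correlation between |residual| and fitted value; lag-1
    autocorrelation with its +/-1.96/sqrt(N) flag; r^2 per series; and the
    |loading| > 0.2 interpretability mask.
    """
    Y = _panel_array(panel)
    pred = fitted_values(fit, covariates)
    resid = Y - pred
    per_r2, overall = r_squared(fit, panel, covariates)
    ids = list(panel.meta.index) if hasattr(panel, "meta") else list(range(Y.shape[0]))
    rows = []
    for i in range(Y.shape[0]):
        r = resid[i]
        o = ~np.isnan(r)
        try:
            r1, flagged = lag1_autocorrelation(r)
        except ValueError:
            r1, flagged = np.nan, False
        if o.sum() >= 8:
            norm_p = float(stats.normaltest(r[o]).pvalue)
        else:
            norm_p = np.nan
        if o.sum() >= 4 and np.std(pred[i, o]) > 0 and np.std(np.abs(r[o])) > 0:
            homo = float(stats.spearmanr(pred[i, o], np.abs(r[o])).statistic)
        else:
            homo = np.nan
        rows.append(
            {
                "series": ids[i],
                "r2": per_r2[i],
                "lag1": r1,
                "lag1_flag": flagged,
                "normality_p": norm_p,
                "homogeneity_rho": homo,
            }
        )
    per_series = pd.DataFrame(rows).set_index("series")
    mask = strong_loadings(fit.params.Z)
    return DiagnosticsReport(
        per_series=per_series,
        overall_r2=overall,
        residuals=resid,
        strong_loading_mask=mask,
        n_lag1_flagged=int(per_series["lag1_flag"].sum()),
        n_nonnormal=int((per_series["normality_p"] < alpha).sum()),
    )
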