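"""Synthetic monitoring panels drawn from the DFA generative model.

The generator emulates a Baltic-style phytoplankton monitoring panel: 17
stations (ordered southwest to northeast) x 4 classes over 34 years
(1979-2012), with 20-33 observed years per station, latent random-walk
trends, block loading structure by class and by north/south geography,
occasional zero biomass years per class, and whole-year class-wide absence
anomalies.  Latent anomalies are scaled to a configurable log-mean/log-sd
and exponentiated, so downstream preprocessing (summer means, zero
replacement, ln, z-score) is exercised end-to-end; the generating trends,
loadings and covariances are kept as ground truth for tests.

All outputs are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_trends",
    "simulate_observations",
    "build_block_loadings",
    "simulate_climate_index",
    "simulate_station_environment",
    "inject_anomalies",
    "impose_missingness",
    "simulate_dataset",
    "write_dataset",
]

DEFAULT_CLASSES = ("cyanobacteria", "dinoflagellates", "diatoms", "cryptophytes")
LOADING_SCHEMES = ("by-class", "by-geography", "mixed")


@dataclass
class SimulationConfig:
    """Study-design knobs of the synthetic monitoring panel.

    Defaults reproduce the reference design: 17 stations, the four major
    summer classes, 34 years starting 1979, with each station observed in
    20-33 of the years.  ``r_spec`` is (structure, variance[, covariance]);
    ``anomaly_events`` lists (year, class, stations-or-None) whole-year
    absences; ``covariate_spec`` is (ar_coef, shift_year, shift_size) for a
    regime-shifting climate index.
    """

    n_stations: int = 17
    classes: tuple[str, ...] = DEFAULT_CLASSES
    T: int = 34
    start_year: int = 1979
    m_true: int = 2
    loading_scheme: str = "mixed"
    loading_magnitude: float = 0.6
    loading_jitter: float = 0.05
    r_spec: tuple = ("diagonal-equal", 0.25)
    missing_years_range: tuple[int, int] = (1, 14)
    zero_inflation_prob: float = 0.03
    anomaly_events: list = field(default_factory=list)
    covariate_spec: tuple = (0.3, 16, -1.0)
    covariate_effect: float = 0.0
    log_mean: float = 4.0
    log_sd: float = 1.0
    samples_per_year: tuple[int, int] = (1, 3)
    within_year_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T < 3:
            raise ValueError("T must be at least 3")
        if self.m_true < 1:
            raise ValueError("m_true must be at least 1")
        if not 0.0 <= self.zero_inflation_prob <= 1.0:
            raise ValueError("zero_inflation_prob must be in [0, 1]")
        for event in self.anomaly_events:
            year = event[0]
            if not (self.start_year <= year < self.start_year + self.T):
                raise ValueError(f"anomaly year {year} outside the simulated span")
        shift_year = self.covariate_spec[1]
        if shift_year is not None and not 0 <= shift_year <= self.T:
            raise ValueError(
                f"covariate shift year index {shift_year} outside the simulated span"
            )
        lo, hi = self.missing_years_range
        if lo < 0 or hi > self.T - 3:
            raise ValueError(
                "missing_years_range must keep at least 3 observed years per station"
            )

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.start_year + self.T)

    @property
    def stations(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_stations)]


@dataclass
class SimulatedDataset:
    """A raw-scale sample table plus the generating truth."""

    biomass_table: pd.DataFrame  # long format: station, date, class, value, unit
    covariates: pd.DataFrame  # year-indexed climate index values
    environment: pd.DataFrame  # station, year, temperature, salinity
    truth: dict  # X (m x T), Z, R, D, anomaly panel
    config: SimulationConfig


def simulate_trends(
    m: int, T: int, seed=None, rng: np.random.Generator | None = None, kappa: float = 5.0
) -> np.ndarray:
    """Draw m latent random-walk trends of length T.

    Each row is a cumulative sum of i.i.d. standard-normal increments
    (state covariance = identity) started from the initial-state prior
    x_0 ~ N(0, kappa I); the first column is x_0 + w_1.
    """
    if m < 1:
        raise ValueError("m must be at least 1")
    if T < 2:
        raise ValueError("T must be at least 2")
    rng = rng if rng is not None else np.random.default_rng(seed)
    x0 = rng.normal(0.0, np.sqrt(kappa), size=m)
    increments = rng.standard_normal((m, T))
    return x0[:, None] + np.cumsum(increments, axis=1)


def simulate_observations(
    trends: np.ndarray,
    Z: np.ndarray,
    R: np.ndarray,
    D: np.ndarray | None = None,
    covariates: np.ndarray | None = None,
    seed=None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Observation equation: Y = Z X + D d + MVN(0, R) noise per year."""
    trends = np.atleast_2d(np.asarray(trends, dtype=float))
    Z = np.asarray(Z, dtype=float)
    m, T = trends.shape
    if Z.ndim != 2 or Z.shape[1] != m:
        raise ValueError(f"Z must be (n, {m})")
    n = Z.shape[0]
    R = np.asarray(R, dtype=float)
    if R.shape != (n, n):
        raise ValueError("R must be n x n")
    if not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("R must be symmetric")
    eig = np.linalg.eigvalsh(R)
    if eig.min() < -1e-10:
        raise ValueError("R must be positive semi-definite")
    rng = rng if rng is not None else np.random.default_rng(seed)
    Y = Z @ trends
    if D is not None:
        d = np.asarray(covariates, dtype=float)
        if d.shape != (T,):
            raise ValueError("covariates must match the trend length")
        Y = Y + np.outer(np.asarray(D, dtype=float), d)
    # PSD square root via eigendecomposition (R may be singular)
    vals, vecs = np.linalg.eigh(R)
    root = vecs @ np.diag(np.sqrt(np.clip(vals, 0.0, None)))
    Y = Y + root @ rng.standard_normal((n, T))
    return Y


def build_block_loadings(
    n_stations: int,
    classes: tuple[str, ...],
    scheme: str,
    magnitude: float = 0.6,
    jitter: float = 0.0,
    seed=None,
    split_index: int | None = None,
    m: int | None = None,
) -> np.ndarray:
    """Construct a block-structured loading matrix Z (series x trends).

    Series are ordered station-major (all classes of station 1, then
    station 2, ...), stations running southwest to northeast.  Schemes:

    - ``by-class``: one trend per class; every series of a class loads
      ``magnitude`` on its class trend.
    - ``by-geography``: two trends; series rows below ``split_index`` load
      trend 1 only, the rest trend 2 only.
    - ``mixed``: two trends crossing geography and class: the *last* class
      (cryptophyte-like) loads strongly on trend 1 in the southern half and
      on trend 2 in the northern half; other classes load at half magnitude
      on their region's trend.

    ``jitter`` adds seeded N(0, jitter) noise to off-block cells.
    """
    if scheme not in LOADING_SCHEMES:
        raise ValueError(f"unknown loading scheme {scheme!r}; choose from {LOADING_SCHEMES}")
    n_classes = len(classes)
    n = n_stations * n_classes
    if scheme == "by-class":
        m_eff = m if m is not None else n_classes
        Z = np.zeros((n, m_eff))
        for s in range(n_stations):
            for c in range(n_classes):
                Z[s * n_classes + c, c % m_eff] = magnitude
    elif scheme == "by-geography":
        m_eff = 2
        k = split_index if split_index is not None else n // 2
        Z = np.zeros((n, m_eff))
        Z[:k, 0] = magnitude
        Z[k:, 1] = magnitude
    else:  # mixed
        m_eff = 2
        Z = np.zeros((n, m_eff))
        south = n_stations // 2
        for s in range(n_stations):
            region = 0 if s < south else 1
            for c in range(n_classes):
                row = s * n_classes + c
                mag = magnitude if c == n_classes - 1 else magnitude / 2.0
                Z[row, region] = mag
    if jitter:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, jitter, size=Z.shape)
        Z = np.where(Z == 0.0, noise, Z)
    return Z


def simulate_climate_index(
    T: int,
    ar_coef: float,
    shift_year: int | None = None,
    shift_size: float = 0.0,
    seed=None,
    rng: np.random.Generator | None = None,
    innovation_sd: float = 1.0,
) -> np.ndarray:
    """AR(1) climate index with an optional step change in its mean.

    ``shift_year`` is the 0-based index at which the mean steps by
    ``shift_size`` (e.g. a mid-series regime shift).  The series never has
    missing values (covariates must be complete).
    """
    if not abs(ar_coef) < 1:
        raise ValueError("|ar_coef| must be < 1 (stationary AR(1))")
    rng = rng if rng is not None else np.random.default_rng(seed)
    x = np.empty(T)
    scale = innovation_sd / np.sqrt(1.0 - ar_coef**2)
    x[0] = rng.normal(0.0, scale)
    eps = rng.normal(0.0, innovation_sd, size=T)
    for t in range(1, T):
        x[t] = ar_coef * x[t - 1] + eps[t]
    if shift_year is not None and shift_size:
        if not 0 <= shift_year <= T:
            raise ValueError("shift_year outside the simulated span")
        x[shift_year:] += shift_size
    return x


def simulate_station_environment(
    stations: list[str], years: np.ndarray, seed=None, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Station temperature/salinity series with a latitudinal gradient.

    Southern (low-index) stations are warmer and saltier; interannual
    variation is AR(1).  Used for residual-vs-environment correlations.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    rows = []
    n = len(stations)
    for i, st in enumerate(stations):
        frac = i / max(n - 1, 1)
        temp = 18.0 - 4.0 * frac + simulate_climate_index(len(years), 0.3, rng=rng) * 0.8
        sal = 9.0 - 6.0 * frac + simulate_climate_index(len(years), 0.4, rng=rng) * 0.5
        rows.append(
            pd.DataFrame(
                {"station": st, "year": years, "temperature": temp, "salinity": sal}
            )
        )
    return pd.concat(rows, ignore_index=True)


def inject_anomalies(biomass_table: pd.DataFrame, events) -> pd.DataFrame:
    """Zero out whole-year class biomass for the listed absence events.

    ``events``: iterable of (year, class, stations) where ``stations`` is a
    collection of station labels or None for all stations.  Idempotent;
    an event referencing a year or class absent from the table raises.
    """
    out = biomass_table.copy()
    dates = pd.to_datetime(out["date"])
    table_years = set(dates.dt.year.unique())
    table_classes = set(out["class"].unique())
    for year, cls, stations in events:
        if year not in table_years:
            raise ValueError(f"anomaly year {year} outside the panel span")
        if cls not in table_classes:
            raise ValueError(f"unknown class {cls!r} in anomaly event")
        mask = (dates.dt.year == year) & (out["class"] == cls)
        if stations is not None:
            mask &= out["station"].isin(list(stations))
        out.loc[mask, "value"] = 0.0
    return out


def impose_missingness(
    panel: np.ndarray, per_series_missing_years, seed=None, rng=None
) -> np.ndarray:
    """Mask a given number of years per series, keeping >= 3 observations.

    ``per_series_missing_years`` is a scalar or length-n array of counts;
    masked cells are chosen uniformly at random among currently observed
    years, seeded.  Over-masking (fewer than 3 observations left) raises.
    """
    panel = np.array(panel, dtype=float)
    n, T = panel.shape
    counts = np.broadcast_to(np.asarray(per_series_missing_years, dtype=int), (n,))
    rng = rng if rng is not None else np.random.default_rng(seed)
    for i in range(n):
        observed = np.where(~np.isnan(panel[i]))[0]
        if observed.size - counts[i] < 3:
            raise ValueError(
                f"masking {counts[i]} years leaves series {i} with fewer than 3 observations"
            )
        if counts[i] > 0:
            drop = rng.choice(observed, size=counts[i], replace=False)
            panel[i, drop] = np.nan
    return panel


def _true_R(config: SimulationConfig, n: int) -> np.ndarray:
    structure, *vals = config.r_spec
    var = float(vals[0]) if vals else 0.25
    if structure == "diagonal-equal":
        return var * np.eye(n)
    if structure == "equal-variance-covariance":
        cov = float(vals[1]) if len(vals) > 1 else 0.0
        return var * np.eye(n) + cov * (np.ones((n, n)) - np.eye(n))
    if structure == "diagonal-unequal":
        if len(vals) > 1:
            return np.diag(np.asarray(vals[1], dtype=float))
        return var * np.eye(n)
    raise ValueError(f"unsupported true R structure {config.r_spec[0]!r}")


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate a full synthetic monitoring dataset with ground truth.

    Steps: latent trends -> block loadings -> anomaly panel (observation
    noise, optional covariate effect) -> scale to log-biomass and
    exponentiate -> zero-inflation -> long sample table with 1-3 July/August
    sampling dates per observed station-year -> whole-year absence events ->
    station-level missing years.  The same years are missing for all classes
    of a station, as in real monitoring (an unsampled station-year).
    """
    root = np.random.SeedSequence(config.seed)
    keys = root.spawn(7)
    n_classes = len(config.classes)
    n = config.n_stations * n_classes

    X = simulate_trends(config.m_true, config.T, rng=np.random.default_rng(keys[0]))
    Z = build_block_loadings(
        config.n_stations,
        config.classes,
        config.loading_scheme,
        magnitude=config.loading_magnitude,
        jitter=config.loading_jitter,
        seed=keys[1],
        m=config.m_true if config.loading_scheme == "by-class" else None,
    )
    if Z.shape[1] != config.m_true:
        raise ValueError(
            f"loading scheme {config.loading_scheme!r} yields {Z.shape[1]} trends, "
            f"but m_true={config.m_true}"
        )
    R = _true_R(config, n)
    ar, shift_year, shift_size = config.covariate_spec
    cov = simulate_climate_index(
        config.T, ar, shift_year, shift_size, rng=np.random.default_rng(keys[2])
    )
    D = None
    if config.covariate_effect:
        D = np.full(n, config.covariate_effect)
    anomalies = simulate_observations(
        X, Z, R, D=D, covariates=cov, rng=np.random.default_rng(keys[3])
    )

    biomass = np.exp(config.log_mean + config.log_sd * anomalies)
    rng_zero = np.random.default_rng(keys[4])
    if config.zero_inflation_prob > 0:
        zero_mask = rng_zero.random(biomass.shape) < config.zero_inflation_prob
        biomass[zero_mask] = 0.0

    # station-level missing years (same years missing for every class there)
    rng_miss = np.random.default_rng(keys[5])
    lo, hi = config.missing_years_range
    station_missing: dict[str, np.ndarray] = {}
    for st in config.stations:
        k = int(rng_miss.integers(lo, hi + 1)) if hi > 0 else 0
        drop = rng_miss.choice(config.T, size=k, replace=False) if k else np.array([], int)
        station_missing[st] = set(drop.tolist())

    rng_obs = np.random.default_rng(keys[6])
    years = config.years
    records = []
    for s, st in enumerate(config.stations):
        for t, year in enumerate(years):
            if t in station_missing[st]:
                continue
            k_lo, k_hi = config.samples_per_year
            n_dates = int(rng_obs.integers(k_lo, k_hi + 1))
            days = np.sort(rng_obs.choice(62, size=n_dates, replace=False))
            for c, cls in enumerate(config.classes):
                value = biomass[s * n_classes + c, t]
                for day in days:
                    month, dom = (7, day + 1) if day < 31 else (8, day - 30)
                    v = value
                    if v > 0 and config.within_year_sd > 0:
                        v = v * np.exp(config.within_year_sd * rng_obs.standard_normal())
                    records.append(
                        (st, f"{year:04d}-{month:02d}-{dom:02d}", cls, v, "mg m-3")
                    )
    table = pd.DataFrame(
        records, columns=["station", "date", "class", "value", "unit"]
    )
    table = inject_anomalies(table, config.anomaly_events)

    env = simulate_station_environment(
        config.stations, years, rng=np.random.default_rng(np.random.SeedSequence([config.seed, 99]))
    )
    covariates = pd.DataFrame({"year": years, "value": cov})
    truth = {"X": X, "Z": Z, "R": R, "D": D, "anomalies": anomalies, "covariate": cov}
    return SimulatedDataset(table, covariates, env, truth, config)


def write_dataset(dataset: SimulatedDataset, out_dir) -> Path:
    """Write samples, covariates, environment and truth sidecars as CSV/JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset.biomass_table.to_csv(out / "samples.csv", index=False)
    dataset.covariates.to_csv(out / "covariates.csv", index=False)
    dataset.environment.to_csv(out / "environment.csv", index=False)
    truth = dataset.truth
    np.savetxt(out / "truth_trends.csv", truth["X"], delimiter=",")
    np.savetxt(out / "truth_loadings.csv", truth["Z"], delimiter=",")
    np.savetxt(out / "truth_R.csv", truth["R"], delimiter=",")
    if truth["D"] is not None:
        np.savetxt(out / "truth_D.csv", truth["D"], delimiter=",")
    cfg = asdict(dataset.config)
    cfg["classes"] = list(cfg["classes"])
    (out / "config.json").write_text(json.dumps(cfg, indent=2, default=str))
    return out
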