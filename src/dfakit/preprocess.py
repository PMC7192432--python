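"""From long-format monitoring samples to the z-scored anomaly panel.

The pipeline mirrors standard practice for plankton monitoring series:
same-day replicate samples are averaged first, then all sampled July-August
dates are averaged with equal weight into one summer mean per station, class
and year.  Within a single sample, taxa are optionally filtered to the
dominant set contributing ~90% of total biovolume (so that rare taxa counted
only in later years do not create spurious trends).  Class-level zero means
are replaced by a small random value so the series can be log-transformed,
and every series is ln-transformed and z-scored (mean 0, sample SD 1 over
its non-missing years) before analysis.

The transform state of a panel is tracked explicitly ("raw" -> "z") and the
pipeline order is enforced: z-scoring an already z-scored panel is an error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SeriesPanel",
    "daily_then_summer_mean",
    "filter_to_90pct_biovolume",
    "apply_biovolume_filter",
    "build_total_panel",
    "replace_zero_means",
    "log_z",
    "mask_years_and_rescore",
]

#: columns of a long-format sample table
SAMPLE_COLUMNS = ("station", "date", "class", "value")


@dataclass
class SeriesPanel:
    """n series x T years of (possibly missing) values plus series metadata.

    ``values`` is indexed by series id (``station_class``) with integer year
    columns; NaN marks missing years.  ``meta`` carries one row per series
    with at least ``station`` and ``class`` columns (class is ``"total"``
    for total-biomass series).  ``transform`` records where the panel sits
    in the pipeline: ``"raw"`` (summer means) or ``"z"`` (ln + z-scored).
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    transform: str = "raw"

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def T(self) -> int:
        return self.values.shape[1]

    @property
    def years(self) -> np.ndarray:
        return np.asarray(self.values.columns, dtype=int)

    def to_array(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def copy(self) -> "SeriesPanel":
        return SeriesPanel(self.values.copy(), self.meta.copy(), self.transform)

    def write_csv(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "station", self.meta["station"].to_numpy())
        out.insert(1, "class", self.meta["class"].to_numpy())
        out.to_csv(path, index_label="series")

    @classmethod
    def read_csv(cls, path, transform: str = "raw") -> "SeriesPanel":
        df = pd.read_csv(path, index_col="series")
        meta = df[["station", "class"]].copy()
        values = df.drop(columns=["station", "class"])
        values.columns = values.columns.astype(int)
        return cls(values, meta, transform)


def _check_samples(samples: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise ValueError(f"sample table lacks columns {missing}")
    if len(samples) == 0:
        raise ValueError("sample table is empty")
    if (samples["value"] < 0).any():
        raise ValueError("biomass/biovolume values must be non-negative")
    out = samples.copy()
    out["date"] = pd.to_datetime(out["date"])
    return out


def daily_then_summer_mean(
    samples: pd.DataFrame,
    months: tuple[int, ...] = (7, 8),
    years: tuple[int, int] | None = None,
) -> SeriesPanel:
    """Collapse raw samples to one July-August mean per station, class, year.

    Same-day replicates are averaged first; the summer mean then weights all
    sampled dates equally (not calendar-weighted).  Years without any sample
    in the selected months are missing.  ``years`` optionally fixes the
    panel span (first, last); by default it spans the observed years.
    """
    df = _check_samples(samples)
    df = df[df["date"].dt.month.isin(months)]
    if len(df) == 0:
        raise ValueError(f"no records in months {months}")
    df = df.assign(year=df["date"].dt.year)
    daily = (
        df.groupby(["station", "class", "year", "date"], sort=True)["value"]
        .mean()
        .reset_index()
    )
    summer = daily.groupby(["station", "class", "year"], sort=True)["value"].mean()
    wide = summer.unstack("year")
    if years is not None:
        span = range(int(years[0]), int(years[1]) + 1)
        wide = wide.reindex(columns=span)
    wide.columns = wide.columns.astype(int)
    meta = wide.index.to_frame(index=False)
    ids = meta["station"].astype(str) + "_" + meta["class"].astype(str)
    wide.index = ids
    meta.index = ids
    return SeriesPanel(wide, meta, transform="raw")


def filter_to_90pct_biovolume(
    sample: pd.DataFrame, threshold: float = 0.90
) -> pd.DataFrame:
    """Keep the dominant taxa of one sample (one station and date).

    Taxa are sorted by descending value (stable, so ties keep input order)
    and the shortest prefix whose cumulative share of the sample total
    reaches ``threshold`` is retained — the taxon that crosses the
    threshold is included.  A sample with zero total returns an empty frame
    with a warning.
    """
    if "value" not in sample.columns:
        raise ValueError("sample records need a 'value' column")
    total = sample["value"].sum()
    if total <= 0:
        warnings.warn("sample has zero total biovolume; nothing retained")
        return sample.iloc[0:0]
    order = sample["value"].to_numpy(dtype=float).argsort(kind="stable")[::-1]
    ordered = sample.iloc[order]
    cum = ordered["value"].cumsum() / total
    # index of the first row reaching the threshold, inclusive
    k = int(np.searchsorted(cum.to_numpy(), threshold - 1e-12) + 1)
    keep = ordered.iloc[:k]
    return sample.loc[sample.index.isin(keep.index)]


def apply_biovolume_filter(samples: pd.DataFrame, threshold: float = 0.90) -> pd.DataFrame:
    """Apply the dominant-taxa filter independently to every (station, date) sample."""
    df = _check_samples(samples)
    parts = [
        filter_to_90pct_biovolume(grp, threshold)
        for _, grp in df.groupby(["station", "date"], sort=False)
    ]
    return pd.concat(parts) if parts else df.iloc[0:0]


def build_total_panel(
    panel: SeriesPanel, include_classes: dict[str, list[str]] | None = None
) -> SeriesPanel:
    """Sum class summer means into one total-biomass series per station.

    ``include_classes`` maps a station to the classes consistently measured
    there (stations can differ, e.g. a ciliate counted at only one site);
    stations not listed use every class present.  A year is missing if any
    included class is missing that year.
    """
    if panel.transform != "raw":
        raise ValueError("totals are built from raw summer means")
    rows = {}
    for station, grp in panel.values.groupby(panel.meta["station"]):
        classes = panel.meta.loc[grp.index, "class"]
        if include_classes and station in include_classes:
            keep = classes.isin(include_classes[station])
            grp = grp[keep.to_numpy()]
        rows[station] = grp.sum(axis=0, skipna=False)
    values = pd.DataFrame(rows).T
    values.index = [f"{s}_total" for s in values.index]
    meta = pd.DataFrame(
        {"station": list(rows), "class": "total"}, index=values.index
    )
    return SeriesPanel(values, meta, transform="raw")


def replace_zero_means(panel: SeriesPanel, seed: int = 0) -> SeriesPanel:
    """Replace zero summer means by a draw from (0, min_nonzero/2].

    Applied to class-level series before the ln-transform (a class can be
    genuinely absent in a year's samples).  The replacement for each zero
    cell is uniform on (0, half the series' smallest positive value],
    seeded for reproducibility.  A series that is entirely zero has no
    defined minimum and raises.
    """
    if panel.transform != "raw":
        raise ValueError("zero replacement applies to raw summer means")
    out = panel.copy()
    rng = np.random.default_rng(seed)
    V = out.values.to_numpy(dtype=float)
    for i in range(V.shape[0]):
        row = V[i]
        zeros = np.where(row == 0.0)[0]
        if zeros.size == 0:
            continue
        positive = row[(row > 0) & ~np.isnan(row)]
        if positive.size == 0:
            raise ValueError(
                f"series {out.values.index[i]!r} is entirely zero; minimum undefined"
            )
        half_min = positive.min() / 2.0
        # uniform on (0, half_min]: 1 - U with U ~ [0, 1)
        row[zeros] = (1.0 - rng.random(zeros.size)) * half_min
    out.values.iloc[:, :] = V
    return out


def log_z(panel: SeriesPanel) -> SeriesPanel:
    """ln-transform then z-score every series over its non-missing years.

    Standardization uses the sample SD (denominator n-1).  Non-positive
    values are a domain error (zeros must be replaced first); a constant
    series has zero variance and raises.
    """
    if panel.transform != "raw":
        raise ValueError(f"panel is already {panel.transform!r}; log_z applies to raw means")
    out = panel.copy()
    V = out.values.to_numpy(dtype=float)
    if np.nanmin(V) <= 0:
        raise ValueError("all values must be positive before ln-transform")
    V = np.log(V)
    for i in range(V.shape[0]):
        row = V[i]
        m = ~np.isnan(row)
        if m.sum() < 2:
            raise ValueError(f"series {out.values.index[i]!r} has fewer than 2 observations")
        sd = np.std(row[m], ddof=1)
        if sd == 0:
            raise ValueError(f"series {out.values.index[i]!r} is constant; cannot z-score")
        V[i, m] = (row[m] - row[m].mean()) / sd
    out.values.iloc[:, :] = V
    out.transform = "z"
    return out


def mask_years_and_rescore(panel: SeriesPanel, years) -> SeriesPanel:
    """Set the listed years to missing in every series and re-z-score.

    The sensitivity analysis for influential years: observed values in the
    masked years are replaced by NaN in all series and each series is
    re-standardized over the remaining cells, so the panel again has mean 0
    and sample SD 1 per series.  Requires a z-scored panel and at least 3
    remaining observations per series.
    """
    if panel.transform != "z":
        raise ValueError("mask_years_and_rescore expects a z-scored panel")
    years = [int(y) for y in np.atleast_1d(years)]
    unknown = [y for y in years if y not in panel.values.columns]
    if unknown:
        raise ValueError(f"years {unknown} outside the panel span")
    out = panel.copy()
    if years:
        out.values.loc[:, years] = np.nan
    V = out.values.to_numpy(dtype=float)
    for i in range(V.shape[0]):
        row = V[i]
        m = ~np.isnan(row)
        if m.sum() < 3:
            raise ValueError(
                f"masking leaves fewer than 3 observations in series {out.values.index[i]!r}"
            )
        sd = np.std(row[m], ddof=1)
        if sd == 0:
            raise ValueError(f"series {out.values.index[i]!r} constant after masking")
        V[i, m] = (row[m] - row[m].mean()) / sd
    out.values.iloc[:, :] = V
    return out
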