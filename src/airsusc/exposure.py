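"""Regional pollutant exposure and susceptibility cross-classification.

Gridded annual pollutant surfaces (cells pre-mapped to health regions)
are reduced to regional multi-year mean concentrations, regions are
split into quartiles of susceptibility and of concentration, counted
into a 4x4 cross-classification, and "double jeopardy" priority regions
are flagged: highest quartile of susceptibility under either criteria
set and highest quartile of either pollutant.

Quantile convention: thresholds are the linearly interpolated 25th, 50th
and 75th percentiles of the regional values (numpy's default, the
classic type-7 rule). A region is labelled 1 if its value is <= Q25, 2
if <= Q50, 3 if <= Q75, else 4; ties straddling a threshold therefore
all receive the lower label.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SURFACE_COLUMNS = ("cell_id", "region_id", "pollutant", "year", "concentration")


def regional_multiyear_mean(
    surface: pd.DataFrame,
    pollutant: str,
    years: Iterable[int],
    area_weighted: bool = False,
) -> pd.Series:
    """Per-region mean concentration over ``years``.

    Cells are averaged within each year first (area-weighted if an
    ``area_weight`` column is supplied and ``area_weighted=True``), then
    the yearly regional means are averaged. Missing cell-years are an
    input error, not imputed: every region must have >= 1 cell for every
    requested year.
    """
    years = sorted(set(int(y) for y in years))
    sub = surface[surface["pollutant"] == pollutant]
    missing_years = set(years) - set(sub["year"].unique())
    if missing_years:
        raise ValueError(f"years {sorted(missing_years)} absent for {pollutant!r}")
    sub = sub[sub["year"].isin(years)]
    regions = sub["region_id"].unique()
    if area_weighted and "area_weight" in sub.columns:
        w = sub["area_weight"].to_numpy(dtype=float)
        tmp = sub.assign(_wx=w * sub["concentration"].to_numpy(dtype=float), _w=w)
        yearly = tmp.groupby(["region_id", "year"]).agg(sx=("_wx", "sum"), sw=("_w", "sum"))
        yearly = yearly["sx"] / yearly["sw"]
    else:
        yearly = sub.groupby(["region_id", "year"])["concentration"].mean()
    counts = yearly.groupby("region_id").size()
    short = counts[counts < len(years)]
    if not short.empty:
        raise ValueError(
            f"regions missing cell-years for {pollutant!r}: {sorted(short.index)}"
        )
    out = yearly.groupby("region_id").mean()
    out.name = pollutant
    return out.reindex(regions).sort_index()


def assign_quartiles(values: pd.Series) -> pd.Series:
    """Quartile labels 1-4 per region under the fixed quantile convention."""
    v = pd.Series(values).astype(float)
    if len(v) < 4:
        raise ValueError(f"need >= 4 regions to form quartiles, got {len(v)}")
    if v.isna().any():
        raise ValueError("missing values in quartile input")
    arr = v.to_numpy()
    if np.all(arr == arr[0]):
        logger.warning("degenerate quartiles: all %d values identical", len(arr))
        return pd.Series(1, index=v.index, dtype=int)
    q25, q50, q75 = np.quantile(arr, [0.25, 0.5, 0.75])
    labels = 1 + (arr > q25).astype(int) + (arr > q50).astype(int) + (arr > q75).astype(int)
    return pd.Series(labels, index=v.index, dtype=int)


def cross_classify(
    susc_quartiles: pd.Series, pollutant_quartiles: pd.Series
) -> pd.DataFrame:
    """4x4 count table: susceptibility quartile (rows) x pollutant quartile."""
    s, p = pd.Series(susc_quartiles), pd.Series(pollutant_quartiles)
    if set(s.index) != set(p.index):
        raise ValueError("susceptibility and pollutant quartiles cover different regions")
    p = p.reindex(s.index)
    tab = pd.crosstab(s, p)
    tab = tab.reindex(index=range(1, 5), columns=range(1, 5), fill_value=0)
    tab.index.name = "susceptibility_quartile"
    tab.columns.name = "pollutant_quartile"
    return tab


def priority_regions(
    restrictive_q: pd.Series,
    inclusive_q: pd.Series,
    o3_q: pd.Series,
    pm25_q: pd.Series,
) -> pd.DataFrame:
    """Flag double-jeopardy regions.

    A region is a priority region iff it sits in the highest quartile of
    susceptibility under the restrictive OR inclusive criteria AND in the
    highest quartile of O3 OR PM2.5 concentration. The returned frame
    records which disjuncts fired.
    """
    idx = restrictive_q.index
    for other in (inclusive_q, o3_q, pm25_q):
        if set(other.index) != set(idx):
            raise ValueError("quartile labelings cover different regions")
    df = pd.DataFrame(
        {
            "restrictive_high": restrictive_q.reindex(idx) == 4,
            "inclusive_high": inclusive_q.reindex(idx) == 4,
            "o3_high": o3_q.reindex(idx) == 4,
            "pm25_high": pm25_q.reindex(idx) == 4,
        },
        index=idx,
    )
    df["priority"] = (df["restrictive_high"] | df["inclusive_high"]) & (
        df["o3_high"] | df["pm25_high"]
    )
    df.index.name = "region_id"
    return df


def stability_check(
    surface: pd.DataFrame,
    short_years: Iterable[int],
    long_years: Iterable[int],
    pollutants: Sequence[str] | None = None,
    area_weighted: bool = False,
) -> dict[str, float]:
    """Squared Pearson correlation of regional means between two windows.

    Used to confirm that a short (e.g. 3-year) averaging window ranks
    regions the same way as a longer (e.g. 10-year) one.
    """
    if pollutants is None:
        pollutants = sorted(surface["pollutant"].unique())
    out: dict[str, float] = {}
    for pol in pollutants:
        a = regional_multiyear_mean(surface, pol, short_years, area_weighted)
        b = regional_multiyear_mean(surface, pol, long_years, area_weighted)
        b = b.reindex(a.index)
        if len(a) < 3:
            raise ValueError(f"need >= 3 regions for stability check, got {len(a)}")
        r = np.corrcoef(a.to_numpy(), b.to_numpy())[0, 1]
        out[pol] = float(r**2)
    return out
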