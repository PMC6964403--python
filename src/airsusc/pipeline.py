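"""End-to-end analysis: survey + tables + surfaces -> regional results.

Chains the module operations in their natural order: build the
prevalence table, run both criteria cascades per region, reduce the
pollutant surfaces to regional multi-year means, cross-classify
susceptibility against concentration quartiles, flag priority regions,
and compute the standard rank-correlation report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import exposure
from .association import correlation_report
from .cascade import (
    CascadeResult,
    aggregate_regions,
    decompose_to_table,
    run_cascade,
    summarize_factor_percents,
)
from .factors import inclusive_criteria, restrictive_criteria
from .prevalence import GestationDurations, PrevalenceTable, build_prevalence_table
from .strata import make_strata

POLLUTANTS = ("o3", "pm25")


@dataclass
class AnalysisResult:
    """All tables produced by one full pipeline run."""

    prevalence_table: PrevalenceTable
    region_totals: pd.DataFrame          # region_id, restrictive_pct, inclusive_pct
    national: dict[str, float]
    factor_summary: dict[str, pd.DataFrame]   # criteria -> variability table
    exposure_means: pd.DataFrame         # region_id x pollutant
    quartiles: pd.DataFrame              # region_id x labelled quartile columns
    crosstabs: dict[tuple[str, str], pd.DataFrame]  # (criteria, pollutant) -> 4x4
    priority: pd.DataFrame
    correlations: pd.DataFrame
    indicator_frame: pd.DataFrame
    cascades: dict[tuple[str, str], CascadeResult] = field(default_factory=dict)


def run_analysis(
    regions: pd.DataFrame,
    survey: pd.DataFrame,
    supplied: pd.DataFrame,
    pregnancy_inputs: pd.DataFrame,
    surface: pd.DataFrame,
    years: list[int] | None = None,
    durations: GestationDurations = GestationDurations(),
    area_weighted: bool = False,
) -> AnalysisResult:
    """Run the complete analysis.

    ``years`` selects the pollutant averaging window; by default the
    last three years present in the surface (per pollutant).
    """
    restrictive, inclusive = restrictive_criteria(), inclusive_criteria()
    table = build_prevalence_table(
        survey, supplied, pregnancy_inputs, regions, [restrictive, inclusive], durations
    )

    region_ids = list(dict.fromkeys(regions["region_id"]))
    totals_rows, cascades = [], {}
    decomp = {"restrictive": [], "inclusive": []}
    for rid in region_ids:
        sub = regions[regions["region_id"] == rid]
        strata = make_strata(
            dict(zip(sub["stratum"], sub["population"])),
            dict(zip(sub["stratum"], sub["female_fraction"])),
        )
        row = {"region_id": rid, "population": float(sub["population"].sum()),
               "urban_fraction": float(sub["urban_fraction"].iloc[0])}
        for crit in (restrictive, inclusive):
            res = run_cascade(strata, table, crit, rid)
            cascades[(crit.name, rid)] = res
            row[f"{crit.name}_pct"] = res.total_percent
            decomp[crit.name].append(decompose_to_table(res).rename(rid))
        totals_rows.append(row)
    region_totals = pd.DataFrame(totals_rows)
    national = {
        name: aggregate_regions(
            region_totals[f"{name}_pct"], region_totals["population"]
        )
        for name in ("restrictive", "inclusive")
    }
    factor_summary = {
        name: summarize_factor_percents(pd.DataFrame(decomp[name]).rename_axis("region_id"))
        for name in ("restrictive", "inclusive")
    }

    means = {}
    for pol in POLLUTANTS:
        sub = surface[surface["pollutant"] == pol]
        if sub.empty:
            continue
        yrs = years or sorted(sub["year"].unique())[-3:]
        means[pol] = exposure.regional_multiyear_mean(surface, pol, yrs, area_weighted)
    exposure_means = pd.DataFrame(means)

    qframe = pd.DataFrame(index=pd.Index(region_ids, name="region_id"))
    rt = region_totals.set_index("region_id")
    for name in ("restrictive", "inclusive"):
        qframe[f"{name}_q"] = exposure.assign_quartiles(rt[f"{name}_pct"])
    for pol in exposure_means.columns:
        qframe[f"{pol}_q"] = exposure.assign_quartiles(
            exposure_means[pol].reindex(qframe.index)
        )

    crosstabs = {
        (name, pol): exposure.cross_classify(qframe[f"{name}_q"], qframe[f"{pol}_q"])
        for name in ("restrictive", "inclusive")
        for pol in exposure_means.columns
    }
    priority = exposure.priority_regions(
        qframe["restrictive_q"], qframe["inclusive_q"],
        qframe["o3_q"], qframe["pm25_q"],
    )

    indicator = pd.DataFrame(
        {
            "restrictive_pct": rt["restrictive_pct"],
            "inclusive_pct": rt["inclusive_pct"],
            "urban_pct": 100.0 * rt["urban_fraction"],
            "rural_pct": 100.0 * (1.0 - rt["urban_fraction"]),
            "pm25": exposure_means.get("pm25"),
            "o3": exposure_means.get("o3"),
        }
    )
    correlations = correlation_report(indicator)

    return AnalysisResult(
        prevalence_table=table,
        region_totals=region_totals,
        national=national,
        factor_summary=factor_summary,
        exposure_means=exposure_means,
        quartiles=qframe,
        crosstabs=crosstabs,
        priority=priority,
        correlations=correlations,
        indicator_frame=indicator,
        cascades=cascades,
    )
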