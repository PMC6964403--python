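"""Seeded synthetic world generator.

Generates health regions, weighted survey microdata, national prevalence
and pregnancy-event tables, and gridded annual pollutant surfaces that
carry the statistical structure the analysis assumes, so the full
pipeline can be exercised and validated without any external data.

What the generator emulates
---------------------------
* Regional age structures are Dirichlet perturbations of the national
  age shares (one concentration knob, ``region_heterogeneity``; the
  infinite limit reproduces the national shares exactly).
* Region populations are log-normal; urban fractions uniform on a
  configurable interval.
* Regional PM2.5 means increase with the urban fraction through a
  configurable gradient so a positive urbanicity-PM2.5 rank correlation
  is built in; O3 has no urbanicity gradient.
* Survey respondents are sampled with age x urbanicity inclusion rates
  tilted on the log scale by ``weight_dispersion`` (0 = self-weighting,
  equal weights). Weights are the exact design weights N_cell/(n p_cell),
  so weighted margins match the region's population margins in
  expectation.
* Chronic-disease status is drawn as four independent component
  conditions whose union has exactly the configured prevalence, so the
  union estimator is exercised with genuine multimorbidity.
* Risk factors are drawn independently within a respondent (matching the
  downstream independence assumption); a dependence hook is left for
  future work.

Default prevalences, shares and pollutant levels are fixed at values
typical of the Canadian setting this emulates (national restrictive /
inclusive totals near one third / two thirds); see ``docs/methods.md``.
Concentrations are truncated at zero rather than drawn log-normally, for
simplicity.

One global seed fans out to per-stage child seeds by fixed offsets
(regions=1, survey=2, surface=3), so each stage is individually
reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .cascade import run_cascade, aggregate_regions
from .factors import inclusive_criteria, restrictive_criteria
from .prevalence import NATIONAL, GestationDurations, PrevalenceTable
from .strata import CANONICAL_BANDS, STRATUM_LABELS, make_strata

_STAGE_OFFSETS = {"regions": 1, "survey": 2, "surface": 3}

_PROVINCES = ("ON", "QC", "BC", "AB", "MB", "SK", "NS", "NB", "NL", "PE")

DEFAULT_AGE_SHARES: dict[str, float] = {
    "<10": 0.110, "10-14": 0.054, "15": 0.011, "16-19": 0.048,
    "20-24": 0.067, "25-34": 0.135, "35-44": 0.132, "45-64": 0.285,
    "65-74": 0.088, "75+": 0.070,
}

DEFAULT_FEMALE_FRACTIONS: dict[str, float] = {
    "<10": 0.488, "10-14": 0.487, "15": 0.487, "16-19": 0.488,
    "20-24": 0.490, "25-34": 0.500, "35-44": 0.500, "45-64": 0.502,
    "65-74": 0.520, "75+": 0.600,
}

DEFAULT_PREVALENCES: dict[str, dict] = {
    # union prevalence of the four chronic conditions; values outside the
    # 10-74 factor scope are used only to generate realistic microdata
    "chronic_disease": {
        "<10": 0.08, "10-14": 0.10, "15": 0.10, "16-19": 0.10,
        "20-24": 0.09, "25-34": 0.10, "35-44": 0.12, "45-64": 0.19,
        "65-74": 0.33, "75+": 0.45,
    },
    # pregnancy point prevalence among females
    "pregnancy": {
        "15": 0.005, "16-19": 0.015, "20-24": 0.040,
        "25-34": 0.065, "35-44": 0.025, "45-64": 0.001,
    },
    # (urban, rural) outdoor-work prevalence
    "outdoor_work": {
        "16-19": (0.28, 0.42), "20-24": (0.28, 0.42), "25-34": (0.26, 0.40),
        "35-44": (0.24, 0.38), "45-64": (0.20, 0.32), "65-74": (0.10, 0.18),
    },
    "less_than_high_school": {
        "16-19": 0.18, "20-24": 0.10, "25-34": 0.07, "35-44": 0.08,
        "45-64": 0.12, "65-74": 0.21, "75+": 0.30,
    },
    "low_vitamin_c": {
        "10-14": 0.10, "15": 0.10, "16-19": 0.12, "20-24": 0.14,
        "25-34": 0.13, "35-44": 0.13, "45-64": 0.13, "65-74": 0.12,
    },
}

#: factors whose true prevalence gets a regional logit-scale jitter and is
#: then estimated from the survey microdata
SURVEY_FACTORS = ("chronic_disease", "less_than_high_school")


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class PollutantParams:
    """Generation parameters for one pollutant surface.

    ``baseline`` and the noise scales are in the pollutant's unit
    (ug/m3 for PM2.5, ppb for O3). The regional mean is ``baseline +
    urban_gradient * urban_fraction + N(0, regional_sd)``; each grid cell
    adds a fixed spatial offset ``N(0, spatial_sd)`` and each year adds a
    region-wide inter-annual shock ``N(0, interannual_sd)``. Values are
    truncated at zero.
    """

    baseline: float
    urban_gradient: float = 0.0
    regional_sd: float = 1.0
    spatial_sd: float = 0.5
    interannual_sd: float = 0.4
    n_years: int = 3
    last_year: int = 2012
    unit: str = ""

    def __post_init__(self) -> None:
        if self.n_years < 1:
            raise ConfigError("n_years must be >= 1")
        for name in ("regional_sd", "spatial_sd", "interannual_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(range(self.last_year - self.n_years + 1, self.last_year + 1))


def default_pollutants() -> dict[str, PollutantParams]:
    return {
        "pm25": PollutantParams(
            baseline=4.5, urban_gradient=5.0, regional_sd=1.5,
            spatial_sd=0.5, interannual_sd=0.4, unit="ug/m3",
        ),
        "o3": PollutantParams(
            baseline=33.0, urban_gradient=0.0, regional_sd=5.0,
            spatial_sd=1.0, interannual_sd=1.2, unit="ppb",
        ),
    }


@dataclass
class GeneratorConfig:
    """Configuration of the synthetic world.

    ``region_heterogeneity`` is the Dirichlet concentration multiplier
    for regional age shares (> 0; ``inf`` = identical shares).
    ``prevalence_jitter_sd`` is the sd of a logit-scale shift applied per
    region x survey factor (shared across age strata) to create regional
    prevalence spread. ``weight_dispersion`` scales the log-spread of
    sampling inclusion rates across age x urbanicity cells (approximately
    the coefficient of variation of the weights; 0 = equal weights).
    """

    n_regions: int = 110
    n_respondents_per_region: int = 2000
    seed: int = 0
    national_age_shares: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AGE_SHARES)
    )
    female_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FEMALE_FRACTIONS)
    )
    prevalence_params: dict[str, dict] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_PREVALENCES.items()}
    )
    region_heterogeneity: float = 150.0
    prevalence_jitter_sd: float = 0.15
    weight_dispersion: float = 0.4
    urban_fraction_range: tuple[float, float] = (0.10, 1.0)
    pollutant_params: dict[str, PollutantParams] = field(
        default_factory=default_pollutants
    )
    cells_per_region: int = 4
    missing_rate: float = 0.02
    population_log_mean: float = math.log(165_000.0)
    population_log_sd: float = 0.9
    population_min: float = 10_000.0
    gestation: GestationDurations = field(default_factory=GestationDurations)

    def __post_init__(self) -> None:
        if self.n_regions < 4:
            raise ConfigError("n_regions must be >= 4 (quartiles must be possible)")
        if self.n_respondents_per_region < 1:
            raise ConfigError("n_respondents_per_region must be >= 1")
        shares = self.national_age_shares
        if set(shares) != set(STRATUM_LABELS):
            raise ConfigError("national_age_shares must cover the ten canonical strata")
        if any(v < 0 for v in shares.values()):
            raise ConfigError("age shares must be >= 0")
        if abs(sum(shares.values()) - 1.0) > 1e-9:
            raise ConfigError("national_age_shares must sum to 1 within 1e-9")
        if not self.region_heterogeneity > 0:
            raise ConfigError("region_heterogeneity must be > 0")
        if self.weight_dispersion < 0:
            raise ConfigError("weight_dispersion must be >= 0")
        lo, hi = self.urban_fraction_range
        if not (0 <= lo <= hi <= 1):
            raise ConfigError("urban_fraction_range must be an interval within [0, 1]")
        for factor, per_stratum in self.prevalence_params.items():
            for stratum, v in per_stratum.items():
                vals = v if isinstance(v, (tuple, list)) else (v,)
                if any(not 0 <= x <= 1 for x in vals):
                    raise ConfigError(
                        f"prevalence outside [0,1]: {factor}/{stratum} = {v}"
                    )
        if self.cells_per_region < 1:
            raise ConfigError("cells_per_region must be >= 1")
        if not 0 <= self.missing_rate < 1:
            raise ConfigError("missing_rate must be in [0, 1)")

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng([_STAGE_OFFSETS[stage], int(self.seed)])


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated world.

    ``prevalence`` holds the true cascade-ready prevalence per (region,
    stratum, factor) — pregnancy already stratum-wide. ``regional_totals``
    holds the true restrictive/inclusive percents per region, obtained by
    running the cascade on the true prevalences (self-consistent by
    construction). ``national`` is the population-weighted aggregate.
    """

    prevalence: pd.DataFrame
    regional_totals: pd.DataFrame
    national: dict[str, float]

    def prevalence_table(self) -> PrevalenceTable:
        table = PrevalenceTable()
        for row in self.prevalence.itertuples(index=False):
            table.set(
                row.factor, row.stratum, float(row.value),
                scope=row.region_id, provenance="truth",
            )
        return table


@dataclass
class SyntheticWorld:
    """All artifacts of one generated world, in the pipeline's CSV dialects."""

    config: GeneratorConfig
    regions: pd.DataFrame        # long: region_id,name,province,stratum,...
    region_attrs: pd.DataFrame   # wide per-region incl. true pollutant means
    truth: SyntheticTruth
    survey: pd.DataFrame
    supplied: pd.DataFrame
    pregnancy: pd.DataFrame
    surface: pd.DataFrame


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def generate_regions(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate regions (long + wide frames) and the ground truth."""
    rng = config.rng("regions")
    R = config.n_regions
    shares_nat = np.array([config.national_age_shares[s] for s in STRATUM_LABELS])

    pop = np.exp(rng.normal(config.population_log_mean, config.population_log_sd, R))
    pop = np.maximum(pop, config.population_min).round()
    if math.isinf(config.region_heterogeneity):
        shares = np.tile(shares_nat, (R, 1))
    else:
        shares = rng.dirichlet(config.region_heterogeneity * shares_nat, size=R)
    lo, hi = config.urban_fraction_range
    urban = rng.uniform(lo, hi, R)

    ids = [f"HR{i + 1:03d}" for i in range(R)]
    long_rows = []
    for i, rid in enumerate(ids):
        for j, stratum in enumerate(STRATUM_LABELS):
            long_rows.append(
                {
                    "region_id": rid,
                    "name": f"Synthetic Region {i + 1}",
                    "province": _PROVINCES[i % len(_PROVINCES)],
                    "stratum": stratum,
                    "population": float(np.round(pop[i] * shares[i, j])),
                    "female_fraction": config.female_fractions[stratum],
                    "urban_fraction": urban[i],
                }
            )
    regions = pd.DataFrame(long_rows)

    # true regional pollutant means (urban gradient applies to each pollutant
    # through its own coefficient; zero for O3 by default)
    attrs = pd.DataFrame(
        {
            "region_id": ids,
            "name": [f"Synthetic Region {i + 1}" for i in range(R)],
            "province": [_PROVINCES[i % len(_PROVINCES)] for i in range(R)],
            "population": regions.groupby("region_id", sort=False)["population"]
            .sum()
            .to_numpy(),
            "urban_fraction": urban,
        }
    )
    for pol, pp in config.pollutant_params.items():
        mean = pp.baseline + pp.urban_gradient * urban + rng.normal(0, pp.regional_sd, R)
        attrs[f"{pol}_mean"] = np.maximum(mean, 0.0)

    # true prevalences: survey factors get a shared logit shift per
    # region x factor; outdoor work is mixed with the urban fraction;
    # vitamin C is national; pregnancy is converted stratum-wide
    truth_rows = []
    for fi, factor in enumerate(SURVEY_FACTORS):
        base = config.prevalence_params[factor]
        shifts = rng.normal(0.0, config.prevalence_jitter_sd, R)
        for i, rid in enumerate(ids):
            for stratum, p in base.items():
                if p <= 0.0 or p >= 1.0:
                    value = float(p)
                else:
                    value = float(_sigmoid(_logit(p) + shifts[i]))
                truth_rows.append(
                    {"region_id": rid, "stratum": stratum, "factor": factor,
                     "value": value}
                )
    for i, rid in enumerate(ids):
        for stratum, (pu, pr) in config.prevalence_params["outdoor_work"].items():
            truth_rows.append(
                {
                    "region_id": rid, "stratum": stratum, "factor": "outdoor_work",
                    "value": urban[i] * pu + (1 - urban[i]) * pr,
                }
            )
        for stratum, rate in config.prevalence_params["pregnancy"].items():
            truth_rows.append(
                {
                    "region_id": rid, "stratum": stratum, "factor": "pregnancy",
                    "value": rate * config.female_fractions[stratum],
                }
            )
        for stratum, p in config.prevalence_params["low_vitamin_c"].items():
            truth_rows.append(
                {"region_id": rid, "stratum": stratum, "factor": "low_vitamin_c",
                 "value": float(p)}
            )
    truth_prev = pd.DataFrame(truth_rows)

    truth = SyntheticTruth(truth_prev, pd.DataFrame(), {})
    table = truth.prevalence_table()
    restrictive, inclusive = restrictive_criteria(), inclusive_criteria()
    totals = []
    for rid in ids:
        sub = regions[regions["region_id"] == rid]
        strata = make_strata(
            dict(zip(sub["stratum"], sub["population"])),
            dict(zip(sub["stratum"], sub["female_fraction"])),
        )
        totals.append(
            {
                "region_id": rid,
                "restrictive_pct": run_cascade(strata, table, restrictive, rid).total_percent,
                "inclusive_pct": run_cascade(strata, table, inclusive, rid).total_percent,
            }
        )
    truth.regional_totals = pd.DataFrame(totals)
    pops = attrs["population"].to_numpy()
    truth.national = {
        "restrictive_pct": aggregate_regions(
            truth.regional_totals["restrictive_pct"], pops
        ),
        "inclusive_pct": aggregate_regions(
            truth.regional_totals["inclusive_pct"], pops
        ),
    }
    return regions, attrs, truth


# standardized log-tilt pattern over age index and urbanicity; unit scale so
# weight_dispersion is approximately the CV of the resulting weights
_AGE_Z = (np.arange(10) - 4.5) / math.sqrt(8.25)
_TILT_AGE = 1.0 / math.sqrt(2.0)
_TILT_RURAL = 1.0 / math.sqrt(2.0)


def generate_survey(
    regions: pd.DataFrame, truth: SyntheticTruth, config: GeneratorConfig
) -> pd.DataFrame:
    """Draw weighted survey microdata from the true prevalences.

    Respondents are drawn per region from age x urbanicity cells with
    inclusion rates tilted by ``weight_dispersion`` (rural and older
    cells oversampled); the recorded weight is the design weight
    N_cell / (n p_cell). Indicators are Bernoulli draws from the regional
    truth, with MCAR missingness at ``missing_rate``.
    """
    rng = config.rng("survey")
    n = config.n_respondents_per_region
    prev = truth.prevalence.set_index(["region_id", "factor", "stratum"])["value"]
    bounds = {label: (lo, hi) for label, lo, hi in CANONICAL_BANDS}
    frames = []
    for rid, sub in regions.groupby("region_id", sort=False):
        sub = sub.set_index("stratum").reindex(list(STRATUM_LABELS))
        pop_a = sub["population"].to_numpy(dtype=float)
        uf = float(sub["urban_fraction"].iloc[0])
        # cells: (stratum index, urbanicity) with urbanicity 0=urban, 1=rural
        N_cell = np.concatenate([pop_a * uf, pop_a * (1.0 - uf)])
        eta = np.concatenate(
            [
                _TILT_AGE * _AGE_Z - _TILT_RURAL,
                _TILT_AGE * _AGE_Z + _TILT_RURAL,
            ]
        )
        tilt = np.exp(config.weight_dispersion * eta)
        rate = N_cell * tilt
        p_cell = rate / rate.sum()
        cell = rng.choice(len(p_cell), size=n, p=p_cell)
        # design weight N_cell/(n p_cell) written so equal tilts give
        # bit-identical weights
        w_cell = rate.sum() / (n * tilt)
        a_idx = cell % 10
        rural = cell >= 10
        labels = np.array(STRATUM_LABELS, dtype=object)[a_idx]

        lo_arr = np.array([bounds[s][0] for s in STRATUM_LABELS])
        hi_arr = np.array(
            [min(bounds[s][1], 95) for s in STRATUM_LABELS], dtype=float
        )
        ages = rng.integers(lo_arr[a_idx], hi_arr[a_idx].astype(int))
        ff = sub["female_fraction"].to_numpy(dtype=float)[a_idx]
        female = rng.random(n) < ff

        def regional_p(factor: str) -> np.ndarray:
            out = np.zeros(10)
            for j, s in enumerate(STRATUM_LABELS):
                out[j] = prev.get((rid, factor, s), 0.0)
            return out

        p_chronic = regional_p("chronic_disease")[a_idx]
        # four independent components whose union prevalence is exact
        q_comp = 1.0 - (1.0 - p_chronic) ** 0.25
        data = {
            "region_id": rid,
            "age": ages,
            "sex": np.where(female, "female", "male"),
            "urbanicity": np.where(rural, "rural", "urban"),
            "weight": w_cell[cell],
        }
        for comp in ("asthma", "copd", "heart_disease", "diabetes"):
            data[comp] = (rng.random(n) < q_comp).astype(float)
        p_educ = regional_p("less_than_high_school")[a_idx]
        educ = (rng.random(n) < p_educ).astype(float)
        # education is not asked below age 16
        educ[np.isin(labels, ("<10", "10-14", "15"))] = np.nan
        data["less_than_hs"] = educ
        frame = pd.DataFrame(data)
        if config.missing_rate > 0:
            for col in ("asthma", "copd", "heart_disease", "diabetes", "less_than_hs"):
                mask = rng.random(n) < config.missing_rate
                frame.loc[mask, col] = np.nan
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def supplied_prevalence_table(config: GeneratorConfig) -> pd.DataFrame:
    """National supplied tables (outdoor work by urbanicity, low vitamin C)."""
    rows = []
    for stratum, (pu, pr) in config.prevalence_params["outdoor_work"].items():
        rows.append({"scope": NATIONAL, "stratum": stratum, "factor": "outdoor_work",
                     "urbanicity": "urban", "value": pu})
        rows.append({"scope": NATIONAL, "stratum": stratum, "factor": "outdoor_work",
                     "urbanicity": "rural", "value": pr})
    for stratum, p in config.prevalence_params["low_vitamin_c"].items():
        rows.append({"scope": NATIONAL, "stratum": stratum, "factor": "low_vitamin_c",
                     "urbanicity": "", "value": p})
    return pd.DataFrame(rows, columns=["scope", "stratum", "factor", "urbanicity", "value"])


def pregnancy_event_table(
    regions: pd.DataFrame, config: GeneratorConfig
) -> pd.DataFrame:
    """National annual pregnancy-outcome counts consistent with the truth.

    Outcome counts are split 80/10/10 (births / fetal losses / induced
    abortions) of the expected concurrent pregnancies and back-converted
    through the gestational durations, so the point-prevalence operation
    recovers the configured rates exactly. Counts are real-valued for
    that reason.
    """
    d = config.gestation
    fpop = (
        regions.assign(
            f=regions["population"].to_numpy() * regions["female_fraction"].to_numpy()
        )
        .groupby("stratum")["f"]
        .sum()
    )
    rows = []
    for stratum in STRATUM_LABELS:
        rate = config.prevalence_params["pregnancy"].get(stratum, 0.0)
        pop = float(fpop.get(stratum, 0.0))
        point = rate * pop
        rows.append(
            {
                "stratum": stratum,
                "live_births": 0.8 * point / d.live_birth,
                "fetal_losses": 0.1 * point / d.fetal_loss,
                "induced_abortions": 0.1 * point / d.induced_abortion,
                "female_population": pop,
            }
        )
    return pd.DataFrame(rows)


def generate_pollutant_surface(
    region_attrs: pd.DataFrame, config: GeneratorConfig
) -> pd.DataFrame:
    """Gridded annual concentrations with a cell-to-region map.

    Each region owns ``cells_per_region`` cells per pollutant; cell-year
    values are regional mean + fixed spatial cell offset + region-wide
    inter-annual shock, truncated at zero.
    """
    rng = config.rng("surface")
    rows = []
    for pol, pp in config.pollutant_params.items():
        col = f"{pol}_mean"
        if col not in region_attrs.columns:
            raise ValueError(f"region_attrs lacks true means for pollutant {pol!r}")
        years = pp.years
        for _, reg in region_attrs.iterrows():
            n_cells = config.cells_per_region
            if n_cells < 1:
                raise RuntimeError(f"region {reg['region_id']} has zero grid cells")
            spatial = rng.normal(0.0, pp.spatial_sd, n_cells)
            annual = rng.normal(0.0, pp.interannual_sd, len(years))
            for ci in range(n_cells):
                for yi, year in enumerate(years):
                    value = max(reg[col] + spatial[ci] + annual[yi], 0.0)
                    rows.append(
                        {
                            "cell_id": f"{reg['region_id']}_c{ci}",
                            "region_id": reg["region_id"],
                            "pollutant": pol,
                            "year": year,
                            "concentration": value,
                        }
                    )
    surface = pd.DataFrame(rows, columns=list(SURFACE_COLUMNS_OUT))
    for pol in config.pollutant_params:
        per_region = surface[surface["pollutant"] == pol]["region_id"].unique()
        missing = set(region_attrs["region_id"]) - set(per_region)
        if missing:
            raise RuntimeError(f"regions with zero cells for {pol!r}: {sorted(missing)}")
    return surface


SURFACE_COLUMNS_OUT = ("cell_id", "region_id", "pollutant", "year", "concentration")


def generate_world(config: GeneratorConfig | None = None) -> SyntheticWorld:
    """Generate the complete synthetic world for one config."""
    config = config or GeneratorConfig()
    regions, attrs, truth = generate_regions(config)
    survey = generate_survey(regions, truth, config)
    supplied = supplied_prevalence_table(config)
    pregnancy = pregnancy_event_table(regions, config)
    surface = generate_pollutant_surface(attrs, config)
    return SyntheticWorld(config, regions, attrs, truth, survey, supplied, pregnancy, surface)


def config_to_dict(config: GeneratorConfig) -> dict:
    """Plain-dict form of a config (YAML-serializable)."""
    d = asdict(config)
    d["urban_fraction_range"] = list(config.urban_fraction_range)
    d["pollutant_params"] = {k: asdict(v) for k, v in config.pollutant_params.items()}
    d["gestation"] = asdict(config.gestation)
    return d


def config_from_dict(d: Mapping) -> GeneratorConfig:
    d = dict(d)
    if "urban_fraction_range" in d:
        d["urban_fraction_range"] = tuple(d["urban_fraction_range"])
    if "pollutant_params" in d:
        d["pollutant_params"] = {
            k: v if isinstance(v, PollutantParams) else PollutantParams(**v)
            for k, v in d["pollutant_params"].items()
        }
    if "gestation" in d and not isinstance(d["gestation"], GestationDurations):
        d["gestation"] = GestationDurations(**d["gestation"])
    return GeneratorConfig(**d)
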