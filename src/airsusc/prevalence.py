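"""Prevalence inputs to the susceptibility cascade.

Three kinds of prevalence feed the cascade:

* **survey-estimated** — chronic disease (union of asthma, COPD, heart
  disease, diabetes) and less-than-high-school education, estimated from
  weighted survey microdata per region and age stratum;
* **supplied** — national age-specific tables for factors not collected
  in the survey (low vitamin C intake; outdoor work by age and
  urban/rural residence, which is then mixed with each region's urban
  fraction);
* **derived** — pregnancy point prevalence computed from annual outcome
  counts (live births, fetal losses, induced abortions) times average
  gestational durations, divided by the female population, then scaled
  by each stratum's female fraction to a stratum-wide value.

Survey estimation is complete-case per indicator: respondents missing an
indicator are dropped from that indicator's numerator and denominator;
for the chronic-disease union, respondents missing any of the four
component indicators are dropped from the union estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .factors import CriteriaSet, FactorSpec
from .strata import STRATUM_LABELS, stratum_for_age

NATIONAL = "NATIONAL"

#: component indicators whose union defines the chronic-disease factor
CHRONIC_COMPONENTS = ("asthma", "copd", "heart_disease", "diabetes")

SURVEY_COLUMNS = (
    "region_id",
    "age",
    "sex",
    "urbanicity",
    "weight",
    "asthma",
    "copd",
    "heart_disease",
    "diabetes",
    "less_than_hs",
)


class EmptyDomainError(ValueError):
    """No respondents in the requested estimation domain."""


class PrevalenceConfigError(ValueError):
    """A factor required by a criteria set cannot be resolved."""


@dataclass(frozen=True)
class GestationDurations:
    """Average time (years) a pregnancy ending in each outcome contributes.

    These are configuration, not constants: typical worksheet values are
    40/52 year for live births, 11/52 for fetal losses and 10/52 for
    induced abortions.
    """

    live_birth: float = 40 / 52
    fetal_loss: float = 11 / 52
    induced_abortion: float = 10 / 52

    def __post_init__(self) -> None:
        for name in ("live_birth", "fetal_loss", "induced_abortion"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"gestation duration {name}={v} outside (0, 1]")


class PrevalenceTable:
    """Prevalences keyed by (scope, stratum, factor) with provenance.

    ``scope`` is a region id or :data:`NATIONAL`; lookups fall back from
    the region to the national entry. All values are fractions in [0, 1].
    """

    def __init__(self) -> None:
        self._entries: dict[tuple[str, str, str], tuple[float, str]] = {}

    def set(
        self,
        factor: str,
        stratum: str,
        value: float,
        scope: str = NATIONAL,
        provenance: str = "supplied",
    ) -> None:
        if not 0.0 <= value <= 1.0:
            raise ValueError(
                f"prevalence outside [0,1]: {factor}/{stratum}/{scope} = {value}"
            )
        if stratum not in STRATUM_LABELS:
            raise ValueError(f"unknown stratum {stratum!r}")
        self._entries[(scope, stratum, factor)] = (float(value), provenance)

    def has(self, factor: str, stratum: str, region: str | None = None) -> bool:
        if region is not None and (region, stratum, factor) in self._entries:
            return True
        return (NATIONAL, stratum, factor) in self._entries

    def get(self, factor: str, stratum: str, region: str | None = None) -> float:
        if region is not None:
            hit = self._entries.get((region, stratum, factor))
            if hit is not None:
                return hit[0]
        hit = self._entries.get((NATIONAL, stratum, factor))
        if hit is None:
            raise KeyError(
                f"no prevalence for factor={factor!r}, stratum={stratum!r}, "
                f"region={region!r} (and no national fallback)"
            )
        return hit[0]

    def __len__(self) -> int:
        return len(self._entries)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"scope": k[0], "stratum": k[1], "factor": k[2], "value": v, "provenance": p}
            for k, (v, p) in sorted(self._entries.items())
        ]
        return pd.DataFrame(
            rows, columns=["scope", "stratum", "factor", "value", "provenance"]
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PrevalenceTable":
        table = cls()
        for row in frame.itertuples(index=False):
            table.set(
                row.factor,
                row.stratum,
                float(row.value),
                scope=row.scope,
                provenance=getattr(row, "provenance", "supplied"),
            )
        return table

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PrevalenceTable":
        return cls.from_frame(pd.read_csv(path, dtype={"scope": str, "stratum": str}))


def attach_stratum(survey: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of ``survey`` with a ``stratum`` column derived from age."""
    out = survey.copy()
    out["stratum"] = [stratum_for_age(a) for a in out["age"].to_numpy()]
    return out


def weighted_prevalence(
    records: pd.DataFrame,
    indicator: str,
    where: pd.Series | np.ndarray | None = None,
) -> float:
    """Survey-weighted prevalence Σ wᵢxᵢ / Σ wᵢ of a binary indicator.

    Respondents with a missing indicator are excluded from both numerator
    and denominator. ``where`` optionally restricts the domain (boolean
    mask aligned with ``records``). Raises :class:`EmptyDomainError` if no
    respondent in the domain has a non-missing indicator — never a silent 0.
    """
    sub = records if where is None else records.loc[np.asarray(where, dtype=bool)]
    x = pd.to_numeric(sub[indicator], errors="coerce")
    ok = x.notna()
    if not ok.any():
        raise EmptyDomainError(f"no respondents with non-missing {indicator!r} in domain")
    w = sub.loc[ok, "weight"].to_numpy(dtype=float)
    if np.any(w <= 0):
        raise ValueError("non-positive survey weight in domain")
    xv = x[ok].to_numpy(dtype=float)
    if not np.isin(xv, (0.0, 1.0)).all():
        raise ValueError(f"indicator {indicator!r} has non-binary values")
    return float(np.dot(w, xv) / w.sum())


def _chronic_union(records: pd.DataFrame) -> pd.Series:
    """Union indicator of the four chronic conditions, NaN if any is missing.

    The union is formed per respondent before weighting, so joint presence
    of several conditions counts once.
    """
    comp = records[list(CHRONIC_COMPONENTS)].apply(pd.to_numeric, errors="coerce")
    union = comp.max(axis=1)
    union[comp.isna().any(axis=1)] = np.nan
    return union


def chronic_disease_prevalence(
    records: pd.DataFrame, region: str | None = None, stratum: str | None = None
) -> float:
    """Weighted prevalence of having >= 1 of the four chronic conditions."""
    sub = records
    if region is not None:
        sub = sub[sub["region_id"] == region]
    if stratum is not None:
        if "stratum" not in sub.columns:
            sub = attach_stratum(sub)
        sub = sub[sub["stratum"] == stratum]
    sub = sub.assign(_union=_chronic_union(sub))
    return weighted_prevalence(sub, "_union")


def pregnancy_point_prevalence(
    inputs: pd.DataFrame, durations: GestationDurations = GestationDurations()
) -> pd.Series:
    """Point prevalence of pregnancy among females, per age stratum.

    ``inputs`` has columns ``stratum, live_births, fetal_losses,
    induced_abortions, female_population`` (annual counts). The expected
    number of concurrently pregnant women is each annual outcome count
    times its average gestational duration; dividing by the female
    population gives the point prevalence. Strata absent from ``inputs``
    are treated as zero by callers.
    """
    df = inputs.set_index("stratum")
    counts = df[["live_births", "fetal_losses", "induced_abortions"]].to_numpy(float)
    if (counts < 0).any():
        raise ValueError("negative annual counts in pregnancy inputs")
    d = np.array(
        [durations.live_birth, durations.fetal_loss, durations.induced_abortion]
    )
    point = counts @ d
    pop = df["female_population"].to_numpy(float)
    if np.any((point > 0) & (pop <= 0)):
        raise ValueError("pregnancy events in a stratum with no female population")
    with np.errstate(invalid="ignore", divide="ignore"):
        prev = np.where(pop > 0, point / np.where(pop > 0, pop, 1.0), 0.0)
    if (prev > 1).any():
        bad = df.index[prev > 1].tolist()
        raise ValueError(f"pregnancy prevalence > 1 in strata {bad}: counts inconsistent")
    return pd.Series(prev, index=df.index, name="pregnancy_prevalence")


def effective_pregnancy_prevalence(
    preg_among_females: float, female_fraction: float
) -> float:
    """Stratum-wide pregnancy prevalence: rate among females x female fraction."""
    for name, v in (
        ("preg_among_females", preg_among_females),
        ("female_fraction", female_fraction),
    ):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    return preg_among_females * female_fraction


def urbanicity_adjusted_prevalence(
    p_urban: float, p_rural: float, urban_fraction: float
) -> float:
    """Mix urban and rural prevalences by a region's urban population share."""
    for name, v in (
        ("p_urban", p_urban),
        ("p_rural", p_rural),
        ("urban_fraction", urban_fraction),
    ):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    return urban_fraction * p_urban + (1.0 - urban_fraction) * p_rural


def _grouped_weighted_prevalence(
    records: pd.DataFrame, values: pd.Series
) -> pd.DataFrame:
    """Weighted prevalence of ``values`` by (region_id, stratum), complete-case.

    Returns a frame indexed by (region_id, stratum) with columns ``value``
    and ``n`` (respondent count), plus the national pooled estimate per
    stratum accessible separately by grouping on stratum alone.
    """
    ok = values.notna()
    sub = records.loc[ok, ["region_id", "stratum", "weight"]].copy()
    sub["wx"] = sub["weight"].to_numpy() * values[ok].to_numpy(dtype=float)
    g = sub.groupby(["region_id", "stratum"], sort=False).agg(
        sw=("weight", "sum"), swx=("wx", "sum"), n=("weight", "size")
    )
    g["value"] = g["swx"] / g["sw"]
    return g[["value", "n"]]


def build_prevalence_table(
    survey: pd.DataFrame,
    supplied: pd.DataFrame,
    pregnancy_inputs: pd.DataFrame,
    regions: pd.DataFrame,
    criteria: CriteriaSet | Sequence[CriteriaSet],
    durations: GestationDurations = GestationDurations(),
) -> PrevalenceTable:
    """Assemble the full prevalence table required by one or more criteria sets.

    Parameters
    ----------
    survey : DataFrame
        Microdata with :data:`SURVEY_COLUMNS` (empty cell = missing).
    supplied : DataFrame
        National tables with columns ``scope, stratum, factor, urbanicity,
        value`` — outdoor work carries ``urban``/``rural`` rows, low
        vitamin C has blank urbanicity.
    pregnancy_inputs : DataFrame
        Annual event counts per stratum (see
        :func:`pregnancy_point_prevalence`).
    regions : DataFrame
        Long region table ``region_id, stratum, population,
        female_fraction, urban_fraction``.
    criteria : CriteriaSet or sequence thereof
        Every non-wholesale factor in these sets is resolved.

    Survey factors are estimated per region x stratum; if a region x
    stratum domain has no usable respondents the national pooled estimate
    is used, tagged ``survey-national-fallback``. National-only factors
    are stored at national scope (low vitamin C) or mixed into per-region
    values with the region's urban fraction (outdoor work). Pregnancy is
    converted stratum-wide with each region's female fraction.
    """
    crit_list = [criteria] if isinstance(criteria, CriteriaSet) else list(criteria)
    factors: dict[str, FactorSpec] = {}
    for cs in crit_list:
        for f in cs.factors:
            if not f.wholesale:
                factors.setdefault(f.name, f)

    if "stratum" not in survey.columns:
        survey = attach_stratum(survey)
    table = PrevalenceTable()
    region_ids = list(dict.fromkeys(regions["region_id"]))
    reg = regions.set_index(["region_id", "stratum"])
    missing_pairs: list[tuple[str, str]] = []

    def survey_factor(spec: FactorSpec, values: pd.Series) -> None:
        per_region = _grouped_weighted_prevalence(survey, values)
        ok = values.notna()
        sub = survey.loc[ok, ["stratum", "weight"]].copy()
        sub["wx"] = sub["weight"].to_numpy() * values[ok].to_numpy(dtype=float)
        nat = sub.groupby("stratum").agg(sw=("weight", "sum"), swx=("wx", "sum"))
        nat["value"] = nat["swx"] / nat["sw"]
        for stratum in sorted(spec.age_scope):
            if stratum in nat.index:
                table.set(
                    spec.prevalence_ref,
                    stratum,
                    float(np.clip(nat.loc[stratum, "value"], 0, 1)),
                    scope=NATIONAL,
                    provenance="survey-estimated",
                )
            for rid in region_ids:
                key = (rid, stratum)
                if key in per_region.index:
                    table.set(
                        spec.prevalence_ref,
                        stratum,
                        float(np.clip(per_region.loc[key, "value"], 0, 1)),
                        scope=rid,
                        provenance="survey-estimated",
                    )
                elif stratum in nat.index:
                    table.set(
                        spec.prevalence_ref,
                        stratum,
                        float(np.clip(nat.loc[stratum, "value"], 0, 1)),
                        scope=rid,
                        provenance="survey-national-fallback",
                    )
                else:
                    missing_pairs.append((spec.name, stratum))

    for name, spec in factors.items():
        if name == "chronic_disease":
            survey_factor(spec, _chronic_union(survey))
        elif name == "less_than_high_school":
            survey_factor(spec, pd.to_numeric(survey["less_than_hs"], errors="coerce"))
        elif name == "pregnancy":
            rates = pregnancy_point_prevalence(pregnancy_inputs, durations)
            for rid in region_ids:
                for stratum in sorted(spec.age_scope):
                    rate = float(rates.get(stratum, 0.0))
                    try:
                        ff = float(reg.loc[(rid, stratum), "female_fraction"])
                    except KeyError:
                        missing_pairs.append((name, stratum))
                        continue
                    table.set(
                        spec.prevalence_ref,
                        stratum,
                        effective_pregnancy_prevalence(rate, ff),
                        scope=rid,
                        provenance="derived",
                    )
        elif name == "outdoor_work":
            rows = supplied[supplied["factor"] == name]
            for stratum in sorted(spec.age_scope):
                srow = rows[rows["stratum"] == stratum]
                pu = srow.loc[srow["urbanicity"] == "urban", "value"]
                pr = srow.loc[srow["urbanicity"] == "rural", "value"]
                if pu.empty or pr.empty:
                    missing_pairs.append((name, stratum))
                    continue
                for rid in region_ids:
                    uf = float(reg.loc[(rid, stratum), "urban_fraction"])
                    table.set(
                        spec.prevalence_ref,
                        stratum,
                        urbanicity_adjusted_prevalence(
                            float(pu.iloc[0]), float(pr.iloc[0]), uf
                        ),
                        scope=rid,
                        provenance="derived",
                    )
        else:
            # national age-specific table broadcast to all regions
            rows = supplied[supplied["factor"] == spec.prevalence_ref]
            for stratum in sorted(spec.age_scope):
                srow = rows[rows["stratum"] == stratum]
                if srow.empty:
                    missing_pairs.append((name, stratum))
                    continue
                table.set(
                    spec.prevalence_ref,
                    stratum,
                    float(srow["value"].iloc[0]),
                    scope=NATIONAL,
                    provenance="supplied",
                )

    if missing_pairs:
        raise PrevalenceConfigError(
            "unresolvable (factor, stratum) pairs: " + repr(sorted(set(missing_pairs)))
        )
    return table
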