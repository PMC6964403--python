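"""Susceptibility risk factors and the restrictive/inclusive criteria sets.

A :class:`FactorSpec` describes one risk factor: its position in the
cascade, the age bands it applies to, whether it applies to females only
(via the stratum female fraction), and whether it is *wholesale* — an
entire age band counted as susceptible with prevalence 1 (e.g. age < 10).

Two named criteria sets are frozen as presets:

* ``restrictive`` — age < 10, age 75+, chronic disease (asthma, COPD,
  heart disease or diabetes, ages 10-74), and pregnancy.
* ``inclusive`` — the restrictive factors plus outdoor work, less than
  high-school education, low vitamin C intake, and a final wholesale
  "remainder" factor that sweeps up everyone aged 10-19 or 65-74 not
  already flagged (so that the inclusive age criteria, < 20 and 65+, are
  met while the decomposition still reports the earlier factors'
  contributions within those bands).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .strata import STRATUM_LABELS

# Commonly used scope shorthands.
_ALL = frozenset(STRATUM_LABELS)
_AGES_10_74 = frozenset(
    ("10-14", "15", "16-19", "20-24", "25-34", "35-44", "45-64", "65-74")
)


@dataclass(frozen=True)
class FactorSpec:
    """One risk factor in a cascade.

    ``prevalence_ref`` is the key under which the factor's prevalence is
    looked up in a :class:`~airsusc.prevalence.PrevalenceTable`; wholesale
    factors need no lookup (prevalence is 1 on scope, 0 off scope).
    ``sex_scope`` is ``"all"`` or ``"female"``; female-scoped prevalences
    are stored already converted to stratum-wide values (rate among
    females times the stratum female fraction).
    """

    name: str
    order_index: int
    age_scope: frozenset[str] = field(default=_ALL)
    sex_scope: str = "all"
    wholesale: bool = False
    prevalence_ref: str = ""

    def __post_init__(self) -> None:
        unknown = self.age_scope - set(STRATUM_LABELS)
        if unknown:
            raise ValueError(f"factor {self.name}: unknown strata {sorted(unknown)}")
        if self.sex_scope not in ("all", "female"):
            raise ValueError(f"factor {self.name}: bad sex_scope {self.sex_scope!r}")
        if not self.wholesale and not self.prevalence_ref:
            object.__setattr__(self, "prevalence_ref", self.name)


@dataclass(frozen=True)
class CriteriaSet:
    """An ordered, named collection of risk factors."""

    name: str
    factors: tuple[FactorSpec, ...]

    def __post_init__(self) -> None:
        idx = [f.order_index for f in self.factors]
        if sorted(idx) != list(range(len(idx))):
            raise ValueError(
                f"criteria {self.name}: order indices must be 0..{len(idx) - 1}, got {idx}"
            )
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise ValueError(f"criteria {self.name}: duplicate factor names")

    @property
    def factor_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factors)


AGE_LT_10 = FactorSpec("age_lt_10", 0, frozenset({"<10"}), wholesale=True)
AGE_GE_75 = FactorSpec("age_ge_75", 1, frozenset({"75+"}), wholesale=True)
CHRONIC_DISEASE = FactorSpec("chronic_disease", 2, _AGES_10_74)
PREGNANCY = FactorSpec(
    "pregnancy",
    3,
    frozenset(("15", "16-19", "20-24", "25-34", "35-44", "45-64")),
    sex_scope="female",
)
OUTDOOR_WORK = FactorSpec(
    "outdoor_work",
    4,
    frozenset(("16-19", "20-24", "25-34", "35-44", "45-64", "65-74")),
)
LOW_EDUCATION = FactorSpec(
    "less_than_high_school",
    5,
    frozenset(("20-24", "25-34", "35-44", "45-64", "65-74")),
)
LOW_VITAMIN_C = FactorSpec("low_vitamin_c", 6, _AGES_10_74)
REMAINDER_10_19_65_74 = FactorSpec(
    "remainder_10_19_65_74",
    7,
    frozenset(("10-14", "15", "16-19", "65-74")),
    wholesale=True,
)


def restrictive_criteria() -> CriteriaSet:
    """The four-factor restrictive preset."""
    return CriteriaSet(
        "restrictive", (AGE_LT_10, AGE_GE_75, CHRONIC_DISEASE, PREGNANCY)
    )


def inclusive_criteria() -> CriteriaSet:
    """The eight-factor inclusive preset (restrictive plus four factors)."""
    return CriteriaSet(
        "inclusive",
        (
            AGE_LT_10,
            AGE_GE_75,
            CHRONIC_DISEASE,
            PREGNANCY,
            OUTDOOR_WORK,
            LOW_EDUCATION,
            LOW_VITAMIN_C,
            REMAINDER_10_19_65_74,
        ),
    )


def criteria_by_name(name: str) -> CriteriaSet:
    if name == "restrictive":
        return restrictive_criteria()
    if name == "inclusive":
        return inclusive_criteria()
    raise KeyError(f"no preset criteria named {name!r}")


def custom_criteria(name: str, factors: Iterable[FactorSpec]) -> CriteriaSet:
    """Build a custom ordered criteria set, reindexing factors contiguously."""
    reindexed = tuple(
        FactorSpec(
            f.name,
            i,
            f.age_scope,
            f.sex_scope,
            f.wholesale,
            f.prevalence_ref,
        )
        for i, f in enumerate(factors)
    )
    return CriteriaSet(name, reindexed)
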