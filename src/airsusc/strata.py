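"""Canonical age stratification.

The population is divided into ten half-open age bands: <10, 10-14, 15,
16-19, 20-24, 25-34, 35-44, 45-64, 65-74 and 75+. The 10-19 range is
deliberately subdivided into bands of unequal width because pregnancy
prevalence applies from age 15 while outdoor-work prevalence applies from
age 16; every risk factor's age scope must align with band boundaries.

Ages are completed years; band ``[lo, hi)`` contains ages ``lo <= age < hi``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

#: (label, lo, hi) for the ten canonical bands, in ascending age order.
CANONICAL_BANDS: tuple[tuple[str, float, float], ...] = (
    ("<10", 0, 10),
    ("10-14", 10, 15),
    ("15", 15, 16),
    ("16-19", 16, 20),
    ("20-24", 20, 25),
    ("25-34", 25, 35),
    ("35-44", 35, 45),
    ("45-64", 45, 65),
    ("65-74", 65, 75),
    ("75+", 75, math.inf),
)

STRATUM_LABELS: tuple[str, ...] = tuple(b[0] for b in CANONICAL_BANDS)

_BOUNDS = {label: (lo, hi) for label, lo, hi in CANONICAL_BANDS}


@dataclass(frozen=True)
class AgeStratum:
    """One canonical age band of a concrete population.

    Parameters
    ----------
    label : str
        One of the ten canonical band labels.
    population : float
        Number of residents in the band (>= 0).
    female_fraction : float
        Fraction of the band's population that is female, in [0, 1].
        Used to convert pregnancy prevalence among females to a
        stratum-wide prevalence.
    """

    label: str
    population: float
    female_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.label not in _BOUNDS:
            raise ValueError(f"unknown age stratum label: {self.label!r}")
        if self.population < 0:
            raise ValueError(f"negative population for stratum {self.label}")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ValueError(f"female_fraction outside [0, 1] for {self.label}")

    @property
    def lo(self) -> float:
        return _BOUNDS[self.label][0]

    @property
    def hi(self) -> float:
        return _BOUNDS[self.label][1]


def stratum_for_age(age: float) -> str:
    """Return the canonical band label containing ``age`` (completed years)."""
    if age < 0:
        raise ValueError(f"negative age: {age}")
    for label, lo, hi in CANONICAL_BANDS:
        if lo <= age < hi:
            return label
    raise AssertionError("unreachable: bands cover [0, inf)")


def make_strata(
    populations: Mapping[str, float],
    female_fractions: Mapping[str, float] | None = None,
) -> tuple[AgeStratum, ...]:
    """Build the full ten-band tuple from per-band populations.

    Every canonical band must be present in ``populations``; missing
    female fractions default to 0.5.
    """
    missing = [lab for lab in STRATUM_LABELS if lab not in populations]
    if missing:
        raise ValueError(f"missing strata: {missing}")
    ff = female_fractions or {}
    return tuple(
        AgeStratum(lab, float(populations[lab]), float(ff.get(lab, 0.5)))
        for lab in STRATUM_LABELS
    )


def total_population(strata: Iterable[AgeStratum]) -> float:
    return float(sum(s.population for s in strata))
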