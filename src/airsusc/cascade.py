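"""Sequential risk-factor cascade.

Within each age stratum the ordered factors are applied one after
another: starting from the whole stratum (q0 = 1), the fraction still
unflagged is multiplied by the next factor's effective prevalence and
that product is removed from further steps,

    c_k = q_{k-1} * p_k,        q_k = q_{k-1} * (1 - p_k),

so no person is counted twice. Under independence of the factors the
flagged total per stratum equals 1 - prod_k (1 - p_k), which is symmetric
in the factors: permuting the order changes the per-factor decomposition
but never the total. Effective prevalence is 0 off a factor's age scope
and 1 for wholesale factors on scope.

Population percents are formed by weighting stratum fractions with the
stratum population shares; all arithmetic is kept in full precision and
rounding happens only at output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .factors import CriteriaSet
from .prevalence import PrevalenceTable
from .strata import AgeStratum, total_population


@dataclass(frozen=True)
class CascadeResult:
    """Outcome of one cascade run over a set of strata.

    ``contribution[a, k]`` is the fraction of stratum ``a``'s population
    attributed to factor ``k``; ``remaining[a]`` the fraction never
    flagged. ``per_factor_percent`` and ``total_percent`` are population
    percents (0-100) over all strata.
    """

    stratum_labels: tuple[str, ...]
    factor_names: tuple[str, ...]
    populations: np.ndarray
    contribution: np.ndarray
    remaining: np.ndarray
    per_factor_percent: np.ndarray
    total_percent: float

    def contribution_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.contribution,
            index=pd.Index(self.stratum_labels, name="stratum"),
            columns=pd.Index(self.factor_names, name="factor"),
        )


def effective_prevalences(
    strata: Sequence[AgeStratum],
    prevalences: PrevalenceTable,
    criteria: CriteriaSet,
    region: str | None = None,
) -> np.ndarray:
    """(A, K) matrix of effective prevalences: 0 off-scope, 1 for wholesale."""
    A, K = len(strata), len(criteria.factors)
    P = np.zeros((A, K))
    for k, f in enumerate(criteria.factors):
        for a, s in enumerate(strata):
            if s.label not in f.age_scope:
                continue
            if f.wholesale:
                P[a, k] = 1.0
            else:
                try:
                    P[a, k] = prevalences.get(f.prevalence_ref, s.label, region)
                except KeyError as exc:
                    raise PrevalenceConfigErrorFromCascade(
                        f"criteria {criteria.name!r}: missing prevalence for "
                        f"factor {f.name!r}, stratum {s.label!r}, region {region!r}"
                    ) from exc
    if (P < 0).any() or (P > 1).any():
        raise ValueError("effective prevalence outside [0, 1]")
    return P


class PrevalenceConfigErrorFromCascade(KeyError):
    """An in-scope factor has no prevalence entry."""


def cascade_fractions(P: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Apply the sequential removal to a prevalence matrix.

    Returns ``(contribution, remaining)`` with ``contribution[a, k] =
    q_{k-1} p_k`` and ``remaining[a] = prod_k (1 - p_k)``.
    """
    P = np.asarray(P, dtype=float)
    A, K = P.shape
    c = np.empty((A, K))
    q = np.ones(A)
    for k in range(K):
        c[:, k] = q * P[:, k]
        q = q * (1.0 - P[:, k])
    return c, q


def run_cascade(
    strata: Sequence[AgeStratum],
    prevalences: PrevalenceTable,
    criteria: CriteriaSet,
    region: str | None = None,
) -> CascadeResult:
    """Run one criteria set over concrete strata.

    Pregnancy (and any female-scoped factor) must already be stored
    stratum-wide in ``prevalences`` (rate among females times female
    fraction); :func:`airsusc.prevalence.build_prevalence_table` does this.
    """
    P = effective_prevalences(strata, prevalences, criteria, region)
    c, q = cascade_fractions(P)
    pop = np.array([s.population for s in strata], dtype=float)
    N = pop.sum()
    if N <= 0:
        raise ValueError("total population is zero")
    share = pop / N
    per_factor = 100.0 * share @ c
    total = float(per_factor.sum())
    return CascadeResult(
        stratum_labels=tuple(s.label for s in strata),
        factor_names=criteria.factor_names,
        populations=pop,
        contribution=c,
        remaining=q,
        per_factor_percent=per_factor,
        total_percent=total,
    )


def decompose_to_table(result: CascadeResult) -> pd.Series:
    """Per-factor population percents (the per-region analogue of a
    variability-table row); recomputed from the contribution matrix."""
    share = result.populations / result.populations.sum()
    return pd.Series(
        100.0 * share @ result.contribution,
        index=pd.Index(result.factor_names, name="factor"),
        name="percent",
    )


def sum_factor_percents(per_factor_percents: Iterable[float]) -> float:
    """Total percent with >= 1 factor as the sum of per-factor percents.

    The decomposition is additive by construction, so the total for any
    criteria set is the plain sum of its factors' population percents —
    this also holds for means of per-factor percents across regions
    (linearity of the mean).
    """
    return float(np.sum(np.fromiter(per_factor_percents, dtype=float)))


def aggregate_regions(
    total_percents: Sequence[float], populations: Sequence[float]
) -> float:
    """Population-weighted national percent from regional totals."""
    t = np.asarray(total_percents, dtype=float)
    w = np.asarray(populations, dtype=float)
    if (w <= 0).any():
        raise ValueError("region populations must be positive")
    return float(np.dot(t, w) / w.sum())


def summarize_factor_percents(decompositions: pd.DataFrame) -> pd.DataFrame:
    """Min/quartile/median/mean/max of each factor's percent across regions.

    ``decompositions`` is regions x factors (one row per region, from
    :func:`decompose_to_table`).
    """
    q = decompositions.quantile([0.25, 0.5, 0.75])
    out = pd.DataFrame(
        {
            "min": decompositions.min(),
            "p25": q.loc[0.25],
            "median": q.loc[0.5],
            "mean": decompositions.mean(),
            "p75": q.loc[0.75],
            "max": decompositions.max(),
        }
    )
    out.index.name = "factor"
    return out
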