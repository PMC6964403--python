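"""Rank correlations between regional susceptibility, rurality and exposure.

:func:`spearman` is a self-contained Spearman rank correlation: the
Pearson correlation of midranks. For small samples (n <= 8 by default)
the two-sided p-value is exact — computed from the full permutation
distribution of the statistic — and for larger samples it uses the usual
t approximation with n - 2 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

EXACT_N_MAX = 8

#: the standard regional pairings reported by the analysis
REPORT_PAIRS: tuple[tuple[str, str], ...] = (
    ("restrictive_pct", "inclusive_pct"),
    ("inclusive_pct", "rural_pct"),
    ("pm25", "restrictive_pct"),
    ("pm25", "inclusive_pct"),
    ("o3", "restrictive_pct"),
    ("o3", "inclusive_pct"),
    ("pm25", "urban_pct"),
    ("o3", "urban_pct"),
)


class DegenerateDataError(ValueError):
    """Rank variance is zero; the correlation is undefined."""


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float
    n: int
    method: str  # "exact" or "t-approx"


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    ac = a - a.mean()
    bc = b - b.mean()
    denom = np.sqrt((ac @ ac) * (bc @ bc))
    if denom == 0:
        raise DegenerateDataError("zero rank variance: correlation undefined")
    return float(np.clip(ac @ bc / denom, -1.0, 1.0))


def spearman(
    x: Sequence[float], y: Sequence[float], p_method: str = "auto"
) -> SpearmanResult:
    """Spearman rank correlation with ties as midranks.

    ``p_method``: ``"exact"`` enumerates all n! permutations of y (two-
    sided p = fraction of permutations with |rho| >= |observed|),
    ``"t"`` uses the t approximation, ``"auto"`` picks exact for
    n <= 8. Raises :class:`DegenerateDataError` when either variable is
    constant in rank.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    n = len(xa)
    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")
    if np.isnan(xa).any() or np.isnan(ya).any():
        raise ValueError("missing values; drop them before calling spearman")
    rx = _midranks(xa)
    ry = _midranks(ya)
    rho = _pearson(rx, ry)

    if p_method not in ("auto", "exact", "t"):
        raise ValueError(f"unknown p_method {p_method!r}")
    use_exact = p_method == "exact" or (p_method == "auto" and n <= EXACT_N_MAX)
    if use_exact:
        perms = np.array(list(permutations(ry)), dtype=float)
        rxc = rx - rx.mean()
        pc = perms - ry.mean()
        denom = np.sqrt((rxc @ rxc) * (pc[0] @ pc[0]))
        rhos = pc @ rxc / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
        return SpearmanResult(rho, p, n, "exact")
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return SpearmanResult(rho, p, n, "t-approx")


def correlation_report(frame: pd.DataFrame, p_method: str = "auto") -> pd.DataFrame:
    """Spearman rho and p for the standard regional pairings.

    ``frame`` holds one row per region with columns ``restrictive_pct,
    inclusive_pct, urban_pct, rural_pct, pm25, o3``. Pairs are evaluated
    pairwise-complete; dropped regions are counted per pair. Degenerate
    pairs (zero rank variance) are reported with NA rho/p rather than
    aborting the report.
    """
    rows = []
    for a, b in REPORT_PAIRS:
        sub = frame[[a, b]].dropna()
        n_dropped = len(frame) - len(sub)
        try:
            res = spearman(sub[a].to_numpy(), sub[b].to_numpy(), p_method=p_method)
            rows.append(
                {"pair": f"{a}~{b}", "rho": res.rho, "p": res.p_value,
                 "n": res.n, "n_dropped": n_dropped, "note": ""}
            )
        except (DegenerateDataError, ValueError) as exc:
            rows.append(
                {"pair": f"{a}~{b}", "rho": np.nan, "p": np.nan,
                 "n": len(sub), "n_dropped": n_dropped, "note": str(exc)}
            )
    return pd.DataFrame(rows, columns=["pair", "rho", "p", "n", "n_dropped", "note"])
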