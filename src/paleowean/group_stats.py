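"""Comparative statistics across age groups: normality, ANOVA, Tukey–Kramer.

The five groups (four juvenile age bins plus adult females) are compared per
isotope with a classical one-way fixed-effects ANOVA and Tukey–Kramer
pairwise comparisons (studentized-range critical values with the Kramer
unequal-n adjustment, family-wise 95% intervals).

Sign convention: groups carry a fixed level order (G1, G2, G3, G4, females)
and every pairwise difference is mean(later level) − mean(earlier level) —
the convention of R's ``TukeyHSD``, which generated the published table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "AnovaResult",
    "PairwiseComparison",
    "shapiro_test",
    "oneway_anova",
    "tukey_kramer",
    "format_p",
]

LEVEL_ORDER = ("G1", "G2", "G3", "G4", "females")
_DISPLAY = {"G1": "Group 1", "G2": "Group 2", "G3": "Group 3", "G4": "Group 4", "females": "Female"}


@dataclass
class AnovaResult:
    isotope: str  # "N" or "C"
    F: float
    df_between: int
    df_within: int
    p: float


@dataclass
class PairwiseComparison:
    """One Tukey–Kramer comparison.

    ``pair`` holds display labels; ``diff`` is mean(later level) − mean(earlier
    level) in the fixed level order, with ``lower``/``upper`` the simultaneous
    95% bounds and ``p_adj`` the studentized-range adjusted p-value.
    """

    pair: tuple[str, str]
    diff: float
    lower: float
    upper: float
    p_adj: float


def shapiro_test(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro–Wilk normality test (W, p); requires 3 ≤ n ≤ 5000."""
    x = np.asarray(values, dtype=float)
    if not (3 <= x.size <= 5000):
        raise ValueError(f"Shapiro-Wilk needs 3 <= n <= 5000, got n={x.size}")
    if x.std() == 0:
        raise ValueError("Shapiro-Wilk is degenerate for a constant sample")
    res = stats.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def _ordered_groups(groups: Mapping[str, Sequence[float]]) -> list[tuple[str, np.ndarray]]:
    known = [g for g in LEVEL_ORDER if g in groups]
    extra = [g for g in groups if g not in LEVEL_ORDER]
    out = [(g, np.asarray(groups[g], dtype=float)) for g in known + extra]
    if len(out) < 2:
        raise ValueError("need at least 2 groups")
    for name, vals in out:
        if vals.size == 0:
            raise ValueError(f"group {name!r} is empty")
    return out


def oneway_anova(groups: Mapping[str, Sequence[float]], isotope: str = "") -> AnovaResult:
    """Classical one-way fixed-effects ANOVA across the given groups."""
    ordered = _ordered_groups(groups)
    arrays = [v for _, v in ordered]
    if any(v.size < 2 for v in arrays):
        raise ValueError("each group needs n >= 2")
    F, p = stats.f_oneway(*arrays)
    n_total = sum(v.size for v in arrays)
    return AnovaResult(
        isotope=isotope,
        F=float(F),
        df_between=len(arrays) - 1,
        df_within=n_total - len(arrays),
        p=float(p),
    )


def tukey_kramer(groups: Mapping[str, Sequence[float]], alpha: float = 0.05) -> list[PairwiseComparison]:
    """All pairwise Tukey–Kramer comparisons at family-wise level ``alpha``.

    Unequal group sizes are handled by the Kramer adjustment (as implemented
    by statsmodels' ``pairwise_tukeyhsd``).  Output order and difference signs
    follow the fixed level order (see module docstring).
    """
    ordered = _ordered_groups(groups)
    names = [g for g, _ in ordered]
    values = np.concatenate([v for _, v in ordered])
    # integer-coded labels freeze the level order through statsmodels' sort
    codes = np.concatenate(
        [np.full(v.size, i) for i, (_, v) in enumerate(ordered)]
    )
    res = pairwise_tukeyhsd(values, codes, alpha=alpha)
    # with sorted integer codes, statsmodels enumerates pairs (i, j), i < j, in
    # upper-triangular order and reports diff = mean(j) − mean(i)
    pair_ij = list(zip(*np.triu_indices(len(names), 1)))
    out: list[PairwiseComparison] = []
    for (i, j), diff, (lo, hi), p in zip(pair_ij, res.meandiffs, res.confint, res.pvalues):
        out.append(
            PairwiseComparison(
                pair=(_DISPLAY.get(names[j], names[j]), _DISPLAY.get(names[i], names[i])),
                diff=float(diff),
                lower=float(lo),
                upper=float(hi),
                p_adj=float(p),
            )
        )
    return out


def format_p(p: float) -> str:
    """Human-readable adjusted p: values below 0.0005 print as '0.000'."""
    return f"{p:.3f}"
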