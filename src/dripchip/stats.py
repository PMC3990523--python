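"""Association statistics: exact Fisher test, Wilcoxon rank-sum, set
overlap tables, and the Bonferroni cutoff used by the cytological screen.

The Fisher test is computed in exact integer arithmetic over the
hypergeometric support, so tied table probabilities (e.g. symmetric
extremes) are resolved exactly rather than to floating-point tolerance.
The two-sided p uses the probability-mass definition: the sum over all
tables, at fixed margins, whose probability does not exceed that of the
observed table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from math import comb
from typing import Collection, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

ALTERNATIVES = ("two-sided", "less", "greater")


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int  # in-set & annotated
    b: int  # in-set & not annotated
    c: int  # not in-set & annotated
    d: int  # neither

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative count in 2x2 table")

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return self.a, self.b, self.c, self.d


def fisher_exact_2x2(
    table: ContingencyTable2x2 | Sequence[Sequence[int]],
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Fisher's exact test on a 2x2 table -> (odds_ratio, p).

    ``greater`` tests enrichment of the top-left cell. A zero margin makes
    the test degenerate: p = 1 and the odds ratio undefined (NaN, with a
    warning). The odds ratio is ``a*d / (b*c)`` (inf when only the
    denominator is zero).
    """
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}")
    if not isinstance(table, ContingencyTable2x2):
        (a, b), (c, d) = table
        table = ContingencyTable2x2(int(a), int(b), int(c), int(d))
    a, b, c, d = table.counts
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        warnings.warn("zero margin: odds ratio undefined, p = 1", stacklevel=2)
        return float("nan"), 1.0
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)

    lo = max(0, c1 - r2)
    hi = min(c1, r1)
    # integer numerators of the hypergeometric pmf at fixed margins
    num = [comb(r1, k) * comb(r2, c1 - k) for k in range(lo, hi + 1)]
    denom = sum(num)
    obs = num[a - lo]
    if alternative == "greater":
        tail = sum(num[a - lo :])
    elif alternative == "less":
        tail = sum(num[: a - lo + 1])
    else:
        tail = sum(v for v in num if v <= obs)
    return odds, float(Fraction(tail, denom))


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
    mode: str = "auto",
) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney U) test -> (U statistic of x, p).

    ``mode='exact'`` uses the exact tie-free null distribution (error on
    ties); ``'normal-approx'`` the normal approximation with tie-corrected
    variance and continuity correction; ``'auto'`` picks exact for tie-free
    samples with ``n_x + n_y <= 50``.
    """
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return len(x) * len(y) / 2.0, 1.0
    ties = len(np.unique(pooled)) < len(pooled)
    if mode == "auto":
        mode = "exact" if (not ties and len(pooled) <= 50) else "normal-approx"
    if mode == "exact":
        if ties:
            raise ValueError("exact mode requires tie-free samples")
        res = mannwhitneyu(x, y, alternative=alternative, method="exact")
    elif mode in ("normal-approx", "asymptotic"):
        res = mannwhitneyu(x, y, alternative=alternative, method="asymptotic",
                           use_continuity=True)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(res.statistic), float(min(res.pvalue, 1.0))


@dataclass(frozen=True)
class AssociationResult:
    table: ContingencyTable2x2
    odds_ratio: float
    p_value: float
    percent_annotated: float    # of the focal set; NaN when focal is empty
    percent_universe: float     # annotated fraction of the whole universe


def set_association(
    focal_ids: Collection[str],
    universe_ids: Collection[str],
    annotated_ids: Collection[str],
    alternative: str = "two-sided",
) -> AssociationResult:
    """Fisher association between membership in a focal set and carrying an
    annotation, within a universe (e.g. hybrid-enriched genes vs
    antisense-associated genes among all annotated transcripts)."""
    focal = set(focal_ids)
    universe = set(universe_ids)
    annotated = set(annotated_ids)
    if not focal <= universe:
        raise ValueError("focal set not contained in universe")
    if not annotated <= universe:
        raise ValueError("annotated set not contained in universe")
    a = len(focal & annotated)
    b = len(focal - annotated)
    c = len(annotated - focal)
    d = len(universe) - a - b - c
    table = ContingencyTable2x2(a, b, c, d)
    if not focal:
        warnings.warn("empty focal set: percent annotated undefined", stacklevel=2)
        percent = float("nan")
        odds, p = float("nan"), 1.0
    else:
        percent = 100.0 * a / len(focal)
        odds, p = fisher_exact_2x2(table, alternative=alternative)
    pct_universe = 100.0 * len(annotated) / len(universe) if universe else float("nan")
    return AssociationResult(table, odds, p, percent, pct_universe)


def association_report(results: dict[str, AssociationResult]) -> pd.DataFrame:
    rows = []
    for name, r in results.items():
        rows.append(
            {
                "comparison": name,
                "a": r.table.a, "b": r.table.b, "c": r.table.c, "d": r.table.d,
                "odds_ratio": r.odds_ratio,
                "p": r.p_value,
                "percent_annotated": r.percent_annotated,
                "percent_universe": r.percent_universe,
            }
        )
    return pd.DataFrame(rows)


def bonferroni_cutoff(n_tests: int, alpha: float = 0.01) -> float:
    """Per-test significance threshold ``alpha / n_tests``."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests
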