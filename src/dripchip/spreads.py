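"""Chromosome-spread screen statistics.

Each strain is scored cytologically: per replicate, the number of nuclei
visualized and the number staining positive for DNA:RNA hybrids. Replicates
are pooled per strain into a single 2x2 table against wild type and tested
with Fisher's exact test; significance uses a Bonferroni cutoff of
alpha / n_tests (alpha = 0.01 over the mutants screened).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .stats import ContingencyTable2x2, bonferroni_cutoff, fisher_exact_2x2

logger = logging.getLogger(__name__)

SPREAD_COLUMNS = ("strain", "replicate", "n_nuclei", "n_positive")

#: replicates with fewer visualized nuclei than this are flagged
MIN_NUCLEI = 100


def read_spread_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"strain": str})
    missing = [c for c in SPREAD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"spread count table missing columns: {missing}")
    if (df["n_positive"] > df["n_nuclei"]).any() or (df["n_positive"] < 0).any():
        raise ValueError("n_positive must lie in [0, n_nuclei]")
    low = df[df["n_nuclei"] < MIN_NUCLEI]
    if len(low):
        logger.warning("%d replicates have < %d nuclei", len(low), MIN_NUCLEI)
    return df


def write_spread_counts(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class ScreenResult:
    strain: str
    n_nuclei: int
    n_positive: int
    rate: float
    sem: float
    wt_rate: float
    p: float
    cutoff: float
    significant: bool
    low_count: bool


def screen_significance(
    counts: pd.DataFrame,
    wt_strain: str = "WT",
    alpha: float = 0.01,
    n_tests: int | None = None,
) -> pd.DataFrame:
    """Per-mutant hybrid-positive rates and Fisher significance vs wild type.

    Replicates are pooled per strain; the two-sided Fisher p compares
    pooled positive/negative counts of each mutant against wild type. The
    cutoff is ``alpha / n_tests`` (``n_tests`` defaults to the number of
    mutants in the table). The SEM is computed across replicate rates.
    Strains with zero total nuclei are excluded and logged.
    """
    if wt_strain not in set(counts["strain"]):
        raise ValueError(f"wild-type strain {wt_strain!r} absent from counts")
    pooled = counts.groupby("strain")[["n_nuclei", "n_positive"]].sum()
    empty = pooled.index[pooled["n_nuclei"] == 0]
    if len(empty):
        logger.warning("excluding strains with zero nuclei: %s", list(empty))
        pooled = pooled.drop(empty)
    mutants = [s for s in pooled.index if s != wt_strain]
    cutoff = bonferroni_cutoff(n_tests if n_tests is not None else len(mutants),
                               alpha=alpha)
    wt_pos = int(pooled.loc[wt_strain, "n_positive"])
    wt_n = int(pooled.loc[wt_strain, "n_nuclei"])
    wt_rate = wt_pos / wt_n

    rows = []
    for strain in [wt_strain] + sorted(mutants):
        n = int(pooled.loc[strain, "n_nuclei"])
        pos = int(pooled.loc[strain, "n_positive"])
        reps = counts[counts["strain"] == strain]
        rates = (reps["n_positive"] / reps["n_nuclei"]).to_numpy(float)
        sem = float(rates.std(ddof=1) / np.sqrt(len(rates))) if len(rates) > 1 else 0.0
        if strain == wt_strain:
            p, significant = 1.0, False
        else:
            table = ContingencyTable2x2(pos, n - pos, wt_pos, wt_n - wt_pos)
            _, p = fisher_exact_2x2(table, alternative="two-sided")
            significant = p < cutoff
        rows.append(
            ScreenResult(
                strain=strain, n_nuclei=n, n_positive=pos, rate=pos / n,
                sem=sem, wt_rate=wt_rate, p=p, cutoff=cutoff,
                significant=significant,
                low_count=bool((reps["n_nuclei"] < MIN_NUCLEI).any()),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def write_screen_results(results: pd.DataFrame, path: str | Path) -> None:
    results.to_csv(path, sep="\t", index=False)
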