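"""Monte Carlo test for feature-class enrichment.

Whether a class of features (rDNA units, telomeric repeats, Ty elements,
tRNAs, snoRNAs, antisense genes, ...) is enriched more often than random
placement predicts: each simulation re-places every class member uniformly
at random in the genome (keeping its length and strand), re-applies the
enrichment-calling rule, and records the proportion of members called
enriched. The observed proportion is then located on a normal distribution
fitted to the simulated null (mean and n-1 SD over the simulations), giving
the cumulative probability P of seeing a lower score by chance. P close to
1 means the class is enriched far beyond random placement.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .annotation import GenomeFeature
from .enrichment import TrackIndex
from .signal import SignalTrack


@dataclass(frozen=True)
class MonteCarloResult:
    feature_class: str
    n_members: int
    observed: float
    null_mean: float
    null_sd: float
    p: float
    n_sims: int
    seed: int


def randomize_feature_starts(
    features: Sequence[GenomeFeature],
    chrom_lengths: Mapping[str, int],
    rng: np.random.Generator,
    same_chromosome: bool = False,
) -> list[GenomeFeature]:
    """Random re-placement of features, lengths and strands preserved.

    Each feature receives a chromosome sampled with probability
    proportional to the number of valid start positions on it
    (``chrom_length - feature_length + 1``) and a uniform start such that
    the feature fits. Overlaps among randomized features are permitted.
    With ``same_chromosome=True`` features stay on their own chromosome.
    """
    names = sorted(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in names], dtype=np.int64)
    out = []
    for f in features:
        if same_chromosome:
            cap = chrom_lengths[f.chrom] - f.length
            if cap < 0:
                raise ValueError(f"{f.id} longer than its chromosome")
            start = int(rng.integers(0, cap + 1))
            out.append(replace(f, start=start, end=start + f.length))
            continue
        w = np.maximum(lengths - f.length + 1, 0)
        total = w.sum()
        if total == 0:
            raise ValueError(f"{f.id} longer than every chromosome")
        ci = int(rng.choice(len(names), p=w / total))
        start = int(rng.integers(0, lengths[ci] - f.length + 1))
        out.append(replace(f, chrom=names[ci], start=start, end=start + f.length))
    return out


def _enriched_proportion(index: TrackIndex, chrom_idx: np.ndarray,
                         starts: np.ndarray, lengths: np.ndarray,
                         chrom_names: list[str], min_fraction: float) -> float:
    enriched = np.zeros(len(starts), dtype=bool)
    for k, name in enumerate(chrom_names):
        mask = chrom_idx == k
        if not mask.any():
            continue
        n, above = index.counts(name, starts[mask], starts[mask] + lengths[mask])
        enriched[mask] = (n > 0) & (above >= min_fraction * n)
    return float(enriched.mean())


def monte_carlo_class_enrichment(
    track: SignalTrack,
    features_of_class: Sequence[GenomeFeature],
    chrom_lengths: Mapping[str, int],
    n_sims: int = 500,
    threshold: float = 1.5,
    min_fraction: float = 0.5,
    seed: int = 0,
    feature_class: str | None = None,
    same_chromosome: bool = False,
) -> MonteCarloResult:
    """Monte Carlo cumulative probability for one feature class.

    ``P = Phi((observed - mu) / sigma)`` with ``mu``/``sigma`` the mean and
    sample SD of the enriched proportion over ``n_sims`` random placements.
    Degenerate ``sigma = 0``: P is 1 if observed > mu, 0 if observed < mu,
    0.5 if equal.
    """
    if n_sims < 2:
        raise ValueError("need at least 2 simulations")
    if not features_of_class:
        raise ValueError("empty feature class")
    rng = np.random.default_rng(seed)
    names = sorted(chrom_lengths)
    clens = np.array([chrom_lengths[c] for c in names], dtype=np.int64)
    flens = np.array([f.length for f in features_of_class], dtype=np.int64)

    index = TrackIndex(track, threshold)

    # observed proportion on the real coordinates
    observed_flags = []
    for f in features_of_class:
        n, above = index.counts(f.chrom, np.array([f.start]), np.array([f.end]))
        observed_flags.append(n[0] > 0 and above[0] >= min_fraction * n[0])
    observed = float(np.mean(observed_flags))

    # placement weights: chromosomes drawn proportional to the number of
    # valid starts for each feature's length
    if same_chromosome:
        name_to_idx = {c: i for i, c in enumerate(names)}
        fixed_ci = np.array([name_to_idx[f.chrom] for f in features_of_class])
        if np.any(clens[fixed_ci] - flens < 0):
            raise ValueError("a feature is longer than its chromosome")
    else:
        w = np.maximum(clens[None, :] - flens[:, None] + 1, 0)
        if np.any(w.sum(axis=1) == 0):
            raise ValueError("a feature is longer than every chromosome")
        cum_w = np.cumsum(w, axis=1)
        tot_w = cum_w[:, -1]

    sims = np.empty(n_sims)
    m = len(features_of_class)
    for s in range(n_sims):
        if same_chromosome:
            ci = fixed_ci
        else:
            u = rng.random(m) * tot_w
            ci = (u[:, None] >= cum_w).sum(axis=1)
        starts = rng.integers(0, clens[ci] - flens + 1)
        sims[s] = _enriched_proportion(index, ci, starts, flens, names, min_fraction)

    mu = float(sims.mean())
    sd = float(sims.std(ddof=1))
    if sd == 0.0:
        p = 1.0 if observed > mu else (0.0 if observed < mu else 0.5)
    else:
        p = float(norm.cdf((observed - mu) / sd))
    return MonteCarloResult(
        feature_class=feature_class or features_of_class[0].feature_class,
        n_members=m,
        observed=observed,
        null_mean=mu,
        null_sd=sd,
        p=p,
        n_sims=n_sims,
        seed=seed,
    )


def results_table(results: Sequence[MonteCarloResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "class": r.feature_class,
                "n_members": r.n_members,
                "observed": r.observed,
                "null_mean": r.null_mean,
                "null_sd": r.null_sd,
                "P": r.p,
                "n_sims": r.n_sims,
                "seed": r.seed,
            }
            for r in results
        ]
    )


def write_results(results: Sequence[MonteCarloResult], path: str | Path) -> None:
    results_table(results).to_csv(path, sep="\t", index=False)
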