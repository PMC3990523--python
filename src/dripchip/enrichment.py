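"""Feature-level enrichment calls from relative-occupancy tracks.

A feature is called enriched when at least half of the probes whose
midpoints fall inside it score strictly above 1.5-fold over mock. Only
features enriched in both replicates make the reported consensus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GenomeFeature
from .signal import SignalTrack

logger = logging.getLogger(__name__)


class TrackIndex:
    """Searchable per-chromosome index of probe positions and above-threshold
    indicator prefix sums; makes per-feature probe counting O(log n)."""

    def __init__(self, track: SignalTrack, threshold: float) -> None:
        self.threshold = threshold
        self._pos: dict[str, np.ndarray] = {}
        self._cum_above: dict[str, np.ndarray] = {}
        for c in track.chroms:
            pos, score = track.data[c]
            self._pos[c] = pos
            self._cum_above[c] = np.concatenate(
                ([0], np.cumsum((score > threshold).astype(np.int64)))
            )

    @property
    def chroms(self) -> list[str]:
        return sorted(self._pos)

    def counts(self, chrom: str, starts: np.ndarray, ends: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray]:
        """(n_probes, n_above) for intervals ``[start, end)`` on ``chrom``."""
        starts = np.asarray(starts)
        ends = np.asarray(ends)
        pos = self._pos.get(chrom)
        if pos is None:
            z = np.zeros(starts.shape, dtype=np.int64)
            return z, z.copy()
        i = np.searchsorted(pos, starts, side="left")
        j = np.searchsorted(pos, ends, side="left")
        cum = self._cum_above[chrom]
        return j - i, cum[j] - cum[i]


@dataclass(frozen=True)
class EnrichmentCall:
    feature_id: str
    n_probes: int
    n_above: int
    enriched: bool

    @property
    def fraction_above(self) -> float:
        return self.n_above / self.n_probes if self.n_probes else float("nan")


def call_feature_enrichment(
    track: SignalTrack,
    features: Sequence[GenomeFeature],
    threshold: float = 1.5,
    min_fraction: float = 0.5,
    index: TrackIndex | None = None,
) -> dict[str, EnrichmentCall]:
    """Call each feature enriched or not on one track.

    A probe is contained in a feature iff its midpoint lies in
    ``[start, end)``; "above" is strict (``score > threshold``); enriched
    iff the feature has probes and ``fraction_above >= min_fraction``.
    Features with zero probes (including those on chromosomes absent from
    the track) are never enriched and are logged.
    """
    if index is None or index.threshold != threshold:
        index = TrackIndex(track, threshold)
    calls: dict[str, EnrichmentCall] = {}
    uncovered = 0
    for f in features:
        n, above = index.counts(f.chrom, np.array([f.start]), np.array([f.end]))
        n, above = int(n[0]), int(above[0])
        enriched = n > 0 and above >= min_fraction * n
        if n == 0:
            uncovered += 1
        calls[f.id] = EnrichmentCall(f.id, n, above, bool(enriched))
    if uncovered:
        logger.info("%d features had no probes on the track (coverage gaps)",
                    uncovered)
    return calls


def consensus_calls(
    calls_rep1: Mapping[str, EnrichmentCall],
    calls_rep2: Mapping[str, EnrichmentCall],
) -> set[str]:
    """Feature ids enriched in both replicates."""
    if set(calls_rep1) != set(calls_rep2):
        raise ValueError("replicate call sets cover different feature universes")
    return {
        fid for fid, c in calls_rep1.items() if c.enriched and calls_rep2[fid].enriched
    }


def calls_table(
    calls_rep1: Mapping[str, EnrichmentCall],
    calls_rep2: Mapping[str, EnrichmentCall],
) -> pd.DataFrame:
    """Per-feature call summary across two replicates, with the consensus."""
    consensus = consensus_calls(calls_rep1, calls_rep2)
    rows = []
    for fid in sorted(calls_rep1):
        c1, c2 = calls_rep1[fid], calls_rep2[fid]
        rows.append(
            {
                "id": fid,
                "n_probes_rep1": c1.n_probes,
                "fraction_rep1": c1.fraction_above,
                "enriched_rep1": c1.enriched,
                "n_probes_rep2": c2.n_probes,
                "fraction_rep2": c2.fraction_above,
                "enriched_rep2": c2.enriched,
                "consensus": fid in consensus,
            }
        )
    return pd.DataFrame(rows)


def export_enriched_regions(
    consensus: Iterable[str],
    features: Sequence[GenomeFeature],
    path: str | Path,
) -> None:
    """Write consensus-enriched features as sorted BED6."""
    by_id = {f.id: f for f in features}
    ids = set(consensus)
    unknown = ids - set(by_id)
    if unknown:
        raise ValueError(f"ids not in feature universe: {sorted(unknown)[:5]}")
    chosen = sorted((by_id[i] for i in ids), key=lambda f: (f.chrom, f.start, f.id))
    with open(path, "w") as fh:
        fh.write("# consensus enriched features (BED6)\n")
        for f in chosen:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.id}\t0\t{f.strand}\n")
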