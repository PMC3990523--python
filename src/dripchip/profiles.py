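"""Visualization-grade summaries: CHROMATRA matrices and meta-profiles.

CHROMATRA rows hold per-transcript signal binned into 150 bp segments
aligned at the transcription start site (TSS), sorted by length or grouped
by transcriptional-frequency / GC classes. Meta-profiles average signal
over many features after length normalization: gene bodies are split into
40 bins with 1500 bp flanks ("UTRs") in 20 bins of 75 bp on each side;
small features (tRNA, snoRNA) into 3 bins with no flanks.

Probes are assigned to exactly one bin by midpoint; bins are half-open;
bins with no probes are missing (NaN), never zero. For minus-strand
features coordinates are mirrored so that bin 0 always sits at the TSS and
bins run 5'->3'.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import GenomeFeature, assign_classes
from .signal import SignalTrack

logger = logging.getLogger(__name__)


@dataclass
class ChromatraMatrix:
    ids: list[str]
    values: np.ndarray          # (n_transcripts, max_bins); NaN = masked/empty
    n_bins: np.ndarray          # unmasked bin count per row: ceil(len/bin_size)
    bin_size: int
    row_meta: pd.DataFrame      # id-indexed: length, group (optional class)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids)

    def write(self, path: str | Path, meta_path: str | Path | None = None) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="id")
        if meta_path is not None:
            self.row_meta.to_csv(meta_path, sep="\t", index_label="id")


@dataclass
class MetaProfile:
    segment: np.ndarray         # label per bin: upstream / body / downstream
    rel_bin: np.ndarray         # bin index within its segment
    mean: np.ndarray            # mean probe score per bin (NaN if empty)
    n_probes: np.ndarray        # probe assignments per bin
    n_features: np.ndarray      # features contributing >=1 probe to the bin

    @property
    def n_bins(self) -> int:
        return len(self.mean)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "segment": self.segment,
                "rel_bin": self.rel_bin,
                "mean": self.mean,
                "n_probes": self.n_probes,
                "n_features": self.n_features,
            }
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Probe -> bin geometry
# ---------------------------------------------------------------------------

def _oriented_rel(pos: np.ndarray, f: GenomeFeature, flank: int) -> np.ndarray:
    """Distance of each probe midpoint from the feature's 5' flank origin,
    running 5'->3'. Integer mirror for minus strand so that reflecting the
    genome and flipping strands is an exact symmetry."""
    if f.strand == "-":
        return (f.end - 1 + flank) - pos
    return pos - (f.start - flank)


def _feature_probes(track: SignalTrack, f: GenomeFeature, flank: int
                    ) -> tuple[np.ndarray, np.ndarray]:
    if f.chrom not in track.data:
        return np.empty(0, dtype=np.int64), np.empty(0)
    pos, score = track.data[f.chrom]
    i = np.searchsorted(pos, f.start - flank, side="left")
    j = np.searchsorted(pos, f.end + flank, side="left")
    return pos[i:j], score[i:j]


def average_feature_score(track: SignalTrack, feature: GenomeFeature) -> float:
    """Mean score of probes with midpoint in ``[start, end)``; NaN if none."""
    _, score = _feature_probes(track, feature, flank=0)
    return float(score.mean()) if len(score) else float("nan")


# ---------------------------------------------------------------------------
# CHROMATRA
# ---------------------------------------------------------------------------

def chromatra_matrix(
    track: SignalTrack,
    transcripts: Sequence[GenomeFeature],
    annotations: pd.DataFrame | None = None,
    bin_size: int = 150,
    order: str = "length",
) -> ChromatraMatrix:
    """TSS-aligned binned score matrix, one row per transcript.

    ``order`` is ``length`` (ascending, ties by id), or ``txn_class`` /
    ``gc_class`` (requires ``annotations``; rows grouped by class, sorted
    by length within each group). Row i carries ``ceil(length_i/bin_size)``
    bins; bins past the transcript end, and bins containing no probes, are
    NaN.
    """
    if order not in ("length", "txn_class", "gc_class"):
        raise ValueError(f"unknown order key {order!r}")
    feats = list(transcripts)
    if not feats:
        raise ValueError("no transcripts")
    if order == "length":
        feats.sort(key=lambda f: (f.length, f.id))
        groups = pd.Series("all", index=[f.id for f in feats])
    else:
        if annotations is None:
            raise ValueError(f"order={order!r} requires annotations")
        classes = assign_classes(annotations)
        by_id = classes[order]
        missing = [f.id for f in feats if f.id not in by_id.index]
        if missing:
            logger.info("chromatra: %d transcripts lack %s and are dropped",
                        len(missing), order)
            feats = [f for f in feats if f.id in by_id.index]
        feats.sort(key=lambda f: (by_id[f.id], f.length, f.id))
        groups = pd.Series({f.id: int(by_id[f.id]) for f in feats})

    n_bins = np.array([-(-f.length // bin_size) for f in feats])
    mat = np.full((len(feats), int(n_bins.max())), np.nan)
    for i, f in enumerate(feats):
        pos, score = _feature_probes(track, f, flank=0)
        if not len(pos):
            continue
        rel = _oriented_rel(pos, f, flank=0)
        bins = rel // bin_size
        for b in np.unique(bins):
            mat[i, int(b)] = score[bins == b].mean()
    meta = pd.DataFrame(
        {"length": [f.length for f in feats],
         "group": [groups[f.id] for f in feats]},
        index=[f.id for f in feats],
    )
    return ChromatraMatrix([f.id for f in feats], mat, n_bins, bin_size, meta)


# ---------------------------------------------------------------------------
# Meta-profiles
# ---------------------------------------------------------------------------

def average_gene_profile(
    track: SignalTrack,
    features: Sequence[GenomeFeature],
    n_body_bins: int = 40,
    utr_bp: int = 1500,
    n_utr_bins: int = 20,
) -> MetaProfile:
    """Length-normalized average profile across stranded features.

    Bodies are split into ``n_body_bins`` equal-width bins (exact rational
    edges; probe midpoint membership decides); each ``utr_bp`` flank is
    split into ``n_utr_bins`` fixed-width bins. The profile runs 5'->3':
    upstream flank, body, downstream flank. Bin value = mean over all
    (feature, probe) score assignments.
    """
    if any(f.strand not in ("+", "-") for f in features):
        raise ValueError("meta-profiles need stranded features")
    if utr_bp > 0 and n_utr_bins <= 0:
        raise ValueError("flanks require n_utr_bins > 0")
    n_flanks = 2 * n_utr_bins if utr_bp > 0 else 0
    total = n_body_bins + n_flanks
    ssum = np.zeros(total)
    nprobe = np.zeros(total, dtype=np.int64)
    nfeat = np.zeros(total, dtype=np.int64)
    short = 0
    for f in features:
        if f.length < n_body_bins:
            short += 1
        pos, score = _feature_probes(track, f, flank=utr_bp)
        if not len(pos):
            continue
        rel = _oriented_rel(pos, f, flank=utr_bp)
        idx = np.empty(len(rel), dtype=np.int64)
        up = rel < utr_bp
        body = (rel >= utr_bp) & (rel < utr_bp + f.length)
        down = rel >= utr_bp + f.length
        if utr_bp > 0:
            idx[up] = rel[up] * n_utr_bins // utr_bp
            idx[down] = (n_utr_bins + n_body_bins
                         + (rel[down] - utr_bp - f.length) * n_utr_bins // utr_bp)
        # exact rational body edges: bin = floor(rel_in_body * n_body / length)
        base = n_utr_bins if utr_bp > 0 else 0
        idx[body] = base + (rel[body] - utr_bp) * n_body_bins // f.length
        keep = up | body | down if utr_bp > 0 else body
        idx = idx[keep]
        sc = score[keep]
        np.add.at(ssum, idx, sc)
        np.add.at(nprobe, idx, 1)
        nfeat[np.unique(idx)] += 1
    if short:
        logger.info("%d features shorter than %d bp; some body bins may be empty",
                    short, n_body_bins)
    with np.errstate(invalid="ignore"):
        mean = np.where(nprobe > 0, ssum / np.maximum(nprobe, 1), np.nan)
    if utr_bp > 0:
        segment = np.array(["upstream"] * n_utr_bins + ["body"] * n_body_bins
                           + ["downstream"] * n_utr_bins)
        rel_bin = np.concatenate([np.arange(n_utr_bins), np.arange(n_body_bins),
                                  np.arange(n_utr_bins)])
    else:
        segment = np.array(["body"] * n_body_bins)
        rel_bin = np.arange(n_body_bins)
    return MetaProfile(segment, rel_bin, mean, nprobe, nfeat)


def small_feature_profile(
    track: SignalTrack,
    features: Sequence[GenomeFeature],
    n_bins: int = 3,
    flank_bp: int = 0,
    n_flank_bins: int = 0,
) -> MetaProfile:
    """Meta-profile for short features (tRNA, snoRNA): 3 body bins, no
    flanks by default."""
    return average_gene_profile(
        track, features, n_body_bins=n_bins, utr_bp=flank_bp,
        n_utr_bins=n_flank_bins,
    )
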