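"""Probe-level signal processing: relative-occupancy tracks.

The raw inputs are tab-separated probe tables (chrom, pos, ip, mock) from a
tiling array, one per replicate. The pipeline turns them into smoothed
"relative occupancy" tracks: per-probe (IP + c)/(mock + c) ratios, averaged
over a 300 bp sliding window, then quantile-normalized across replicates
and averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class SignalTrack:
    """Per-chromosome sorted probe positions with occupancy scores."""

    sample: str = "sample"
    replicate: str = "1"
    data: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (pos, score) in self.data.items():
            pos = np.asarray(pos, dtype=np.int64)
            score = np.asarray(score, dtype=np.float64)
            if pos.shape != score.shape:
                raise ValueError(f"{chrom}: positions and scores differ in length")
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"{chrom}: probe positions not strictly increasing")
            if not np.all(np.isfinite(score)):
                raise ValueError(f"{chrom}: non-finite scores")
            clean[chrom] = (pos, score)
        self.data = clean

    @property
    def chroms(self) -> list[str]:
        return sorted(self.data)

    def positions(self, chrom: str) -> np.ndarray:
        return self.data[chrom][0]

    def scores(self, chrom: str) -> np.ndarray:
        return self.data[chrom][1]

    @property
    def n_probes(self) -> int:
        return sum(len(p) for p, _ in self.data.values())

    def concat_scores(self) -> np.ndarray:
        """All scores, chromosomes in sorted name order."""
        return np.concatenate([self.data[c][1] for c in self.chroms])

    def with_scores(self, flat: np.ndarray, sample: str | None = None,
                    replicate: str | None = None) -> "SignalTrack":
        """New track with identical positions and scores taken from a flat
        vector laid out like :meth:`concat_scores`."""
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        i = 0
        for c in self.chroms:
            pos = self.data[c][0]
            out[c] = (pos, np.asarray(flat[i : i + len(pos)], dtype=float))
            i += len(pos)
        return SignalTrack(sample or self.sample, replicate or self.replicate, out)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            pd.DataFrame({"chrom": c, "pos": p, "score": s})
            for c, (p, s) in sorted(self.data.items())
        ]
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, score_col: str = "score",
                   sample: str = "sample", replicate: str = "1") -> "SignalTrack":
        data = {}
        for chrom, grp in df.groupby("chrom", sort=True):
            grp = grp.sort_values("pos")
            data[str(chrom)] = (grp["pos"].to_numpy(), grp[score_col].to_numpy())
        return cls(sample, replicate, data)


def read_probe_table(path: str | Path) -> pd.DataFrame:
    """Read a probe TSV with columns chrom, pos, ip, mock."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in ("chrom", "pos", "ip", "mock"):
        if col not in df.columns:
            raise ValueError(f"probe table {path} missing column {col!r}")
    if (df[["ip", "mock"]] < 0).any().any():
        raise ValueError("negative intensities in probe table")
    return df


def write_probe_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Normalization and smoothing
# ---------------------------------------------------------------------------

def mock_normalize(probes: pd.DataFrame, pseudocount: float = 1.0,
                   sample: str = "sample", replicate: str = "1") -> SignalTrack:
    """Per-probe relative occupancy ``(ip + c) / (mock + c)``.

    The pseudocount ``c`` (default 1 intensity unit) guards against division
    by zero in low-intensity mock probes.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    score = (probes["ip"].to_numpy(float) + pseudocount) / (
        probes["mock"].to_numpy(float) + pseudocount
    )
    df = probes[["chrom", "pos"]].copy()
    df["score"] = score
    return SignalTrack.from_frame(df, sample=sample, replicate=replicate)


def mock_normalize_tracks(ip: SignalTrack, mock: SignalTrack,
                          pseudocount: float = 1.0) -> SignalTrack:
    """Track-level variant of :func:`mock_normalize`; positions must match."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if ip.chroms != mock.chroms:
        raise ValueError(f"chromosome sets differ: {ip.chroms} vs {mock.chroms}")
    data = {}
    for c in ip.chroms:
        p1, s1 = ip.data[c]
        p2, s2 = mock.data[c]
        if len(p1) != len(p2) or np.any(p1 != p2):
            k = int(np.flatnonzero(p1[: min(len(p1), len(p2))] !=
                                   p2[: min(len(p1), len(p2))])[0]) \
                if min(len(p1), len(p2)) else 0
            raise ValueError(f"{c}: probe position mismatch at index {k}")
        data[c] = (p1, (s1 + pseudocount) / (s2 + pseudocount))
    return SignalTrack(ip.sample, ip.replicate, data)


def sliding_window_score(track: SignalTrack, window: float = 300.0,
                         return_counts: bool = False):
    """Smooth scores with a centred sliding window (default 300 bp).

    Each probe's score becomes the mean over all probes on the same
    chromosome whose position lies within ``window/2`` of it (both ends
    closed). Isolated probes keep their own score.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    half = window / 2.0
    data = {}
    counts: dict[str, np.ndarray] = {}
    for c, (pos, score) in track.data.items():
        lo = np.searchsorted(pos, pos - half, side="left")
        hi = np.searchsorted(pos, pos + half, side="right")
        csum = np.concatenate(([0.0], np.cumsum(score)))
        n = hi - lo
        data[c] = (pos, (csum[hi] - csum[lo]) / n)
        counts[c] = n
    smoothed = SignalTrack(track.sample, track.replicate, data)
    return (smoothed, counts) if return_counts else smoothed


def _require_same_positions(tracks: Sequence[SignalTrack]) -> None:
    ref = tracks[0]
    for t in tracks[1:]:
        if t.chroms != ref.chroms:
            raise ValueError("tracks cover different chromosome sets")
        for c in ref.chroms:
            if len(t.positions(c)) != len(ref.positions(c)) or np.any(
                t.positions(c) != ref.positions(c)
            ):
                raise ValueError(f"tracks disagree on probe positions ({c})")


def quantile_normalize_and_average(
    tracks: Sequence[SignalTrack],
) -> tuple[list[SignalTrack], SignalTrack]:
    """Quantile-normalize replicate tracks and average them per probe.

    After normalization every track has the same sorted score vector (the
    rank-wise mean of the inputs); tied values within a track receive the
    mean of the reference quantiles spanned by their ranks. The averaged
    track is the per-probe mean of the normalized tracks.
    """
    if len(tracks) < 2:
        raise ValueError("need at least two tracks")
    _require_same_positions(tracks)
    mat = np.column_stack([t.concat_scores() for t in tracks])
    n, k = mat.shape
    ref = np.sort(mat, axis=0).mean(axis=1)
    out = np.empty_like(mat)
    for j in range(k):
        order = np.argsort(mat[:, j], kind="stable")
        col = mat[order, j]
        vals = np.empty(n)
        change = np.flatnonzero(np.diff(col)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [n]))
        for s, e in zip(starts, ends):
            vals[s:e] = ref[s:e].mean()
        out[order, j] = vals
    normalized = [
        t.with_scores(out[:, j], replicate=t.replicate) for j, t in enumerate(tracks)
    ]
    averaged = tracks[0].with_scores(out.mean(axis=1), replicate="avg")
    return normalized, averaged


def track_correlation(track_a: SignalTrack, track_b: SignalTrack,
                      method: str = "spearman") -> float:
    """Correlation between two tracks over their shared probe positions."""
    xs, ys = [], []
    for c in sorted(set(track_a.chroms) & set(track_b.chroms)):
        pa, sa = track_a.data[c]
        pb, sb = track_b.data[c]
        common, ia, ib = np.intersect1d(pa, pb, return_indices=True)
        xs.append(sa[ia])
        ys.append(sb[ib])
    if not xs:
        raise ValueError("tracks share no probe positions")
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if len(x) < 3:
        raise ValueError("need at least 3 shared probes")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance; correlation undefined")
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Track export
# ---------------------------------------------------------------------------

def write_wig(track: SignalTrack, path: str | Path, name: str | None = None) -> None:
    """Export as variableStep WIG (1-based positions)."""
    with open(path, "w") as fh:
        fh.write(f'track type=wiggle_0 name="{name or track.sample}"\n')
        for c in track.chroms:
            pos, score = track.data[c]
            fh.write(f"variableStep chrom={c}\n")
            for p, s in zip(pos, score):
                fh.write(f"{p + 1}\t{s:.6g}\n")


def write_bedgraph(track: SignalTrack, path: str | Path, span: int = 1) -> None:
    """Export as bedGraph; each probe covers ``[pos, pos + span)``."""
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{track.sample}"\n')
        for c in track.chroms:
            pos, score = track.data[c]
            for p, s in zip(pos, score):
                fh.write(f"{c}\t{p}\t{p + span}\t{s:.6g}\n")
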