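"""Genome feature model, annotation I/O, and attribute-class assignment.

All coordinates inside the package are 0-based, half-open ``[start, end)``.
Conversion to and from 1-based inclusive coordinates happens only at the
GFF3 I/O boundary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Feature classes recognised by the pipeline.
FEATURE_CLASSES = (
    "ORF",
    "rDNA",
    "telomeric_repeat",
    "Ty1",
    "Ty2",
    "Ty3",
    "Ty4",
    "Ty5",
    "tRNA",
    "snoRNA",
)

TY_CLASSES = ("Ty1", "Ty2", "Ty3", "Ty4", "Ty5")


@dataclass(frozen=True, order=True)
class GenomeFeature:
    """A genomic interval with a class label.

    ``start``/``end`` are 0-based half-open base-pair coordinates.
    """

    chrom: str
    start: int
    end: int
    id: str
    strand: str = "."
    feature_class: str = "ORF"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"feature {self.id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"feature {self.id}: bad strand {self.strand!r}")
        if self.feature_class in ("ORF", "tRNA") and self.strand == ".":
            raise ValueError(
                f"feature {self.id}: {self.feature_class} features must be stranded"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


def _sorted(features: Iterable[GenomeFeature]) -> list[GenomeFeature]:
    return sorted(features, key=lambda f: (f.chrom, f.start, f.end, f.id))


# ---------------------------------------------------------------------------
# Feature I/O
# ---------------------------------------------------------------------------

def load_features(path: str | Path, format: str | None = None) -> list[GenomeFeature]:
    """Read genome features from BED6, GFF3 or a plain TSV.

    The format is inferred from the file suffix when not given. Coordinates
    are normalised to 0-based half-open (GFF3 input is 1-based inclusive).
    Returns features sorted by ``(chrom, start)``.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower().lstrip(".")
        format = {"bed": "BED", "gff3": "GFF3", "gff": "GFF3", "tsv": "TSV"}.get(
            suffix, "TSV"
        )
    format = format.upper()
    if format not in ("BED", "GFF3", "TSV"):
        raise ValueError(f"unknown feature format {format!r}")

    features: list[GenomeFeature] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                features.append(_parse_feature_line(line, format))
            except Exception as exc:  # noqa: BLE001 - re-raise with location
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    if not features:
        logger.warning("no features parsed from %s", path)
    return _sorted(features)


def _parse_feature_line(line: str, format: str) -> GenomeFeature:
    fields = line.split("\t") if "\t" in line else line.split()
    if format == "BED":
        if len(fields) < 4:
            raise ValueError("BED line needs at least 4 fields")
        chrom, start, end, name = fields[:4]
        strand = fields[5] if len(fields) > 5 else "."
        fclass = fields[6] if len(fields) > 6 else "ORF"
        return GenomeFeature(chrom, int(start), int(end), name, strand, fclass)
    if format == "GFF3":
        if len(fields) < 9:
            raise ValueError("GFF3 line needs 9 fields")
        chrom, _source, ftype, start, end, _score, strand, _phase, attrs = fields[:9]
        attr_map = dict(
            kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
        )
        name = attr_map.get("ID") or attr_map.get("Name")
        if name is None:
            raise ValueError("GFF3 attributes lack ID=")
        fclass = attr_map.get("feature_class", ftype)
        # GFF3 is 1-based inclusive
        return GenomeFeature(chrom, int(start) - 1, int(end), name, strand, fclass)
    # TSV: id, chrom, start, end, strand, feature_class (already half-open)
    if len(fields) < 6:
        raise ValueError("TSV feature line needs 6 fields")
    fid, chrom, start, end, strand, fclass = fields[:6]
    return GenomeFeature(chrom, int(start), int(end), fid, strand, fclass)


def write_features(
    features: Iterable[GenomeFeature], path: str | Path, format: str = "BED"
) -> None:
    """Write features as BED6 (+class column) or GFF3, sorted by position."""
    format = format.upper()
    feats = _sorted(features)
    with open(path, "w") as fh:
        if format == "BED":
            for f in feats:
                fh.write(
                    f"{f.chrom}\t{f.start}\t{f.end}\t{f.id}\t0\t{f.strand}"
                    f"\t{f.feature_class}\n"
                )
        elif format == "GFF3":
            fh.write("##gff-version 3\n")
            for f in feats:
                fh.write(
                    f"{f.chrom}\tdripchip\t{f.feature_class}\t{f.start + 1}\t{f.end}"
                    f"\t.\t{f.strand}\t.\tID={f.id};feature_class={f.feature_class}\n"
                )
        else:
            raise ValueError(f"unknown output format {format!r}")


# ---------------------------------------------------------------------------
# Sequence utilities
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into ``{name: sequence}`` (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def compute_gc(sequence: str) -> float:
    """GC fraction of a nucleotide string; ``N`` bases are ignored.

    Raises ``ValueError`` for an empty sequence, an all-N sequence, or
    characters outside ``ACGTN``.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    counts = {b: seq.count(b) for b in "ACGTN"}
    total = sum(counts.values())
    if total != len(seq):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"non-ACGTN characters in sequence: {bad}")
    denom = total - counts["N"]
    if denom == 0:
        raise ValueError("sequence is all N; GC fraction undefined")
    return (counts["G"] + counts["C"]) / denom


def compute_at(sequence: str) -> float:
    """AT fraction, the complement of :func:`compute_gc` on N-free input."""
    return 1.0 - compute_gc(sequence)


# ---------------------------------------------------------------------------
# Per-gene attribute table
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = ("txn_frequency", "gc_fraction", "antisense", "half_life")


def load_annotations(path: str | Path) -> pd.DataFrame:
    """Read the per-gene attribute TSV.

    Columns: ``id``, ``txn_frequency`` (mRNA/h), ``gc_fraction`` (0..1),
    ``antisense`` (bool), ``half_life`` (min, may be empty). Indexed by id.
    """
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    missing = [c for c in ("id",) + ANNOTATION_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {missing}")
    df = df.set_index("id")
    df["antisense"] = df["antisense"].astype(bool)
    bad_gc = df["gc_fraction"].dropna()
    if ((bad_gc < 0) | (bad_gc > 1)).any():
        raise ValueError("gc_fraction outside [0, 1]")
    if (df["txn_frequency"].dropna() < 0).any():
        raise ValueError("negative txn_frequency")
    return df


def write_annotations(annotations: pd.DataFrame, path: str | Path) -> None:
    annotations.to_csv(path, sep="\t", index_label="id")


# ---------------------------------------------------------------------------
# Class assignment (transcriptional-frequency quintiles, GC quartiles)
# ---------------------------------------------------------------------------

def _classify(values: pd.Series, breaks: Sequence[float] | None, n_classes: int,
              what: str) -> pd.Series:
    vals = values.dropna()
    excluded = values.index.difference(vals.index)
    if len(excluded):
        logger.info("%s classes: %d features lack the attribute and are excluded",
                    what, len(excluded))
    if breaks is not None:
        edges = np.asarray(breaks, dtype=float)
        if np.any(np.diff(edges) <= 0):
            raise ValueError(f"{what} breakpoints must be strictly increasing")
        interior = edges[1:-1]
        out_of_range = vals[(vals <= edges[0]) | (vals > edges[-1])]
        if len(out_of_range):
            raise ValueError(
                f"{what}: {len(out_of_range)} values outside ({edges[0]}, {edges[-1]}]"
            )
    else:
        if vals.nunique() == 1:
            warnings.warn(f"{what}: all values identical; single class", stacklevel=3)
            return pd.Series(1, index=vals.index, dtype=int)
        n = len(vals)
        sorted_vals = np.sort(vals.to_numpy())
        interior = np.array(
            [sorted_vals[n * j // n_classes - 1] for j in range(1, n_classes)]
        )
    # value in (edge_{k-1}, edge_k] -> class k; ties at an edge go to the
    # lower class, deterministically.
    cls = np.searchsorted(interior, vals.to_numpy(), side="left") + 1
    return pd.Series(cls, index=vals.index, dtype=int)


def assign_classes(
    annotations: pd.DataFrame,
    txn_breaks: Sequence[float] | None = None,
    n_txn_classes: int = 5,
    gc_breaks: Sequence[float] | None = None,
    n_gc_classes: int = 4,
) -> pd.DataFrame:
    """Group genes into transcriptional-frequency and GC-content classes.

    By default genes are split into five transcriptional-frequency classes
    (quintiles) and four GC classes (quartiles) of the supplied annotation;
    explicit breakpoints (a monotone edge sequence, classes are the
    half-open-on-the-left intervals ``(e[k-1], e[k]]``) override the
    quantile scheme. Returns a frame with ``txn_class`` and ``gc_class``.
    """
    txn = _classify(annotations["txn_frequency"], txn_breaks, n_txn_classes,
                    "txn_frequency")
    gc = _classify(annotations["gc_fraction"], gc_breaks, n_gc_classes,
                   "gc_fraction")
    return pd.DataFrame({"txn_class": txn, "gc_class": gc})
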