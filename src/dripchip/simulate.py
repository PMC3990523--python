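"""Synthetic toy genomes, probe tracks, expression tables and spread counts.

The generator emulates the statistical structure of a budding-yeast
DRIP-chip study at desk scale: a multi-chromosome genome (~270 kb vs the
real 12 Mb) carrying ORFs whose GC content correlates with transcriptional
frequency, a tandem rDNA array, telomeric repeat ends, Ty1-Ty5
retrotransposons with class-specific expression (Ty1 > Ty2 >> Ty3 ~ Ty4,
Ty5 silent), and tRNA/snoRNA genes. Probes are laid at regular spacing
(default 25 bp vs the real ~5 bp); mock intensities are lognormal and the
IP channel gains a multiplicative lift inside hybrid-prone features, so
that the relative-occupancy ratio at a lifted probe is centred on
``1 + lift``. Expression data plants a responder set, mostly
antisense-associated and of low transcriptional frequency, that changes
over 2-fold under a simulated RNase-H perturbation. Spread counts are
binomial draws per replicate. Every generator records its ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .annotation import GenomeFeature

# stream offsets so each generator stage has its own reproducible substream
_STREAM_GENOME = 1
_STREAM_TRACKS = 2
_STREAM_EXPRESSION = 3
_STREAM_SPREADS = 4


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream])


def _default_ty_counts() -> dict[str, int]:
    return {"Ty1": 4, "Ty2": 3, "Ty3": 2, "Ty4": 2, "Ty5": 1}


def _default_ty_txn() -> dict[str, float]:
    # expression ordering Ty1 > Ty2 >> Ty3 ~ Ty4, Ty5 silent
    return {"Ty1": 40.0, "Ty2": 15.0, "Ty3": 2.0, "Ty4": 2.0, "Ty5": 0.0}


def _default_ty_gc() -> dict[str, float]:
    # Ty3 has the highest GC despite modest expression
    return {"Ty1": 0.41, "Ty2": 0.41, "Ty3": 0.47, "Ty4": 0.42, "Ty5": 0.40}


def _default_class_lift() -> dict[str, float]:
    # multiplicative IP lift per feature class; scores at lifted probes sit
    # near 1 + lift, against the 1.5 calling threshold
    return {
        "rDNA": 1.2,
        "telomeric_repeat": 0.9,
        "Ty1": 1.2,
        "Ty2": 0.9,
        "Ty3": 0.1,
        "Ty4": 0.1,
        "Ty5": 0.0,
        "tRNA": 0.0,
        "snoRNA": 0.0,
    }


@dataclass
class SimulationConfig:
    seed: int = 0
    chromosome_lengths: tuple[int, ...] = (120_000, 90_000, 60_000)
    probe_spacing: int = 25
    n_replicates: int = 2

    # features
    n_orfs: int = 150
    orf_log_length_mean: float = 6.8     # ~900 bp median
    orf_log_length_sd: float = 0.45
    orf_min_length: int = 300
    orf_max_length: int = 3000
    n_rdna_units: int = 2
    rdna_unit_length: int = 5000
    telomere_length: int = 300
    ty_counts: dict[str, int] = field(default_factory=_default_ty_counts)
    ty_length: int = 3000
    n_trna: int = 20
    trna_length: int = 80
    n_snorna: int = 10
    snorna_length: int = 150
    placement_gap_range: tuple[int, int] = (50, 400)

    # ORF attributes
    gc_txn_correlation: float = 0.3
    gc_mean: float = 0.40
    gc_sd: float = 0.05
    txn_log_mean: float = 1.6            # mRNA/h, lognormal
    txn_log_sd: float = 1.0
    antisense_fraction: float = 0.37
    antisense_prob_hybrid: float = 0.60

    # hybrid-prone sampling for ORFs: logistic in standardized txn and GC
    hybrid_logit_intercept: float = -1.0
    hybrid_logit_txn: float = 0.8
    hybrid_logit_gc: float = 0.8
    orf_hybrid_lift: float = 1.0
    class_lift: dict[str, float] = field(default_factory=_default_class_lift)
    ty_txn: dict[str, float] = field(default_factory=_default_ty_txn)
    ty_gc: dict[str, float] = field(default_factory=_default_ty_gc)

    # probe signal model
    mock_median: float = 100.0
    mock_log_sd: float = 0.2
    noise_log_sd: float = 0.1

    # expression arm; responders are kept a modest fraction of the universe
    # so the planted effect does not distort global median scaling
    n_up_responders: int = 25
    n_down_responders: int = 10
    responder_fold: float = 4.0
    responder_antisense_prob: float = 0.8
    expression_log_mean: float = 6.2     # ~500 median signal
    expression_log_sd: float = 0.8
    # responders are planted on well-expressed genes so that a full
    # responder_fold drop still clears the 100-unit detection floor
    responder_base_min: float = 1000.0
    expression_noise_sd: float = 0.1
    detection_p_max: float = 0.04
    absent_fraction: float = 0.05

    # spreads arm
    wt_spread_rate: float = 0.02
    n_spread_replicates: int = 3
    n_nuclei_per_replicate: int = 100

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(len(self.chromosome_lengths))]

    def chrom_lengths(self) -> dict[str, int]:
        return dict(zip(self.chrom_names(), self.chromosome_lengths))


@dataclass
class GroundTruth:
    hybrid_prone_ids: frozenset[str]
    lifts: dict[str, float]              # feature id -> IP lift delta
    up_responders: frozenset[str]
    down_responders: frozenset[str]
    spread_rates: dict[str, float] = field(default_factory=dict)


@dataclass
class ToyGenome:
    sequences: dict[str, str]
    features: list[GenomeFeature]
    annotations: pd.DataFrame
    ground_truth: GroundTruth
    config: SimulationConfig

    def features_of_class(self, *classes: str) -> list[GenomeFeature]:
        return [f for f in self.features if f.feature_class in classes]


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------

def _draw_orf_attributes(cfg: SimulationConfig, rng: np.random.Generator,
                         n: int) -> tuple[np.ndarray, np.ndarray]:
    """Correlated (txn_frequency, gc_fraction) via a Gaussian copula."""
    rho = cfg.gc_txn_correlation
    z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
    txn = np.exp(cfg.txn_log_mean + cfg.txn_log_sd * z[:, 0])
    gc = np.clip(cfg.gc_mean + cfg.gc_sd * z[:, 1], 0.25, 0.65)
    return txn, gc


def _place_features(cfg: SimulationConfig, rng: np.random.Generator,
                    queue: list[tuple[str, int, str]]) -> list[GenomeFeature]:
    """Lay features left-to-right with random gaps; telomeric repeats pinned
    to chromosome ends, rDNA tandem on the second chromosome."""
    names = cfg.chrom_names()
    lengths = cfg.chrom_lengths()
    features: list[GenomeFeature] = []
    for c in names:
        L = lengths[c]
        features.append(GenomeFeature(c, 0, cfg.telomere_length,
                                      f"TEL_{c}_L", ".", "telomeric_repeat"))
        features.append(GenomeFeature(c, L - cfg.telomere_length, L,
                                      f"TEL_{c}_R", ".", "telomeric_repeat"))
    # tandem rDNA array mid-way along the second chromosome
    rdna_chrom = names[min(1, len(names) - 1)]
    rdna_start = lengths[rdna_chrom] // 3
    cursor_override: dict[str, list[tuple[int, int]]] = {c: [] for c in names}
    for i in range(cfg.n_rdna_units):
        s = rdna_start + i * cfg.rdna_unit_length
        features.append(GenomeFeature(rdna_chrom, s, s + cfg.rdna_unit_length,
                                      f"RDN_{i + 1}", "+", "rDNA"))
    cursor_override[rdna_chrom].append(
        (rdna_start, rdna_start + cfg.n_rdna_units * cfg.rdna_unit_length)
    )

    order = rng.permutation(len(queue))
    remaining = [queue[i] for i in order]
    lo, hi = cfg.placement_gap_range
    for c in names:
        cursor = cfg.telomere_length + int(rng.integers(lo, hi))
        limit = lengths[c] - cfg.telomere_length
        blocked = sorted(cursor_override[c])
        while remaining:
            fid, flen, fclass = remaining[-1]
            end = cursor + flen
            for bs, be in blocked:
                if cursor < be and end > bs:
                    cursor = be + int(rng.integers(lo, hi))
                    end = cursor + flen
            if end > limit:
                break
            remaining.pop()
            strand = "+" if rng.random() < 0.5 else "-"
            if fclass == "snoRNA" and strand == ".":
                strand = "+"
            features.append(GenomeFeature(c, cursor, end, fid, strand, fclass))
            cursor = end + int(rng.integers(lo, hi))
    if remaining:
        raise ValueError(
            f"features exceed genome capacity: {len(remaining)} unplaced"
        )
    return sorted(features, key=lambda f: (f.chrom, f.start))


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.frombuffer(b"AGCT", dtype="S1"), size=n, p=p)


def generate_toy_genome(config: SimulationConfig | None = None) -> ToyGenome:
    """Build the toy genome: sequences, features, annotations, ground truth.

    ORF GC content is written into the FASTA so that recomputation from
    sequence approximates the annotated ``gc_fraction``.
    """
    cfg = config or SimulationConfig()
    rng = _rng(cfg.seed, _STREAM_GENOME)

    # feature queue: (id, length, class)
    queue: list[tuple[str, int, str]] = []
    orf_lengths = np.clip(
        np.exp(rng.normal(cfg.orf_log_length_mean, cfg.orf_log_length_sd,
                          cfg.n_orfs)).astype(int),
        cfg.orf_min_length, cfg.orf_max_length,
    )
    for i, L in enumerate(orf_lengths):
        queue.append((f"ORF{i + 1:04d}", int(L), "ORF"))
    for ty_class, count in cfg.ty_counts.items():
        for i in range(count):
            queue.append((f"{ty_class}_{i + 1}", cfg.ty_length, ty_class))
    for i in range(cfg.n_trna):
        queue.append((f"tRNA{i + 1:03d}", cfg.trna_length, "tRNA"))
    for i in range(cfg.n_snorna):
        queue.append((f"snoRNA{i + 1:03d}", cfg.snorna_length, "snoRNA"))

    features = _place_features(cfg, rng, queue)
    by_class: dict[str, list[GenomeFeature]] = {}
    for f in features:
        by_class.setdefault(f.feature_class, []).append(f)

    # --- per-gene attributes -------------------------------------------------
    orfs = by_class.get("ORF", [])
    txn, gc = _draw_orf_attributes(cfg, rng, len(orfs))
    half_life = np.exp(rng.normal(3.0, 0.4, len(orfs)))  # minutes, ~20 median

    # hybrid-prone ORFs: probability increasing in txn frequency and GC
    z_txn = (np.log(txn) - np.log(txn).mean()) / np.log(txn).std()
    z_gc = (gc - gc.mean()) / gc.std()
    p_hybrid = expit(cfg.hybrid_logit_intercept + cfg.hybrid_logit_txn * z_txn
                     + cfg.hybrid_logit_gc * z_gc)
    hybrid_orf = rng.random(len(orfs)) < p_hybrid

    # antisense flags enriched among hybrid-prone ORFs, overall fraction
    # held near the configured background
    n, nh = len(orfs), int(hybrid_orf.sum())
    p_hot = cfg.antisense_prob_hybrid
    p_bg = ((cfg.antisense_fraction * n - p_hot * nh) / (n - nh)
            if n > nh else cfg.antisense_fraction)
    p_bg = float(np.clip(p_bg, 0.05, 1.0))
    antisense = np.where(hybrid_orf, rng.random(n) < p_hot, rng.random(n) < p_bg)

    rows = []
    for i, f in enumerate(orfs):
        rows.append({"id": f.id, "txn_frequency": txn[i], "gc_fraction": gc[i],
                     "antisense": bool(antisense[i]),
                     "half_life": half_life[i], "length": f.length})
    for ty_class in cfg.ty_counts:
        for f in by_class.get(ty_class, []):
            rows.append({"id": f.id, "txn_frequency": cfg.ty_txn[ty_class],
                         "gc_fraction": cfg.ty_gc[ty_class], "antisense": True,
                         "half_life": np.nan, "length": f.length})
    for fclass, tf, gcv in (("rDNA", 100.0, 0.45), ("telomeric_repeat", 0.5, 0.30),
                            ("tRNA", 50.0, 0.45), ("snoRNA", 20.0, 0.40)):
        for f in by_class.get(fclass, []):
            rows.append({"id": f.id, "txn_frequency": tf, "gc_fraction": gcv,
                         "antisense": False, "half_life": np.nan,
                         "length": f.length})
    annotations = pd.DataFrame(rows).set_index("id")

    # --- hybrid-prone ground truth and lifts --------------------------------
    lifts: dict[str, float] = {}
    for fclass, delta in cfg.class_lift.items():
        for f in by_class.get(fclass, []):
            lifts[f.id] = delta
    for i, f in enumerate(orfs):
        lifts[f.id] = cfg.orf_hybrid_lift if hybrid_orf[i] else 0.0
    hybrid_ids = frozenset(fid for fid, d in lifts.items() if d >= 0.5)

    # --- expression responders ----------------------------------------------
    orf_ids = np.array([f.id for f in orfs])
    as_pool = orf_ids[antisense]
    non_pool = orf_ids[~antisense]
    # weight antisense picks toward low transcriptional frequency
    w = 1.0 / np.sqrt(txn[antisense]) if antisense.any() else np.array([])

    def _pick(k: int, taken: set[str]) -> list[str]:
        picked: list[str] = []
        avail_as = [g for g in as_pool if g not in taken]
        avail_non = [g for g in non_pool if g not in taken]
        wa = np.array([w[list(as_pool).index(g)] for g in avail_as]) \
            if avail_as else np.array([])
        for _ in range(k):
            use_as = avail_as and (not avail_non
                                   or rng.random() < cfg.responder_antisense_prob)
            if use_as:
                pw = wa / wa.sum()
                j = int(rng.choice(len(avail_as), p=pw))
                picked.append(avail_as.pop(j))
                wa = np.delete(wa, j)
            elif avail_non:
                j = int(rng.integers(len(avail_non)))
                picked.append(avail_non.pop(j))
            else:
                break
        return picked

    up = _pick(cfg.n_up_responders, set())
    down = _pick(cfg.n_down_responders, set(up))

    truth = GroundTruth(
        hybrid_prone_ids=hybrid_ids,
        lifts=lifts,
        up_responders=frozenset(up),
        down_responders=frozenset(down),
    )

    # --- sequences -----------------------------------------------------------
    sequences: dict[str, str] = {}
    gc_by_id = annotations["gc_fraction"].to_dict()
    for c, L in cfg.chrom_lengths().items():
        arr = _random_seq(rng, L, 0.38)
        for f in features:
            if f.chrom == c:
                arr[f.start:f.end] = _random_seq(rng, f.length, gc_by_id[f.id])
        sequences[c] = arr.tobytes().decode()

    return ToyGenome(sequences, features, annotations, truth, cfg)


# ---------------------------------------------------------------------------
# Probe tracks
# ---------------------------------------------------------------------------

def simulate_drip_tracks(genome: ToyGenome,
                         config: SimulationConfig | None = None
                         ) -> list[pd.DataFrame]:
    """IP/mock probe tables, one per replicate.

    Probes sit at regular spacing. Mock intensity is lognormal around the
    configured median; IP = mock * (1 + lift) * lognormal noise, with the
    lift taken from the planted ground truth of whichever feature contains
    the probe midpoint (max over overlapping features). Replicate noise is
    independent.
    """
    cfg = config or genome.config
    rng = _rng(cfg.seed, _STREAM_TRACKS)
    lengths = genome.config.chrom_lengths()

    frames = []
    chrom_col, pos_col, lift_col = [], [], []
    for c in genome.config.chrom_names():
        pos = np.arange(cfg.probe_spacing // 2, lengths[c], cfg.probe_spacing,
                        dtype=np.int64)
        lift = np.zeros(len(pos))
        for f in genome.features:
            if f.chrom != c:
                continue
            delta = genome.ground_truth.lifts.get(f.id, 0.0)
            if delta <= 0:
                continue
            i = np.searchsorted(pos, f.start, side="left")
            j = np.searchsorted(pos, f.end, side="left")
            lift[i:j] = np.maximum(lift[i:j], delta)
        chrom_col.append(np.full(len(pos), c))
        pos_col.append(pos)
        lift_col.append(lift)
    chrom_all = np.concatenate(chrom_col)
    pos_all = np.concatenate(pos_col)
    lift_all = np.concatenate(lift_col)

    for _rep in range(cfg.n_replicates):
        mock = np.exp(rng.normal(np.log(cfg.mock_median), cfg.mock_log_sd,
                                 len(pos_all)))
        noise = np.exp(rng.normal(0.0, cfg.noise_log_sd, len(pos_all)))
        ip = mock * (1.0 + lift_all) * noise
        frames.append(pd.DataFrame({
            "chrom": chrom_all, "pos": pos_all,
            "ip": ip.round(3), "mock": mock.round(3),
        }))
    return frames


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def simulate_expression(genome: ToyGenome,
                        config: SimulationConfig | None = None) -> pd.DataFrame:
    """Long-format expression records for control and RNase-H treatment.

    Planted up-responders gain ``responder_fold`` in treatment, planted
    down-responders lose it; everything else stays near 1-fold with
    lognormal noise. Responder baselines are floored so that both
    directions stay above the detection signal cutoff. A small fraction of
    non-responder genes is "absent" (high detection p, low signal).
    """
    cfg = config or genome.config
    rng = _rng(cfg.seed, _STREAM_EXPRESSION)
    truth = genome.ground_truth
    orf_ids = [f.id for f in genome.features_of_class("ORF")]

    base = np.exp(rng.normal(cfg.expression_log_mean, cfg.expression_log_sd,
                             len(orf_ids)))
    fc = np.ones(len(orf_ids))
    absent = rng.random(len(orf_ids)) < cfg.absent_fraction
    for i, tid in enumerate(orf_ids):
        if tid in truth.up_responders:
            fc[i] = cfg.responder_fold
        elif tid in truth.down_responders:
            fc[i] = 1.0 / cfg.responder_fold
        if fc[i] != 1.0:
            base[i] = max(base[i], cfg.responder_base_min)
            absent[i] = False

    rows = []
    for rep in (1, 2):
        for cond, mult in (("control", 1.0), ("treatment", None)):
            noise = np.exp(rng.normal(0, cfg.expression_noise_sd, len(orf_ids)))
            sig = base * (fc if mult is None else mult) * noise
            det = rng.uniform(0.0005, cfg.detection_p_max, len(orf_ids))
            det[absent] = rng.uniform(0.2, 0.8, int(absent.sum()))
            sig[absent] = rng.uniform(5, 60, int(absent.sum()))
            sample = f"{cond}_{rep}"
            for i, tid in enumerate(orf_ids):
                rows.append((tid, sample, cond, rep, sig[i], det[i]))
    return pd.DataFrame(
        rows, columns=["id", "sample", "condition", "replicate", "signal",
                       "detection_p"],
    )


# ---------------------------------------------------------------------------
# Spread counts
# ---------------------------------------------------------------------------

def simulate_spread_counts(
    strain_rates: Mapping[str, float],
    config: SimulationConfig | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Binomial spread counts per strain and replicate.

    ``strain_rates`` maps strain id -> per-nucleus hybrid-positive rate;
    include the wild type (e.g. ``{"WT": 0.02, "mutantA": 0.25}``).
    """
    cfg = config or SimulationConfig()
    rng = _rng(seed if seed is not None else cfg.seed, _STREAM_SPREADS)
    rows = []
    for strain in strain_rates:
        rate = strain_rates[strain]
        if not 0 <= rate <= 1:
            raise ValueError(f"{strain}: rate {rate} outside [0, 1]")
        for rep in range(1, cfg.n_spread_replicates + 1):
            pos = int(rng.binomial(cfg.n_nuclei_per_replicate, rate))
            rows.append((strain, rep, cfg.n_nuclei_per_replicate, pos))
    return pd.DataFrame(rows, columns=["strain", "replicate", "n_nuclei",
                                       "n_positive"])
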