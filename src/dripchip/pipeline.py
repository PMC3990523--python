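"""End-to-end pipeline: simulate (or load) -> normalize -> smooth ->
quantile-normalize/average -> enrichment calls -> consensus -> Monte Carlo
-> profiles -> association report. Writes every intermediate with a
manifest of SHA-256 checksums and the resolved configuration."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .annotation import (
    TY_CLASSES,
    load_annotations,
    load_features,
    write_annotations,
    write_fasta,
    write_features,
)
from .enrichment import call_feature_enrichment, calls_table, consensus_calls, \
    export_enriched_regions
from .expression import filter_modulated, median_scale, \
    modulated_set_characterization, read_expression_table, write_expression_table
from .montecarlo import monte_carlo_class_enrichment, write_results
from .profiles import average_gene_profile, chromatra_matrix, \
    small_feature_profile
from .signal import (
    SignalTrack,
    mock_normalize,
    quantile_normalize_and_average,
    read_probe_table,
    sliding_window_score,
    track_correlation,
    write_probe_table,
    write_wig,
)
from .simulate import SimulationConfig, generate_toy_genome, \
    simulate_drip_tracks, simulate_expression
from .stats import set_association

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Numeric defaults follow the study design this pipeline models:
    enrichment threshold 1.5, at-least-half probe fraction, 300 bp
    smoothing window, 150 bp matrix bins, 40/20/3 profile bins, 500 Monte
    Carlo simulations, screen alpha 0.01."""

    outdir: str = "dripchip_out"
    seed: int = 0
    simulate: bool = True
    probe_tables: tuple[str, ...] = ()   # used when simulate=False
    features_path: str | None = None
    annotations_path: str | None = None
    expression_path: str | None = None

    pseudocount: float = 1.0
    window: float = 300.0
    smooth_before_quantile: bool = True
    threshold: float = 1.5
    min_fraction: float = 0.5
    bin_size: int = 150
    n_body_bins: int = 40
    utr_bp: int = 1500
    n_utr_bins: int = 20
    n_small_bins: int = 3
    n_sims: int = 500
    alpha: float = 0.01
    sim: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        if isinstance(self.sim, dict):
            self.sim = SimulationConfig(**self.sim)
        self.sim = dataclasses.replace(self.sim, seed=self.seed)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full analysis; returns the output directory.

    With ``simulate=True`` a seeded toy genome and probe tracks are
    generated first; otherwise probe tables, features and annotations are
    read from the configured paths.
    """
    cfg = config
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "pipeline.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("dripchip")
    root.addHandler(fh)
    root.setLevel(logging.INFO)
    artifacts: list[Path] = []

    def save(path: Path) -> Path:
        artifacts.append(path)
        return path

    try:
        resolved = dataclasses.asdict(cfg)
        (out / "config.yaml").write_text(yaml.safe_dump(resolved, sort_keys=True))
        save(out / "config.yaml")
        logger.info("dripchip %s seed=%d", __version__, cfg.seed)

        # ---- stage: inputs -------------------------------------------------
        expression = None
        if cfg.simulate:
            genome = generate_toy_genome(cfg.sim)
            features = genome.features
            annotations = genome.annotations
            write_fasta(genome.sequences, save(out / "genome.fasta"))
            write_features(features, save(out / "features.gff3"), "GFF3")
            write_annotations(annotations, save(out / "annotations.tsv"))
            probe_frames = simulate_drip_tracks(genome, cfg.sim)
            for i, df in enumerate(probe_frames, start=1):
                write_probe_table(df, save(out / f"probes_rep{i}.tsv"))
            expression = simulate_expression(genome, cfg.sim)
            write_expression_table(expression, save(out / "expression.tsv"))
            truth = {
                "hybrid_prone_ids": sorted(genome.ground_truth.hybrid_prone_ids),
                "up_responders": sorted(genome.ground_truth.up_responders),
                "down_responders": sorted(genome.ground_truth.down_responders),
            }
            (out / "ground_truth.json").write_text(json.dumps(truth, indent=1))
            save(out / "ground_truth.json")
            chrom_lengths = cfg.sim.chrom_lengths()
        else:
            if not cfg.probe_tables or cfg.features_path is None \
                    or cfg.annotations_path is None:
                raise FileNotFoundError(
                    "simulate=False requires probe_tables, features_path and "
                    "annotations_path"
                )
            features = load_features(cfg.features_path)
            annotations = load_annotations(cfg.annotations_path)
            probe_frames = [read_probe_table(p) for p in cfg.probe_tables]
            if cfg.expression_path:
                expression = read_expression_table(cfg.expression_path)
            chrom_lengths = {}
            for df in probe_frames:
                for chrom, grp in df.groupby("chrom"):
                    chrom_lengths[str(chrom)] = max(
                        chrom_lengths.get(str(chrom), 0), int(grp["pos"].max()) + 1
                    )
            for f in features:
                chrom_lengths[f.chrom] = max(chrom_lengths.get(f.chrom, 0), f.end)

        # ---- stage: signal processing --------------------------------------
        tracks: list[SignalTrack] = []
        for i, df in enumerate(probe_frames, start=1):
            t = mock_normalize(df, cfg.pseudocount, sample="drip",
                               replicate=str(i))
            if cfg.smooth_before_quantile:
                t = sliding_window_score(t, cfg.window)
            tracks.append(t)
        normalized, averaged = quantile_normalize_and_average(tracks)
        if not cfg.smooth_before_quantile:
            normalized = [sliding_window_score(t, cfg.window) for t in normalized]
            averaged = sliding_window_score(averaged, cfg.window)
        rho = track_correlation(normalized[0], normalized[1]) \
            if len(normalized) >= 2 else float("nan")
        logger.info("replicate spearman rho = %.4f", rho)
        for t in normalized:
            write_wig(t, save(out / f"track_rep{t.replicate}.wig"))
        write_wig(averaged, save(out / "track_avg.wig"))

        # ---- stage: enrichment calls ---------------------------------------
        calls = [
            call_feature_enrichment(t, features, cfg.threshold, cfg.min_fraction)
            for t in normalized[:2]
        ]
        consensus = consensus_calls(calls[0], calls[1])
        calls_table(calls[0], calls[1]).to_csv(
            save(out / "enrichment_calls.tsv"), sep="\t", index=False
        )
        export_enriched_regions(consensus, features,
                                save(out / "consensus_enriched.bed"))
        logger.info("consensus enriched features: %d", len(consensus))

        # ---- stage: Monte Carlo per feature class --------------------------
        class_sets: dict[str, list] = {}
        for f in features:
            class_sets.setdefault(f.feature_class, []).append(f)
        antisense_ids = set(annotations.index[annotations["antisense"]])
        orf_feats = class_sets.get("ORF", [])
        class_sets["antisense_gene"] = [f for f in orf_feats
                                        if f.id in antisense_ids]
        mc_results = []
        for label in ("rDNA", "telomeric_repeat", *TY_CLASSES, "tRNA",
                      "snoRNA", "antisense_gene"):
            members = class_sets.get(label)
            if not members:
                continue
            mc_results.append(
                monte_carlo_class_enrichment(
                    averaged, members, chrom_lengths, n_sims=cfg.n_sims,
                    threshold=cfg.threshold, min_fraction=cfg.min_fraction,
                    seed=cfg.seed, feature_class=label,
                )
            )
        write_results(mc_results, save(out / "montecarlo.tsv"))

        # ---- stage: profiles ------------------------------------------------
        if orf_feats:
            cm = chromatra_matrix(averaged, orf_feats, annotations,
                                  cfg.bin_size, order="length")
            cm.write(save(out / "chromatra_length.tsv"),
                     save(out / "chromatra_length_rows.tsv"))
            prof = average_gene_profile(averaged, orf_feats, cfg.n_body_bins,
                                        cfg.utr_bp, cfg.n_utr_bins)
            prof.write(save(out / "profile_genes.tsv"))
        for label in ("tRNA", "snoRNA"):
            members = class_sets.get(label)
            if members:
                small_feature_profile(averaged, members, cfg.n_small_bins).write(
                    save(out / f"profile_{label}.tsv")
                )

        # ---- stage: associations -------------------------------------------
        universe = set(annotations.index)
        enriched_orfs = {f.id for f in orf_feats} & consensus
        assoc = set_association(enriched_orfs & universe, universe,
                                antisense_ids)
        summary = {
            "replicate_spearman_rho": rho,
            "n_consensus_enriched": len(consensus),
            "n_enriched_orfs": len(enriched_orfs),
            "antisense_percent_of_enriched": assoc.percent_annotated,
            "antisense_fisher_p": assoc.p_value,
        }

        # ---- stage: expression ----------------------------------------------
        if expression is not None:
            scaled = median_scale(expression)
            mod = filter_modulated(scaled)
            (out / "upregulated_ids.txt").write_text("\n".join(mod.up) + "\n")
            (out / "downregulated_ids.txt").write_text("\n".join(mod.down) + "\n")
            save(out / "upregulated_ids.txt")
            save(out / "downregulated_ids.txt")
            report = modulated_set_characterization(mod.up, mod.down,
                                                    annotations)
            report.to_csv(save(out / "expression_report.tsv"), sep="\t",
                          index=False)
            summary["n_upregulated"] = len(mod.up)
            summary["n_downregulated"] = len(mod.down)

        (out / "summary.json").write_text(json.dumps(summary, indent=1))
        save(out / "summary.json")

        manifest = {p.name: _sha256(p) for p in sorted(artifacts)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    finally:
        root.removeHandler(fh)
        fh.close()
    return out
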