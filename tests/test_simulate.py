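import numpy as np
import pandas as pd
import pytest

from dripchip.annotation import compute_gc, load_features
from dripchip.enrichment import call_feature_enrichment, consensus_calls
from dripchip.expression import filter_modulated, median_scale
from dripchip.signal import (
    mock_normalize,
    quantile_normalize_and_average,
    sliding_window_score,
    track_correlation,
)
from dripchip.simulate import (
    SimulationConfig,
    generate_toy_genome,
    simulate_drip_tracks,
    simulate_expression,
    simulate_spread_counts,
)


class TestGenomeGeneration:
    def test_deterministic_under_seed(self):
        a = generate_toy_genome(SimulationConfig(seed=3))
        b = generate_toy_genome(SimulationConfig(seed=3))
        assert a.features == b.features
        assert a.sequences == b.sequences
        pd.testing.assert_frame_equal(a.annotations, b.annotations)
        assert a.ground_truth.hybrid_prone_ids == b.ground_truth.hybrid_prone_ids

    def test_feature_census(self, toy_genome):
        cfg = toy_genome.config
        by_class = {}
        for f in toy_genome.features:
            by_class[f.feature_class] = by_class.get(f.feature_class, 0) + 1
        assert by_class["ORF"] == cfg.n_orfs
        assert by_class["rDNA"] == cfg.n_rdna_units
        assert by_class["tRNA"] == cfg.n_trna
        assert by_class["snoRNA"] == cfg.n_snorna
        assert by_class["telomeric_repeat"] == 2 * len(cfg.chromosome_lengths)
        for ty, n in cfg.ty_counts.items():
            assert by_class[ty] == n

    def test_features_fit_and_do_not_overlap(self, toy_genome):
        lengths = toy_genome.config.chrom_lengths()
        by_chrom = {}
        for f in toy_genome.features:
            assert 0 <= f.start < f.end <= lengths[f.chrom]
            by_chrom.setdefault(f.chrom, []).append(f)
        for feats in by_chrom.values():
            feats.sort(key=lambda f: f.start)
            for a, b in zip(feats, feats[1:]):
                assert a.end <= b.start, f"{a.id} overlaps {b.id}"

    def test_ty5_is_silent_and_ordering_holds(self, toy_genome):
        ann = toy_genome.annotations
        ty = {c: ann.loc[[f.id for f in toy_genome.features_of_class(c)],
                         "txn_frequency"].mean()
              for c in ("Ty1", "Ty2", "Ty3", "Ty4", "Ty5")}
        assert ty["Ty5"] == 0.0
        assert ty["Ty1"] > ty["Ty2"] > ty["Ty3"] == ty["Ty4"]

    def test_gc_txn_correlation_configurable(self):
        g0 = generate_toy_genome(SimulationConfig(seed=11, n_orfs=2000,
                                                  gc_txn_correlation=0.0,
                                                  chromosome_lengths=(2_500_000,),
                                                  n_rdna_units=1))
        orfs = [f.id for f in g0.features_of_class("ORF")]
        ann = g0.annotations.loc[orfs]
        r = np.corrcoef(np.log(ann["txn_frequency"]), ann["gc_fraction"])[0, 1]
        assert abs(r) < 0.05

    def test_sequence_gc_tracks_annotation(self, toy_genome):
        orfs = toy_genome.features_of_class("ORF")[:10]
        for f in orfs:
            seq = toy_genome.sequences[f.chrom][f.start:f.end]
            gc = compute_gc(seq)
            assert gc == pytest.approx(
                toy_genome.annotations.loc[f.id, "gc_fraction"], abs=0.06
            )

    def test_antisense_enriched_among_hybrid_prone(self, toy_genome):
        ann = toy_genome.annotations
        orf_ids = [f.id for f in toy_genome.features_of_class("ORF")]
        hyb = [i for i in orf_ids
               if i in toy_genome.ground_truth.hybrid_prone_ids]
        cold = [i for i in orf_ids if i not in hyb]
        assert ann.loc[hyb, "antisense"].mean() > ann.loc[cold, "antisense"].mean()


class TestDripTracks:
    def test_probe_spacing_and_replicates(self, toy_genome):
        frames = simulate_drip_tracks(toy_genome)
        assert len(frames) == toy_genome.config.n_replicates
        chr1 = frames[0][frames[0]["chrom"] == "chr1"]
        assert (np.diff(chr1["pos"]) == toy_genome.config.probe_spacing).all()

    def test_planted_features_recovered_and_null_clean(self, toy_genome):
        frames = simulate_drip_tracks(toy_genome)
        tracks = [
            sliding_window_score(mock_normalize(df, replicate=str(i)), 300)
            for i, df in enumerate(frames)
        ]
        normed, _ = quantile_normalize_and_average(tracks)
        calls = [call_feature_enrichment(t, toy_genome.features)
                 for t in normed]
        consensus = consensus_calls(calls[0], calls[1])
        truth = toy_genome.ground_truth.hybrid_prone_ids
        recovered = len(consensus & truth) / len(truth)
        false_pos = consensus - truth
        assert recovered >= 0.95
        assert len(false_pos) <= 0.02 * len(toy_genome.features)

    def test_replicate_correlation_increases_as_noise_drops(self):
        rhos = []
        for sd in (0.4, 0.2, 0.05):
            cfg = SimulationConfig(seed=2, noise_log_sd=sd)
            g = generate_toy_genome(cfg)
            frames = simulate_drip_tracks(g, cfg)
            tracks = [sliding_window_score(mock_normalize(df), 300)
                      for df in frames]
            rhos.append(track_correlation(tracks[0], tracks[1]))
        assert rhos[0] < rhos[1] < rhos[2]

    def test_no_lift_gives_low_false_positive_rate(self):
        cfg = SimulationConfig(seed=4, orf_hybrid_lift=0.0,
                               class_lift={k: 0.0 for k in
                                           ("rDNA", "telomeric_repeat", "Ty1",
                                            "Ty2", "Ty3", "Ty4", "Ty5",
                                            "tRNA", "snoRNA")})
        g = generate_toy_genome(cfg)
        frames = simulate_drip_tracks(g, cfg)
        tracks = [sliding_window_score(mock_normalize(df), 300)
                  for df in frames]
        normed, _ = quantile_normalize_and_average(tracks)
        consensus = consensus_calls(
            *[call_feature_enrichment(t, g.features) for t in normed]
        )
        assert len(consensus) <= 0.01 * len(g.features)


class TestExpressionSimulation:
    def test_responders_recovered(self, toy_genome):
        records = median_scale(simulate_expression(toy_genome))
        mod = filter_modulated(records)
        truth = toy_genome.ground_truth
        assert set(mod.up) == set(truth.up_responders)
        assert set(mod.down) == set(truth.down_responders)

    def test_no_responders_yields_empty_sets(self):
        cfg = SimulationConfig(seed=6, n_up_responders=0, n_down_responders=0)
        g = generate_toy_genome(cfg)
        mod = filter_modulated(median_scale(simulate_expression(g, cfg)))
        assert len(mod.up) + len(mod.down) <= 2  # rare noise-only calls

    def test_deterministic(self, toy_genome):
        a = simulate_expression(toy_genome)
        b = simulate_expression(toy_genome)
        pd.testing.assert_frame_equal(a, b)


class TestSpreadSimulation:
    def test_counts_within_bounds_and_deterministic(self):
        cfg = SimulationConfig(seed=8)
        rates = {"WT": 0.02, "m1": 0.25}
        a = simulate_spread_counts(rates, cfg)
        b = simulate_spread_counts(rates, cfg)
        pd.testing.assert_frame_equal(a, b)
        assert (a["n_positive"] <= a["n_nuclei"]).all()
        assert len(a) == 2 * cfg.n_spread_replicates

    def test_bad_rate_rejected(self):
        with pytest.raises(ValueError, match="rate"):
            simulate_spread_counts({"WT": 1.5})


class TestRoundTrip:
    def test_generated_files_reload_cleanly(self, toy_genome, tmp_path):
        from dripchip.annotation import (load_annotations, write_annotations,
                                         write_features)
        write_features(toy_genome.features, tmp_path / "f.gff3", "GFF3")
        back = load_features(tmp_path / "f.gff3")
        assert back == sorted(toy_genome.features,
                              key=lambda f: (f.chrom, f.start, f.end, f.id))
        write_annotations(toy_genome.annotations, tmp_path / "a.tsv")
        ann = load_annotations(tmp_path / "a.tsv")
        assert set(ann.index) == set(toy_genome.annotations.index)
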