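import numpy as np
import pytest

from dripchip.annotation import GenomeFeature
from dripchip.signal import SignalTrack
from dripchip.simulate import SimulationConfig, generate_toy_genome


def make_track(positions, scores, chrom="chrI", **kw):
    return SignalTrack(data={chrom: (np.asarray(positions),
                                     np.asarray(scores, dtype=float))}, **kw)


@pytest.fixture(scope="session")
def toy_genome():
    return generate_toy_genome(SimulationConfig(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def planted_track(chrom_lengths, features, spacing=25, inside=2.0, rng=None,
                  background_mean=1.0, background_sd=0.2):
    """Track with N(mean, sd) background and a constant score inside the
    given features; the independent fixture used by recovery tests."""
    rng = rng or np.random.default_rng(0)
    data = {}
    for chrom, L in chrom_lengths.items():
        pos = np.arange(spacing // 2, L, spacing, dtype=np.int64)
        score = rng.normal(background_mean, background_sd, len(pos))
        for f in features:
            if f.chrom == chrom:
                score[(pos >= f.start) & (pos < f.end)] = inside
        data[chrom] = (pos, score)
    return SignalTrack(data=data)


def feature(chrom, start, end, fid, strand="+", fclass="ORF"):
    return GenomeFeature(chrom, start, end, fid, strand, fclass)
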