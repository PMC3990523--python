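"""Statistical operations against independent enumeration oracles."""

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
import pytest

from dripchip.stats import (
    ContingencyTable2x2,
    bonferroni_cutoff,
    fisher_exact_2x2,
    set_association,
    wilcoxon_rank_sum,
)


# ---------------------------------------------------------------------------
# Oracles (kept deliberately independent of the implementations they check)
# ---------------------------------------------------------------------------

def fisher_oracle(a, b, c, d, alternative="two-sided"):
    """Exact-fraction enumeration over all tables with the observed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = a + b + c + d
    denom = comb(n, c1)
    probs = {}
    for k in range(max(0, c1 - r2), min(c1, r1) + 1):
        probs[k] = Fraction(comb(r1, k) * comb(r2, c1 - k), denom)
    if alternative == "greater":
        p = sum(v for k, v in probs.items() if k >= a)
    elif alternative == "less":
        p = sum(v for k, v in probs.items() if k <= a)
    else:
        p = sum(v for v in probs.values() if v <= probs[a])
    return float(p)


def wilcoxon_oracle(x, y, alternative="greater"):
    """Full enumeration of rank splits (tie-free samples only)."""
    pooled = sorted(x + y)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    nx = len(x)
    obs = sum(ranks[v] for v in x)
    total = 0
    hits = 0
    for subset in combinations(range(1, len(pooled) + 1), nx):
        s = sum(subset)
        total += 1
        if alternative == "greater":
            hits += s >= obs
        elif alternative == "less":
            hits += s <= obs
        else:
            mean = nx * (len(pooled) + 1) / 2
            hits += abs(s - mean) >= abs(obs - mean)
    return hits / total


# ---------------------------------------------------------------------------
# Fisher
# ---------------------------------------------------------------------------

class TestFisherExact:
    def test_symmetric_table_p1(self):
        odds, p = fisher_exact_2x2([[1, 1], [1, 1]])
        assert p == 1.0 and odds == pytest.approx(1.0)

    def test_diagonal_3_3_two_sided_is_one_tenth(self):
        # both extreme tables have probability 1/20; two-sided sums to 0.1
        _, p = fisher_exact_2x2([[3, 0], [0, 3]])
        assert p == pytest.approx(0.1, abs=1e-15)

    def test_zero_margin_degenerate(self):
        with pytest.warns(UserWarning, match="zero margin"):
            odds, p = fisher_exact_2x2([[0, 0], [3, 4]])
        assert p == 1.0 and np.isnan(odds)

    def test_infinite_odds_ratio(self):
        odds, _ = fisher_exact_2x2([[3, 0], [1, 3]])
        assert odds == float("inf")

    @pytest.mark.parametrize("alternative", ["two-sided", "less", "greater"])
    def test_matches_enumeration_on_random_tables(self, alternative, rng):
        for _ in range(200):
            a, b, c, d = rng.integers(0, 12, 4)
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            _, p = fisher_exact_2x2([[a, b], [c, d]], alternative)
            assert p == pytest.approx(
                fisher_oracle(int(a), int(b), int(c), int(d), alternative),
                abs=1e-12,
            )

    def test_one_sided_never_exceeds_two_sided_plus_p_in_unit(self, rng):
        for _ in range(50):
            a, b, c, d = rng.integers(0, 10, 4) + 1
            _, p2 = fisher_exact_2x2([[a, b], [c, d]])
            _, pg = fisher_exact_2x2([[a, b], [c, d]], "greater")
            _, pl = fisher_exact_2x2([[a, b], [c, d]], "less")
            for p in (p2, pg, pl):
                assert 0 < p <= 1
            assert p2 >= min(pg, pl)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 0, 0, 0)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

class TestWilcoxon:
    def test_textbook_one_sided(self):
        # x entirely above y: p = 1/C(6,3) = 0.05
        u, p = wilcoxon_rank_sum([4, 5, 6], [1, 2, 3], "greater", "exact")
        assert u == 9.0
        assert p == pytest.approx(0.05)

    def test_identical_samples_p1(self):
        _, p = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_all_values_identical_p1(self):
        _, p = wilcoxon_rank_sum([2, 2], [2, 2, 2])
        assert p == 1.0

    @pytest.mark.parametrize("alternative", ["two-sided", "less", "greater"])
    def test_exact_matches_full_enumeration(self, alternative, rng):
        for _ in range(20):
            nx = int(rng.integers(2, 6))
            ny = int(rng.integers(2, 11 - nx))
            vals = rng.choice(1000, nx + ny, replace=False) / 7.0
            x, y = list(vals[:nx]), list(vals[nx:])
            _, p = wilcoxon_rank_sum(x, y, alternative, "exact")
            assert p == pytest.approx(wilcoxon_oracle(x, y, alternative),
                                      abs=1e-12)

    def test_exact_and_approx_agree_at_n20(self, rng):
        x = list(rng.normal(0, 1, 20))
        y = list(rng.normal(0.5, 1, 20))
        _, p_exact = wilcoxon_rank_sum(x, y, mode="exact")
        _, p_approx = wilcoxon_rank_sum(x, y, mode="normal-approx")
        assert p_exact == pytest.approx(p_approx, abs=0.01)

    def test_exact_mode_rejects_ties(self):
        with pytest.raises(ValueError, match="tie-free"):
            wilcoxon_rank_sum([1, 1, 2], [3, 4, 5], mode="exact")

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


# ---------------------------------------------------------------------------
# Set association & Bonferroni
# ---------------------------------------------------------------------------

class TestSetAssociation:
    def test_counts_and_margins(self):
        universe = {f"g{i}" for i in range(20)}
        focal = {f"g{i}" for i in range(8)}
        annotated = {f"g{i}" for i in range(4, 14)}
        r = set_association(focal, universe, annotated)
        assert (r.table.a, r.table.b, r.table.c, r.table.d) == (4, 4, 6, 6)
        assert r.table.a + r.table.b == len(focal)
        assert r.table.a + r.table.c == len(annotated)
        assert r.percent_annotated == pytest.approx(50.0)
        # hand-computed odds ratio 4*6/(4*6) = 1
        assert r.odds_ratio == pytest.approx(1.0)

    def test_focal_subset_of_annotated_is_100pct(self):
        u = {"a", "b", "c", "d"}
        r = set_association({"a", "b"}, u, {"a", "b", "c"})
        assert r.percent_annotated == 100.0

    def test_disjoint_focal_is_0pct(self):
        u = {"a", "b", "c", "d"}
        r = set_association({"a"}, u, {"b", "c"})
        assert r.percent_annotated == 0.0

    def test_empty_focal_signalled(self):
        with pytest.warns(UserWarning, match="empty focal"):
            r = set_association(set(), {"a", "b"}, {"a"})
        assert np.isnan(r.percent_annotated)

    def test_focal_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="not contained"):
            set_association({"z"}, {"a"}, set())


class TestBonferroni:
    @pytest.mark.parametrize("alpha,n,expected", [
        (0.01, 40, 0.00025),
        (0.05, 1, 0.05),
    ])
    def test_cutoff(self, alpha, n, expected):
        assert bonferroni_cutoff(n, alpha) == pytest.approx(expected)

    def test_41_tests_rounds_to_printed_value(self):
        # 0.01 / 41 = 0.000244; the screen's published cutoff 0.00024
        assert bonferroni_cutoff(41, 0.01) == pytest.approx(0.00024, abs=5e-6)

    def test_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_cutoff(0)
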