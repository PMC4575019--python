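import itertools
import math

import numpy as np
import pytest

from phyloherb.datasets import Assemblage
from phyloherb.metrics import (
    DPrimeRecord,
    PairwiseCounts,
    UndefinedMetricError,
    build_plant_metrics,
    dprime,
    dprime_table,
    jaccard_dissimilarity,
    mean_dissimilarity,
    mean_dprime_per_plant,
    min_kl_allocation,
    pairwise_abc,
    richness,
    simpson_dissimilarity,
)
from phyloherb.phylo import Phylogeny

from conftest import make_table


def brute_force_min_kl(A, q):
    """Independent oracle: enumerate every integer allocation of A."""
    usable = np.flatnonzero(q > 0)
    best = math.inf
    n = len(usable)
    for cuts in itertools.combinations(range(A + n - 1), n - 1):
        parts, prev = [], -1
        for c in cuts:
            parts.append(c - prev - 1)
            prev = c
        parts.append(A + n - 1 - prev - 1)
        tot = 0.0
        for k, i in zip(parts, usable):
            if k:
                p = k / A
                tot += p * math.log(p / q[i])
        best = min(best, tot)
    return best


class TestRichness:
    def test_counts_nonzero(self):
        t = make_table([[2, 0, 1, 1]])
        assert richness(t, "P1") == 3

    def test_single(self):
        t = make_table([[1, 0, 0, 0]])
        assert richness(t, "P1") == 1

    def test_zero_row_violates_contract(self):
        t = make_table([[0, 0], [1, 1]])
        with pytest.raises(Exception):
            richness(t, "P1")

    def test_unknown_plant(self, toy_table):
        with pytest.raises(KeyError):
            richness(toy_table, "Px")


class TestPairwiseABC:
    def test_set_arithmetic(self, toy_table):
        pc = pairwise_abc(toy_table, "P1", "P2")  # {H1,H2,H3} vs {H2,H3,H4,H5}
        assert (pc.a, pc.b, pc.c) == (2, 1, 2)

    def test_disjoint(self):
        t = make_table([[1, 0], [0, 1]])
        pc = pairwise_abc(t, "P1", "P2")
        assert pc.a == 0

    def test_identical(self):
        t = make_table([[1, 1, 1], [2, 5, 1]])
        pc = pairwise_abc(t, "P1", "P2")
        assert (pc.a, pc.b, pc.c) == (3, 0, 0)

    def test_same_plant_rejected(self, toy_table):
        with pytest.raises(ValueError):
            pairwise_abc(toy_table, "P1", "P1")

    def test_abc_sums_to_richness(self, toy_table):
        pc = pairwise_abc(toy_table, "P1", "P2")
        assert pc.a + pc.b == richness(toy_table, "P1")
        assert pc.a + pc.c == richness(toy_table, "P2")


class TestDissimilarityIndices:
    def test_jaccard_arithmetic(self):
        assert jaccard_dissimilarity(PairwiseCounts(2, 1, 3)) == pytest.approx(4 / 6)

    def test_jaccard_bounds(self):
        assert jaccard_dissimilarity(PairwiseCounts(5, 0, 0)) == 0.0
        assert jaccard_dissimilarity(PairwiseCounts(0, 2, 3)) == 1.0

    def test_jaccard_undefined(self):
        with pytest.raises(UndefinedMetricError):
            jaccard_dissimilarity(PairwiseCounts(0, 0, 0))

    def test_simpson_arithmetic(self):
        assert simpson_dissimilarity(PairwiseCounts(1, 3, 5)) == pytest.approx(3 / 4)

    def test_simpson_nested(self):
        assert simpson_dissimilarity(PairwiseCounts(4, 0, 7)) == 0.0

    def test_simpson_turnover(self):
        assert simpson_dissimilarity(PairwiseCounts(0, 2, 3)) == 1.0

    def test_simpson_undefined(self):
        with pytest.raises(UndefinedMetricError):
            simpson_dissimilarity(PairwiseCounts(0, 0, 3))

    def test_simpson_le_jaccard_small_grid(self):
        for a, b, c in itertools.product(range(6), repeat=3):
            if a + b + c == 0 or (a == 0 and min(b, c) == 0):
                continue
            pc = PairwiseCounts(a, b, c)
            assert simpson_dissimilarity(pc) <= jaccard_dissimilarity(pc) + 1e-12

    def test_presence_only_and_column_permutation_invariance(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(0, 4, (4, 6))
        counts[counts.sum(axis=1) == 0, 0] = 1
        t1 = make_table(counts)
        t2 = make_table(np.where(counts > 0, counts * 7, 0))  # magnitudes changed
        perm = rng.permutation(6)
        t3 = make_table(counts[:, perm],
                        herb_names=[f"H{j+1}" for j in perm])
        for p, q in itertools.combinations(["P1", "P2", "P3", "P4"], 2):
            ref = pairwise_abc(t1, p, q)
            assert pairwise_abc(t2, p, q) == ref
            assert pairwise_abc(t3, p, q) == ref


class TestMeanDissimilarity:
    def test_mean_of_values(self):
        # focal P1 vs natives P2 (jaccard 0.5) and P3 (jaccard 1.0)
        t = make_table([[1, 1, 0, 0], [1, 0, 1, 0], [0, 0, 0, 1]])
        val, n = mean_dissimilarity(t, "P1", ["P2", "P3"], "jaccard")
        assert n == 2
        assert val == pytest.approx((2 / 3 + 1.0) / 2)

    def test_self_only_errors(self):
        t = make_table([[1]])
        with pytest.raises(UndefinedMetricError):
            mean_dissimilarity(t, "P1", ["P1"], "jaccard")

    def test_disjoint_gives_one(self):
        t = make_table(np.eye(3, dtype=int))
        for index in ("jaccard", "simpson"):
            val, _ = mean_dissimilarity(t, "P1", ["P2", "P3"], index)
            assert val == 1.0

    def test_within_minmax_of_constituents(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 3, (5, 8))
        counts[counts.sum(axis=1) == 0, 0] = 1
        t = make_table(counts)
        natives = ["P2", "P3", "P4", "P5"]
        vals = [jaccard_dissimilarity(pairwise_abc(t, "P1", n)) for n in natives]
        mean, _ = mean_dissimilarity(t, "P1", natives, "jaccard")
        assert min(vals) <= mean <= max(vals)


class TestDPrime:
    def test_proportional_allocation_is_zero(self):
        # column exactly proportional to availability -> d_raw == d_min
        counts = np.array([[2, 1, 0], [4, 2, 0], [2, 1, 3]])
        t = make_table(counts)
        rec = dprime(t, "H1")
        assert rec.d_raw == pytest.approx(rec.d_min, abs=1e-12) or rec.d_prime < 0.1

    def test_sole_visitor_maximum(self):
        counts = np.array([[3, 0], [0, 5]])
        t = make_table(counts)
        rec = dprime(t, "H1")
        assert rec.d_raw == pytest.approx(math.log(8 / 3))
        assert rec.d_prime == pytest.approx(1.0)

    def test_single_plant_degenerate(self):
        t = make_table([[2, 3]])
        rec = dprime(t, "H1")
        assert rec.degenerate and rec.d_prime == 0.0

    def test_no_interactions_undefined(self):
        t = make_table([[1, 0], [1, 0]])
        with pytest.raises(UndefinedMetricError):
            dprime(t, "H2")

    def test_oracle_equivalence_random_tables(self):
        rng = np.random.default_rng(12)
        for _ in range(150):
            P, H = rng.integers(2, 5, 2)
            counts = rng.integers(0, 4, (P, H))
            if counts.sum() == 0 or (counts.sum(axis=1) == 0).any():
                continue
            t = make_table(counts)
            q = counts.sum(axis=1) / counts.sum()
            for h in t.herbivore_names:
                j = t.herbivore_index(h)
                A = int(counts[:, j].sum())
                if A < 1:
                    continue
                rec = dprime(t, h)
                assert rec.d_min == pytest.approx(brute_force_min_kl(A, q), abs=1e-12)
                assert rec.d_min - 1e-12 <= rec.d_raw <= rec.d_max + 1e-12

    def test_in_unit_interval_random_matrices(self):
        rng = np.random.default_rng(3)
        for _ in range(2000):
            P, H = rng.integers(1, 7, 2)
            counts = rng.integers(0, 5, (P, H))
            if counts.sum() == 0:
                continue
            t = make_table(counts)
            for h in t.herbivore_names:
                if counts[:, t.herbivore_index(h)].sum() < 1:
                    continue
                rec = dprime(t, h)
                assert 0.0 <= rec.d_prime <= 1.0

    def test_min_kl_requires_interactions(self):
        with pytest.raises(ValueError):
            min_kl_allocation(0, np.array([0.5, 0.5]))


class TestMeanDPrimePerPlant:
    def test_all_ones(self):
        recs = {f"H{j}": DPrimeRecord(f"H{j}", 1, 0, 1, 1.0) for j in (1, 2, 3)}
        t = make_table([[1, 1, 1]])
        assert mean_dprime_per_plant(t, "P1", recs) == 1.0

    def test_single_herbivore(self):
        counts = np.array([[3, 0], [0, 5]])
        t = make_table(counts)
        rec = dprime(t, "H1")
        assert mean_dprime_per_plant(t, "P1") == pytest.approx(rec.d_prime)

    def test_matches_hand_average(self):
        counts = np.array([[1, 1, 0], [0, 1, 2], [3, 0, 1]])
        t = make_table(counts)
        recs = dprime_table(t)
        expected = np.mean([recs["H1"].d_prime, recs["H2"].d_prime])
        assert mean_dprime_per_plant(t, "P1", recs) == pytest.approx(expected)


class TestBuildPlantMetrics:
    @pytest.fixture
    def five_plant_assemblage(self):
        rng = np.random.default_rng(8)
        counts = rng.integers(0, 3, (5, 8))
        counts[counts.sum(axis=1) == 0, 0] = 1
        names = [f"S{i}" for i in range(1, 6)]
        t = make_table(counts, plant_names=names,
                       origins=["native", "native", "native", "exotic", "exotic"])
        tree = "((((S1:1,S2:1):1,S3:2):2,S4:4):1,S5:5);"
        return Assemblage("A1", t), Phylogeny.from_newick(tree)

    def test_complete_records(self, five_plant_assemblage):
        a, phy = five_plant_assemblage
        df = build_plant_metrics(a, phy)
        assert len(df) == 5
        assert df.notna().all().all()
        assert (df["richness"] >= 1).all()
        assert df[["mean_jaccard", "mean_simpson", "mean_dprime"]].min().min() >= 0
        assert df[["mean_jaccard", "mean_simpson", "mean_dprime"]].max().max() <= 1

    def test_deterministic(self, five_plant_assemblage):
        a, phy = five_plant_assemblage
        df1 = build_plant_metrics(a, phy)
        df2 = build_plant_metrics(a, phy)
        assert df1.equals(df2)
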