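"""Anchor annotation, 1v1/mvm partition, negative sampling, and splits."""

import numpy as np
import pytest
from scipy import stats

from encontact.interactions import (
    DistanceError,
    EEPair,
    RegionInteraction,
    SamplingError,
    annotate_interactions,
    kmer_featurize,
    pair_distance,
    partition_1v1_mvm,
    sample_negatives_distance_matched,
    sample_negatives_fixed_anchor,
    sample_negatives_random_pairs,
    split_by_chromosome,
    split_folds,
)
from encontact.sequence_io import Enhancer


def enh(i, chrom="chr1", start=0, L=2000):
    return Enhancer(f"e{i}", chrom, start, start + L)


class TestAnnotate:
    def test_overlap_is_half_open(self):
        inter = RegionInteraction(("chr1", 0, 100), ("chr1", 5000, 6000), "x")
        touching = Enhancer("a", "chr1", 100, 300)  # no 1-bp intersection
        inside = Enhancer("b", "chr1", 5500, 5600)
        assert annotate_interactions([inter], [touching, inside]) == {}

    def test_multi_enhancer_anchors(self):
        inter = RegionInteraction(("chr1", 0, 5000), ("chr1", 9000, 12000), "x")
        e = [Enhancer("a", "chr1", 100, 2100), Enhancer("b", "chr1", 3000, 5000),
             Enhancer("c", "chr1", 9000, 9500), Enhancer("d", "chr1", 10000, 10500),
             Enhancer("x", "chr1", 11000, 11900)]
        a1, a2 = annotate_interactions([inter], e)["x"]
        assert [x.id for x in a1] == ["a", "b"]
        assert [x.id for x in a2] == ["c", "d", "x"]

    def test_empty_anchor_drops_interaction(self):
        inter = RegionInteraction(("chr1", 0, 100), ("chr1", 200, 300), "x")
        assert annotate_interactions([inter], [Enhancer("a", "chr1", 0, 50)]) == {}


class TestPartition:
    def test_one_v_one_yields_positive(self):
        annotated = {"x": ([enh(1, start=0)], [enh(2, start=10000)])}
        pos, mvm = partition_1v1_mvm(annotated)
        assert len(pos) == 1 and pos[0].label == 1 and not mvm

    def test_cross_product_size(self):
        a1 = [enh(i, start=5000 * i) for i in range(2)]
        a2 = [enh(10 + i, start=100000 + 5000 * i) for i in range(3)]
        pos, mvm = partition_1v1_mvm({"x": (a1, a2)})
        assert not pos
        assert len(mvm) == 1 and len(mvm[0].candidates) == 6
        assert all(p.label is None for p in mvm[0].candidates)

    def test_1v1_dedup_across_interactions(self):
        a, b = enh(1, start=0), enh(2, start=10000)
        pos, _ = partition_1v1_mvm({"x": ([a], [b]), "y": ([b], [a])})
        assert len(pos) == 1

    def test_partition_is_exhaustive(self):
        annotated = {
            "p": ([enh(1, start=0)], [enh(2, start=10000)]),
            "m": ([enh(3, start=0), enh(4, start=5000)], [enh(5, start=50000)]),
        }
        pos, mvm = partition_1v1_mvm(annotated)
        assert len(pos) + len(mvm) == len(annotated)


class TestPairDistance:
    LOOKUP = {
        "a": Enhancer("a", "chr1", 9000, 11000),
        "b": Enhancer("b", "chr1", 59000, 61000),
        "c": Enhancer("c", "chr2", 9000, 11000),
    }

    def test_midpoint_distance(self):
        assert pair_distance(EEPair("a", "b"), self.LOOKUP) == 50000

    def test_same_midpoint_is_zero(self):
        lookup = dict(self.LOOKUP, d=Enhancer("d", "chr1", 8000, 12000))
        assert pair_distance(EEPair("a", "d"), lookup) == 0

    def test_cross_chromosome_is_error(self):
        with pytest.raises(DistanceError):
            pair_distance(EEPair("a", "c"), self.LOOKUP)


def _pool_and_positives(seed=0, n_pool=300, n_pos=100):
    """Enhancer pool on two chromosomes plus sampled positives."""
    rng = np.random.default_rng(seed)
    pool = []
    for chrom in ("chr1", "chr2"):
        starts = np.sort(rng.choice(np.arange(0, 1_000_000, 2500),
                                    size=n_pool // 2, replace=False))
        pool += [Enhancer(f"{chrom}_{i}", chrom, int(s), int(s) + 2000)
                 for i, s in enumerate(starts)]
    by_chrom = {}
    for e in pool:
        by_chrom.setdefault(e.chrom, []).append(e)
    positives, used = [], set()
    while len(positives) < n_pos:
        es = by_chrom[("chr1", "chr2")[rng.integers(2)]]
        i, j = rng.choice(len(es), 2, replace=False)
        p = EEPair(es[i].id, es[j].id, 1,
                   abs(es[i].midpoint - es[j].midpoint))
        if p.key not in used:
            used.add(p.key)
            positives.append(p)
    return pool, positives


class TestDistanceMatchedNegatives:
    def test_counts_and_exclusion(self):
        pool, positives = _pool_and_positives()
        negs = sample_negatives_distance_matched(positives, pool, seed=1)
        assert len(negs) == len(positives)
        assert not {n.key for n in negs} & {p.key for p in positives}

    def test_per_bin_membership_matches_recomputed_edges(self):
        pool, positives = _pool_and_positives(seed=2)
        negs = sample_negatives_distance_matched(positives, pool, n_bins=5, seed=3)
        pos_d = np.array([p.distance for p in positives], float)
        edges = np.quantile(pos_d, np.linspace(0, 1, 6))
        neg_d = np.array([n.distance for n in negs], float)
        counts = np.histogram(neg_d, bins=edges)[0]
        assert counts.sum() == len(negs)
        # each bin holds as many negatives as positives (20 of 100, 5 bins)
        assert np.all(np.abs(counts - 20) <= 1)  # edge ties may shift by one

    def test_distance_distributions_indistinguishable(self):
        pool, positives = _pool_and_positives(seed=4, n_pos=200)
        negs = sample_negatives_distance_matched(positives, pool, seed=5)
        _, p = stats.ks_2samp([p.distance for p in positives],
                              [n.distance for n in negs])
        assert p > 0.01

    def test_deterministic_under_seed(self):
        pool, positives = _pool_and_positives()
        a = sample_negatives_distance_matched(positives, pool, seed=9)
        b = sample_negatives_distance_matched(positives, pool, seed=9)
        assert a == b

    def test_exhaustion_reports_bin(self):
        pool = [enh(1, start=0), enh(2, start=10_000), enh(3, start=20_000)]
        positives = [EEPair("e1", "e2", 1, 10_000), EEPair("e2", "e3", 1, 10_000),
                     EEPair("e1", "e3", 1, 20_000)] * 2
        positives = positives[:5]
        with pytest.raises((SamplingError, ValueError)):
            sample_negatives_distance_matched(positives[:5], pool, seed=0)


class TestFixedAnchorNegatives:
    def test_size_sharing_and_exclusion(self):
        pool, positives = _pool_and_positives(seed=6)
        negs = sample_negatives_fixed_anchor(positives, pool, seed=7)
        assert len(negs) == len(positives)
        pos_ids = {i for p in positives for i in (p.e1, p.e2)}
        assert all((n.e1 in pos_ids) or (n.e2 in pos_ids) for n in negs)
        assert not {n.key for n in negs} & {p.key for p in positives}


class TestRandomPairNegatives:
    def test_capacity_bound(self):
        pool = [enh(i, start=10_000 * i) for i in range(3)]
        assert len(sample_negatives_random_pairs(pool, 3, seed=0)) == 3
        with pytest.raises(SamplingError):
            sample_negatives_random_pairs(pool, 4, seed=0)

    def test_zero_request(self):
        pool = [enh(i, start=10_000 * i) for i in range(3)]
        assert sample_negatives_random_pairs(pool, 0, seed=0) == []

    def test_deterministic_under_seed(self):
        pool, positives = _pool_and_positives(seed=8)
        a = sample_negatives_random_pairs(pool, 50, positives, seed=11)
        b = sample_negatives_random_pairs(pool, 50, positives, seed=11)
        assert a == b and len(a) == 50


class TestSplits:
    def _pairs(self, n=1000):
        return [EEPair(f"a{i}", f"b{i}", i % 2, 1000 * i) for i in range(n)]

    def test_fold_sizes_and_disjointness(self):
        split = split_folds(self._pairs(), k=10, seed=0)
        assert len(split.test) == 100 and len(split.train) == 900
        assert not {p.key for p in split.test} & {p.key for p in split.train}

    def test_stratification(self):
        split = split_folds(self._pairs(), k=10, seed=1)
        frac = np.mean([p.label for p in split.test])
        assert abs(frac - 0.5) <= 0.02

    def test_chromosome_split(self):
        lookup = {
            "a": Enhancer("a", "chr5", 0, 2000), "b": Enhancer("b", "chr5", 9000, 11000),
            "c": Enhancer("c", "chr20", 0, 2000), "d": Enhancer("d", "chr20", 9000, 11000),
        }
        pairs = [EEPair("a", "b", 1), EEPair("c", "d", 0)]
        split = split_by_chromosome(pairs, lookup)
        assert split.train == [pairs[0]] and split.test == [pairs[1]]

    def test_empty_test_warns(self):
        lookup = {"a": Enhancer("a", "chr1", 0, 2000),
                  "b": Enhancer("b", "chr1", 9000, 11000)}
        with pytest.warns(UserWarning):
            split_by_chromosome([EEPair("a", "b", 1)], lookup)


class TestKmerFeaturize:
    def test_hand_counts(self):
        v = kmer_featurize("AAAA", k=2)
        assert v[0] == 3 and v.sum() == 3  # AA at lexicographic index 0

    def test_lexicographic_order(self):
        # "AC" -> index 0*4+1 = 1 in A,C,G,T ordering
        v = kmer_featurize("AC", k=2)
        assert v[1] == 1 and v.sum() == 1

    def test_window_count_identity(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=137))
        assert kmer_featurize(seq, k=6).sum() == 137 - 6 + 1

    def test_n_windows_excluded(self):
        assert kmer_featurize("AANAA", k=2).sum() == 2

    def test_too_short_gives_zero_vector(self):
        assert kmer_featurize("AC", k=6).sum() == 0
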