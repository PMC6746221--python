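"""Openness, co-opening, peak/enhancer activity, networks, and hub calling."""

import numpy as np
import pytest

from encontact.sequence_io import Enhancer
from encontact.signal import (
    Peak,
    SignalTrack,
    build_network,
    call_hub_enhancers,
    compare_groups,
    coopening_degree,
    enhancer_activity_score,
    enhancer_openness_vector,
    openness_score,
    peak_activity_score,
    read_bedgraph,
    write_bedgraph,
)


def track(counts, chrom="chr1", rep="r1"):
    return SignalTrack(replicate_id=rep, counts={chrom: np.array(counts, float)})


class TestOpenness:
    def test_hand_example(self):
        # site read count 4, window total 4, W=10: O = 4 / (4/10) = 10
        t = track([0, 0, 0, 4, 0, 0, 0, 0, 0, 0])
        assert openness_score(t, "chr1", 3, W=10) == pytest.approx(10.0)

    def test_zero_reads_at_site(self):
        t = track([1, 0, 1, 1])
        assert openness_score(t, "chr1", 1, W=4) == 0.0

    def test_depth_invariance(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(2.0, size=1000).astype(float)
        t1, t7 = track(counts), track(counts * 7)
        for site in (10, 500, 990):
            assert openness_score(t1, "chr1", site, W=200) == pytest.approx(
                openness_score(t7, "chr1", site, W=200))

    def test_zero_background_is_zero(self):
        assert openness_score(track([0, 0, 0]), "chr1", 1, W=3) == 0.0

    def test_out_of_range_site(self):
        with pytest.raises(IndexError):
            openness_score(track([1, 2]), "chr1", 5)


class TestOpennessVector:
    def test_single_replicate_identity(self):
        t = track(np.arange(10, dtype=float))
        e = Enhancer("e", "chr1", 2, 6)
        v = enhancer_openness_vector(e, [t], W=10)
        expected = [openness_score(t, "chr1", s, W=10) for s in range(2, 6)]
        assert np.allclose(v, expected)

    def test_replicate_average(self):
        base = np.array([1, 2, 3, 4, 5], float)
        t1, t3 = track(base), track(3 * base, rep="r2")
        e = Enhancer("e", "chr1", 0, 5)
        v1 = enhancer_openness_vector(e, [t1], W=5)
        # openness is depth-invariant, so averaging t and 3t equals either one
        v = enhancer_openness_vector(e, [t1, t3], W=5)
        assert np.allclose(v, v1)

    def test_all_zero_tracks(self):
        e = Enhancer("e", "chr1", 0, 5)
        assert np.allclose(enhancer_openness_vector(e, [track([0] * 8)], W=8), 0.0)


class TestCoopening:
    def test_perfect_linear_relation(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        res = coopening_degree(v, 2 * v + 1)
        assert res.degree == pytest.approx(1.0)
        assert res.co_opening

    def test_anticorrelation_has_degree_one(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        assert coopening_degree(v, -v).degree == pytest.approx(1.0)

    def test_constant_vector_undefined(self):
        res = coopening_degree(np.ones(5), np.arange(5.0))
        assert res.degree is None and res.co_opening is False

    def test_independent_vectors_have_small_degree(self):
        rng = np.random.default_rng(1)
        degrees = [coopening_degree(rng.standard_normal(2000),
                                    rng.standard_normal(2000)).degree
                   for _ in range(20)]
        assert np.mean(np.array(degrees) < 0.08) >= 0.95

    def test_symmetry_and_affine_invariance(self):
        rng = np.random.default_rng(2)
        a, b = rng.standard_normal(100), rng.standard_normal(100)
        d1 = coopening_degree(a, b).degree
        assert coopening_degree(b, a).degree == pytest.approx(d1)
        assert coopening_degree(3 * a - 2, b).degree == pytest.approx(d1)
        assert 0.0 <= d1 <= 1.0


class TestPeakActivity:
    def test_hand_example(self):
        # 100 reads in a 200-bp peak, 1,000 reads in the (clipped) window,
        # nominal W=1e6: PAS = (100/200) / (1000/1e6) = 500
        counts = np.zeros(2000)
        counts[:200] = 0.5           # 100 reads in the peak
        counts[200:2000] = 0.5       # 900 more reads -> 1000 in window
        t = track(counts)
        pas = peak_activity_score(Peak("chr1", 0, 200), t, W=10**6)
        assert pas == pytest.approx(500.0)

    def test_empty_peak(self):
        counts = np.ones(1000)
        counts[:100] = 0
        assert peak_activity_score(Peak("chr1", 0, 100), track(counts),
                                   W=1000) == 0.0

    def test_uniform_coverage_is_one(self):
        # chromosome length equals W so the centered window is exactly the chromosome
        t = track(np.full(1000, 3.0))
        assert peak_activity_score(Peak("chr1", 400, 600), t,
                                   W=1000) == pytest.approx(1.0)

    def test_depth_invariance(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(5.0, 1000).astype(float)
        p = Peak("chr1", 100, 300)
        assert peak_activity_score(p, track(counts), W=1000) == pytest.approx(
            peak_activity_score(p, track(counts * 11), W=1000))


class TestEnhancerActivity:
    E = Enhancer("e", "chr1", 100, 300)

    def test_max_rule_and_threshold(self):
        peaks = [(Peak("chr1", 50, 150), 0.5), (Peak("chr1", 200, 400), 3.0)]
        eas, active = enhancer_activity_score(self.E, peaks)
        assert eas == 3.0 and active

    def test_boundary_is_strict(self):
        eas, active = enhancer_activity_score(self.E, [(Peak("chr1", 50, 150), 1.0)])
        assert eas == 1.0 and not active

    def test_no_overlap(self):
        eas, active = enhancer_activity_score(self.E, [(Peak("chr1", 300, 400), 9.0)])
        assert eas == 0.0 and not active


class TestNetworkAndHubs:
    def test_degrees_and_duplicates(self):
        net = build_network([("a", "b"), ("b", "c"), ("b", "a")])
        assert net.number_of_edges() == 2
        assert dict(net.degree) == {"a": 1, "b": 2, "c": 1}
        assert sum(d for _, d in net.degree) == 2 * net.number_of_edges()

    def test_self_pair_warns_and_skips(self):
        with pytest.warns(UserWarning):
            net = build_network([("a", "a"), ("a", "b")])
        assert net.number_of_edges() == 1

    def test_hub_count_is_ceil_of_fraction(self):
        edges = [(f"n{i}", f"n{(i + 1) % 100}") for i in range(100)]
        net = build_network(edges)
        assert len(call_hub_enhancers(net)) == 10

    def test_star_center_is_hub(self):
        net = build_network([("hub", f"leaf{i}") for i in range(30)])
        assert "hub" in call_hub_enhancers(net)

    def test_tie_break_is_lexicographic_and_deterministic(self):
        edges = [(f"n{i:02d}", f"n{(i + 1) % 20:02d}") for i in range(20)]
        net = build_network(edges)  # all degrees equal (cycle)
        hubs = call_hub_enhancers(net)
        assert hubs == {"n00", "n01"}
        assert call_hub_enhancers(net) == hubs

    def test_too_few_nodes(self):
        with pytest.raises(ValueError):
            call_hub_enhancers(build_network([("a", "b")]))


class TestCompareGroups:
    def test_identical_samples_near_half(self):
        x = list(range(50))
        assert 0.4 < compare_groups(x, x) < 0.6

    def test_large_shift_is_significant(self):
        rng = np.random.default_rng(4)
        b = rng.normal(0, 1, 50)
        assert compare_groups(b + 100, b) < 1e-10

    def test_u_statistic_matches_all_pairs_enumeration(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 10, 8).astype(float)
        b = rng.integers(0, 10, 7).astype(float)
        from scipy.stats import mannwhitneyu

        u = mannwhitneyu(a, b, alternative="greater", method="asymptotic").statistic
        brute = sum(1.0 if x > y else 0.5 if x == y else 0.0 for x in a for y in b)
        assert u == pytest.approx(brute)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([], [1.0])


class TestBedgraphIO:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(6)
        counts = rng.poisson(0.3, 500).astype(float)
        t = SignalTrack("r1", {"chr1": counts})
        path = tmp_path / "t.bedgraph"
        write_bedgraph(t, path)
        back = read_bedgraph(path, {"chr1": 500}, replicate_id="r1")
        assert np.allclose(back.counts["chr1"], counts)
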