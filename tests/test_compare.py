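import math

import networkx as nx
import pytest

from triosv.compare import (
    MatchParams,
    match_callsets,
    reciprocal_overlap_compare,
    snv_set_compare,
    sv_pair_matches,
    ti_tv_ratio,
)
from triosv.datamodel import RegionSet, SNVRecord

from conftest import make_sv


def bipartite_max_tp(base, comp, params):
    """Independent maximum bipartite matching under the pair predicate."""
    g = nx.Graph()
    g.add_nodes_from((0, i) for i in range(len(base)))
    g.add_nodes_from((1, j) for j in range(len(comp)))
    for i, b in enumerate(base):
        for j, c in enumerate(comp):
            if sv_pair_matches(b, c, params):
                g.add_edge((0, i), (1, j))
    match = nx.bipartite.maximum_matching(g, top_nodes=[(0, i) for i in range(len(base))])
    return sum(1 for k in match if k[0] == 0)


def random_separated_instance(rng, params, n_max=20, cluster_sep=None):
    """Random base/comp sets built from clusters > 2*refdist apart.

    Within a cluster, starts lie within refdist/2 and sizes within the
    size-ratio band, so every same-type within-cluster pair satisfies the
    predicate while no cross-cluster pair can.
    """
    sep = cluster_sep or (2 * params.refdist + 1)
    n_clusters = int(rng.integers(1, 6))
    base, comp = [], []
    pos = 10_000
    for _ in range(n_clusters):
        n_b = int(rng.integers(0, 4))
        n_c = int(rng.integers(0, 4))
        types = rng.choice(["DEL", "INS", "INV"], size=2)
        base_size = {"DEL": 50, "INS": 50, "INV": 200}
        s0 = {t: base_size[t] + int(rng.integers(0, 60)) for t in set(types)}
        for i in range(n_b + n_c):
            svtype = str(types[rng.integers(0, 2)])
            start = pos + int(rng.integers(0, params.refdist // 2))
            svlen = int(rng.integers(s0[svtype], int(s0[svtype] / params.size_ratio_min)))
            rec = make_sv(start=start, svtype=svtype, svlen=svlen, id=f"r{pos}_{i}")
            (base if i < n_b else comp).append(rec)
        pos += sep + params.refdist + 500
    n = min(n_max, len(base) + len(comp))
    return base[:n], comp[:n]


class TestPairPredicate:
    def test_within_refdist_same_size(self):
        a = make_sv(start=1000, svlen=100)
        b = make_sv(start=1500, svlen=100)
        assert sv_pair_matches(a, b, MatchParams())

    def test_type_mismatch_rejected(self):
        a = make_sv(start=1000, svtype="DEL", svlen=100)
        b = make_sv(start=1000, svtype="INS", svlen=100)
        assert not sv_pair_matches(a, b, MatchParams())
        assert sv_pair_matches(a, b, MatchParams(require_same_type=False))

    def test_size_ratio_boundary_inclusive(self):
        a = make_sv(start=1000, svlen=70)
        b = make_sv(start=1000, svlen=100)
        assert sv_pair_matches(a, b, MatchParams())  # exactly 0.7
        assert not sv_pair_matches(make_sv(start=1000, svlen=69), b, MatchParams())

    def test_distance_boundary(self):
        a = make_sv(start=1000, svlen=100)
        assert sv_pair_matches(a, make_sv(start=2000, svlen=100), MatchParams())
        assert not sv_pair_matches(a, make_sv(start=2001, svlen=100), MatchParams())

    def test_different_contigs_never_match(self):
        a = make_sv(chrom="chr1", start=1000, svlen=100)
        b = make_sv(chrom="chr2", start=1000, svlen=100)
        assert not sv_pair_matches(a, b, MatchParams())


class TestMatchCallsets:
    def test_identity(self):
        recs = [make_sv(start=s, svlen=100, id=f"v{s}") for s in range(0, 50_000, 5_000)]
        res = match_callsets(recs, recs)
        assert (res.tp, res.fp, res.fn) == (len(recs), 0, 0)
        assert res.precision == res.recall == 1.0

    def test_subset_recall(self):
        recs = [make_sv(start=s, svlen=100, id=f"v{s}") for s in range(0, 100_000, 10_000)]
        res = match_callsets(recs, recs[:6])
        assert res.recall == pytest.approx(0.6)
        assert res.precision == 1.0

    def test_undefined_rates_are_none(self):
        res = match_callsets([], [])
        assert res.precision is None and res.recall is None

    def test_size_window_excludes_records(self):
        small = make_sv(start=0, svlen=49, svtype="INS")
        big = make_sv(start=10_000, svlen=100)
        res = match_callsets([small, big], [big])
        assert (res.tp, res.fn) == (1, 0)  # the 49 bp record is ineligible

    def test_greedy_equals_bipartite_on_separated_instances(self, rng):
        params = MatchParams()
        for _ in range(60):
            base, comp = random_separated_instance(rng, params)
            got = match_callsets(base, comp, params).tp
            assert got == bipartite_max_tp(base, comp, params)

    def test_symmetry_swaps_precision_and_recall(self, rng):
        params = MatchParams()
        for _ in range(25):
            base, comp = random_separated_instance(rng, params)
            fwd = match_callsets(base, comp, params)
            rev = match_callsets(comp, base, params)
            assert fwd.tp == rev.tp
            assert fwd.precision == rev.recall and fwd.recall == rev.precision

    def test_monotone_in_refdist_and_ratio(self, rng):
        for _ in range(20):
            base, comp = random_separated_instance(rng, MatchParams())
            tp_tight = match_callsets(base, comp, MatchParams(refdist=300, size_ratio_min=0.9)).tp
            tp_mid = match_callsets(base, comp, MatchParams(refdist=1000, size_ratio_min=0.9)).tp
            tp_loose = match_callsets(base, comp, MatchParams(refdist=1000, size_ratio_min=0.7)).tp
            assert tp_tight <= tp_mid <= tp_loose

    def test_multimatch_recall_counts_base_once(self):
        base = [make_sv(start=1000, svlen=100, id="b")]
        comp = [make_sv(start=1100, svlen=100, id="c1"), make_sv(start=1200, svlen=100, id="c2")]
        res = match_callsets(base, comp, MatchParams(multimatch=True))
        assert len(res.pairs) == 2
        assert res.recall == 1.0 and res.precision == 1.0
        res1 = match_callsets(base, comp, MatchParams(multimatch=False))
        assert res1.tp == 1 and res1.fp == 1


class TestReciprocalOverlap:
    def test_half_overlap_boundary_inclusive(self):
        call = make_sv(start=100, svlen=100)
        ext = {"DEL": RegionSet([("chr1", 150, 250)])}
        assert reciprocal_overlap_compare([call], ext) == [True]

    def test_reciprocity_fails_one_sided(self):
        call = make_sv(start=100, svlen=100)
        ext = {"DEL": RegionSet([("chr1", 100, 120)])}
        assert reciprocal_overlap_compare([call], ext) == [False]

    def test_identical_intervals_match(self):
        call = make_sv(start=100, svlen=100)
        ext = {"DEL": RegionSet([("chr1", 100, 200)])}
        assert reciprocal_overlap_compare([call], ext) == [True]

    def test_ins_matched_by_anchor_distance_and_size(self):
        call = make_sv(start=5_000, svtype="INS", svlen=300)
        near = {"INS": RegionSet([("chr1", 5_400, 5_700)])}
        far = {"INS": RegionSet([("chr1", 7_000, 7_300)])}
        assert reciprocal_overlap_compare([call], near) == [True]
        assert reciprocal_overlap_compare([call], far) == [False]


def snv(pos, ref="A", alt="G", chrom="chr1"):
    return SNVRecord(chrom=chrom, pos=pos, ref_allele=ref, alt_allele=alt)


class TestSnvCompare:
    def test_partition_identical_disjoint_conservation(self):
        a = [snv(1), snv(2), snv(3, "C", "T")]
        shared, only_a, only_b = snv_set_compare(a, a)
        assert not only_a and not only_b and len(shared) == 3
        b = [snv(10), snv(11)]
        shared, only_a, only_b = snv_set_compare(a, b)
        assert not shared and len(only_a) == 3 and len(only_b) == 2
        shared, only_a, _ = snv_set_compare(a, [snv(1), snv(99)])
        assert len(a) == len(shared) + len(only_a)


class TestTiTv:
    def test_by_definition(self):
        snvs = [snv(i) for i in range(4)] + [snv(10, "A", "C"), snv(11, "A", "T")]
        assert ti_tv_ratio(snvs) == pytest.approx(2.0)

    def test_degenerate_all_transitions(self):
        assert math.isnan(ti_tv_ratio([snv(1), snv(2)]))
        assert math.isnan(ti_tv_ratio([]))

    def test_simulated_ratio_near_target(self, full_sim):
        """Configured ti_tv 2.1 recovered within 3 s.e. (delta method)."""
        n = len(full_sim.snv_records)
        target = full_sim.config.ti_tv_target
        p = target / (1 + target)
        se_ratio = math.sqrt(p * (1 - p) / n) / (1 - p) ** 2
        assert ti_tv_ratio(full_sim.snv_records) == pytest.approx(target, abs=3 * se_ratio)
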