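from fractions import Fraction

import networkx as nx
import numpy as np
import pytest

from splithom.formats_io import PipelineThresholds
from splithom.fulllength import ContaminationCutoff
from splithom.splitdetect import (
    GenomePlacedAlignment,
    call_split,
    expand_to_genomes,
    find_neighborhoods,
    joint_coverage,
)

from conftest import mk_feature, mk_record

CUTOFF = ContaminationCutoff(mean_pct_id=30.0, sd_pct_id=7.2667, k=3.0, cutoff=51.8)


def place(record, feature):
    return GenomePlacedAlignment(base=record, feature=feature)


class TestExpandToGenomes:
    def test_genomes_with_single_cluster_dropped(self):
        r1 = mk_record(query_id="C1", subject_id="H1")
        r2 = mk_record(query_id="C2", subject_id="H1")
        feats = [
            mk_feature(genome="g1", index=1, cluster="C1"),
            mk_feature(genome="g2", index=1, cluster="C1"),
            mk_feature(genome="g1", index=2, cluster="C2"),
        ]
        placed, warnings = expand_to_genomes([r1, r2], feats)
        assert {p.feature.genome_id for p in placed} == {"g1"}
        assert len(placed) == 2 and not warnings

    def test_no_shared_genome_empty(self):
        r1 = mk_record(query_id="C1", subject_id="H1")
        r2 = mk_record(query_id="C2", subject_id="H1")
        feats = [mk_feature(genome="g1", cluster="C1"),
                 mk_feature(genome="g2", cluster="C2")]
        placed, _ = expand_to_genomes([r1, r2], feats)
        assert placed == []

    def test_cluster_twice_in_one_genome_two_placements(self):
        r1 = mk_record(query_id="C1", subject_id="H1")
        r2 = mk_record(query_id="C2", subject_id="H1")
        feats = [
            mk_feature(index=1, cluster="C1"),
            mk_feature(index=10, cluster="C1"),
            mk_feature(index=2, cluster="C2"),
        ]
        placed, _ = expand_to_genomes([r1, r2], feats)
        assert sum(p.base.query_id == "C1" for p in placed) == 2

    def test_cluster_without_feature_warned_and_dropped(self):
        r1 = mk_record(query_id="C1", subject_id="H1")
        placed, warnings = expand_to_genomes([r1], [])
        assert placed == [] and "C1" in warnings[0]

    def test_mismatched_placement_rejected(self):
        with pytest.raises(ValueError):
            place(mk_record(query_id="C1"), mk_feature(cluster="C2"))


def _bitmask_coverage(intervals, s_len):
    mask = np.zeros(s_len, dtype=bool)
    for a, b in intervals:
        mask[a - 1 : b] = True
    return Fraction(int(mask.sum()), s_len)


class TestJointCoverage:
    @pytest.mark.parametrize(
        "intervals, s_len, expected",
        [
            ([(1, 40), (35, 80)], 100, Fraction(80, 100)),
            ([], 100, Fraction(0)),
            ([(1, 100)], 100, Fraction(1)),
            ([(1, 10), (11, 20)], 40, Fraction(20, 40)),  # adjacent, no overlap
            ([(5, 30), (10, 20)], 50, Fraction(26, 50)),  # containment
        ],
    )
    def test_examples(self, intervals, s_len, expected):
        assert joint_coverage(intervals, s_len) == expected

    def test_out_of_range_interval_rejected(self):
        with pytest.raises(ValueError):
            joint_coverage([(0, 10)], 100)

    def test_matches_bitmask_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(2000):
            s_len = int(rng.integers(1, 500))
            n = int(rng.integers(0, 8))
            ivs = []
            for _ in range(n):
                a = int(rng.integers(1, s_len + 1))
                b = int(rng.integers(a, s_len + 1))
                ivs.append((a, b))
            assert joint_coverage(ivs, s_len) == _bitmask_coverage(ivs, s_len)


def _brute_force_components(placed, max_gap):
    g = nx.Graph()
    g.add_nodes_from(range(len(placed)))
    for i, a in enumerate(placed):
        for j, b in enumerate(placed):
            if i < j and a.feature.contig_id == b.feature.contig_id \
                    and a.feature.strand == b.feature.strand \
                    and abs(a.feature.feature_index - b.feature.feature_index) <= max_gap:
                g.add_edge(i, j)
    comps = []
    for comp in nx.connected_components(g):
        members = [placed[i] for i in comp]
        if len({p.base.query_id for p in members}) >= 2:
            comps.append(frozenset(
                (p.base.query_id, p.feature.feature_index) for p in members
            ))
    return set(comps)


def _placed_at(indices, strands=None, contigs=None, subject="H1"):
    placed = []
    for k, idx in enumerate(indices):
        strand = strands[k] if strands else "+"
        contig = contigs[k] if contigs else "c1"
        r = mk_record(query_id=f"C{k}", subject_id=subject)
        placed.append(place(r, mk_feature(contig=contig, strand=strand,
                                          index=idx, cluster=f"C{k}")))
    return placed


class TestFindNeighborhoods:
    def test_close_pair_kept_isolated_dropped(self):
        comps = find_neighborhoods(_placed_at([3, 5, 9]), max_gap=3)
        assert len(comps) == 1
        assert {p.feature.feature_index for p in comps[0]} == {3, 5}

    def test_transitive_chaining(self):
        comps = find_neighborhoods(_placed_at([1, 4, 7]), max_gap=3)
        assert len(comps) == 1
        assert {p.feature.feature_index for p in comps[0]} == {1, 4, 7}

    def test_opposite_strands_never_neighbors(self):
        comps = find_neighborhoods(_placed_at([1, 3], strands=["+", "-"]), max_gap=3)
        assert comps == []

    def test_different_contigs_never_neighbors(self):
        comps = find_neighborhoods(_placed_at([1, 2], contigs=["c1", "c2"]), max_gap=3)
        assert comps == []

    def test_matches_brute_force_components(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            n = int(rng.integers(2, 13))
            indices = rng.choice(np.arange(1, 40), size=n, replace=False)
            strands = [("+", "-")[int(rng.integers(0, 2))] for _ in range(n)]
            contigs = [f"c{int(rng.integers(1, 3))}" for _ in range(n)]
            placed = []
            for k in range(n):
                cluster = f"C{int(rng.integers(0, max(2, n - 2)))}"
                r = mk_record(query_id=cluster, subject_id="H1")
                placed.append(place(r, mk_feature(
                    contig=contigs[k], strand=strands[k],
                    index=int(indices[k]), cluster=cluster)))
            gap = int(rng.integers(1, 5))
            ours = {
                frozenset((p.base.query_id, p.feature.feature_index) for p in comp)
                for comp in find_neighborhoods(placed, gap)
            }
            assert ours == _brute_force_components(placed, gap)


def _split_pair(subject="H1", genome="g1", s_len=100, covs=((1, 40), (41, 72)),
                strands=("+", "+"), contigs=("c1", "c1"), indices=(1, 2),
                identities=(30.0, 32.0)):
    records, feats = [], []
    for k, ((a, b), strand, contig, idx, pid) in enumerate(
        zip(covs, strands, contigs, indices, identities)
    ):
        records.append(mk_record(query_id=f"P{k}", subject_id=subject,
                                 s_start=a, s_end=b, s_len=s_len,
                                 pct_identity=pid, q_len=90))
        feats.append(mk_feature(genome=genome, contig=contig, strand=strand,
                                index=idx, cluster=f"P{k}"))
    return records, feats


class TestCallSplit:
    def test_planted_three_way_split_recovered(self, thresholds):
        records, feats = _split_pair(
            covs=((1, 30), (31, 60), (61, 90)), strands=("+",) * 3,
            contigs=("c1",) * 3, indices=(4, 6, 9), identities=(30.0, 31.0, 29.0),
        )
        calls, _ = call_split(records, feats, thresholds, CUTOFF)
        assert len(calls) == 1
        assert len(calls[0].members) == 3
        assert calls[0].joint_coverage == pytest.approx(0.9)

    def test_individually_covering_member_rejected(self, thresholds):
        # one member covers 0.75 alone: belongs to the full-length branch
        records, feats = _split_pair(covs=((1, 75), (76, 95)))
        calls, _ = call_split(records, feats, thresholds, CUTOFF)
        assert calls == []

    def test_gap_of_four_rejected(self, thresholds):
        records, feats = _split_pair(indices=(1, 5))
        calls, _ = call_split(records, feats, thresholds, CUTOFF)
        assert calls == []

    def test_joint_coverage_below_threshold_rejected(self, thresholds):
        records, feats = _split_pair(covs=((1, 30), (31, 60)))
        calls, _ = call_split(records, feats, thresholds, CUTOFF)
        assert calls == []

    def test_contaminant_member_removed_then_rechecked(self, thresholds):
        """A contaminant third member is dropped, and the surviving pair is
        re-evaluated: still jointly covering -> called; not -> dropped."""
        records, feats = _split_pair(
            covs=((1, 40), (41, 72), (30, 60)), strands=("+",) * 3,
            contigs=("c1",) * 3, indices=(1, 2, 3),
            identities=(30.0, 31.0, 95.0),
        )
        calls, _ = call_split(records, feats, thresholds, CUTOFF)
        assert len(calls) == 1
        assert all(c != "P2" for c, _ in calls[0].members)

        # same geometry, but the pair only jointly covers with the contaminant
        records, feats = _split_pair(
            covs=((1, 40), (41, 60), (55, 90)), strands=("+",) * 3,
            contigs=("c1",) * 3, indices=(1, 2, 3),
            identities=(30.0, 31.0, 95.0),
        )
        calls, _ = call_split(records, feats, thresholds, CUTOFF)
        assert calls == []

    def test_contaminant_removal_can_disconnect_component(self, thresholds):
        """Removing a bridging contaminant splits the chain; the remaining
        singletons cannot form a call."""
        records, feats = _split_pair(
            covs=((1, 40), (30, 60), (41, 72)), strands=("+",) * 3,
            contigs=("c1",) * 3, indices=(1, 4, 7),
            identities=(30.0, 95.0, 31.0),
        )
        calls, _ = call_split(records, feats, thresholds, CUTOFF)
        assert calls == []

    def test_two_loci_one_genome_yield_two_calls(self, thresholds):
        records, feats = _split_pair()
        # same clusters occur again far away on the contig
        feats += [mk_feature(index=50, cluster="P0"), mk_feature(index=51, cluster="P1")]
        calls, _ = call_split(records, feats, thresholds, CUTOFF)
        assert len(calls) == 2
        assert calls[0].min_feature_index == 1 and calls[1].min_feature_index == 50

    def test_no_member_also_full_length_for_same_pair(self, thresholds):
        """Any reported member's own coverage is < human_cov, so it cannot
        simultaneously be an accepted full-length call for that pair."""
        rng = np.random.default_rng(21)
        records, feats = [], []
        for k in range(60):
            s_len = 100
            a = int(rng.integers(1, 50))
            b = min(s_len, a + int(rng.integers(20, 80)))
            records.append(mk_record(query_id=f"C{k}", subject_id=f"H{k % 7}",
                                     s_start=a, s_end=b, s_len=s_len, q_len=90,
                                     pct_identity=float(rng.uniform(20, 45))))
            feats.append(mk_feature(genome=f"g{k % 5}", index=k + 1, cluster=f"C{k}"))
        calls, _ = call_split(records, feats, thresholds, CUTOFF)
        for call in calls:
            assert call.max_member_coverage < thresholds.human_cov
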