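import networkx as nx
import numpy as np
import pandas as pd
import pytest

from splithom.fulllength import FullLengthCall
from splithom.pharm import (
    ChemicalRecord,
    HomologCountSummary,
    ReactionRecord,
    chemicals_of_interest,
    filter_reactions,
    go_class_members,
    load_reference_drug_enzymes,
    load_reference_split_majority,
    load_reference_survey_counts,
    map_identifiers,
    select_split_majority,
    summarize_counts,
)
from splithom.splitdetect import SplitCall


class TestChemicalsOfInterest:
    @pytest.mark.parametrize(
        "chem_class, included",
        [("Drug", True), ("Drug Class", True), ("Prodrug", True),
         ("Metabolite", True), ("Biological Intermediate", False),
         (" Drug ", True), ("drug", False)],
    )
    def test_class_membership(self, chem_class, included):
        c = ChemicalRecord("X1", "x", chem_class)
        assert (chemicals_of_interest([c]) == {"X1"}) is included

    def test_empty_table(self):
        assert chemicals_of_interest([]) == set()


def _rx(reactant="A", product="B", controller="GENE1", rtype="Biochemical"):
    return ReactionRecord("R1", reactant, product, controller, rtype)


class TestFilterReactions:
    INTEREST = {"A"}

    def test_passing_reaction_kept(self):
        assert filter_reactions([_rx()], self.INTEREST) == [_rx()]

    @pytest.mark.parametrize(
        "rx",
        [
            _rx(reactant="A", product="A"),          # no transformation
            _rx(rtype="Transport"),                  # transport
            _rx(controller="unknown"),               # controller unknown
            _rx(controller=""),
            _rx(reactant="X", product="Y"),          # no chemical of interest
        ],
    )
    def test_each_predicate_individually_necessary(self, rx):
        assert filter_reactions([rx], self.INTEREST) == []

    def test_output_subset_of_input(self):
        rng = np.random.default_rng(31)
        rxs = [
            ReactionRecord(f"R{i}",
                           f"C{int(rng.integers(0, 4))}", f"C{int(rng.integers(0, 4))}",
                           ["GENE", "unknown"][int(rng.integers(0, 2))],
                           ["Biochemical", "Transport"][int(rng.integers(0, 2))])
            for i in range(100)
        ]
        kept = filter_reactions(rxs, {"C0"})
        assert set(kept) <= set(rxs)


class TestMapIdentifiers:
    TABLE = pd.DataFrame(
        {"hgnc_id": ["HGNC:1", "HGNC:2"], "uniprot_id": ["P1", "P2"]}
    )

    def test_one_to_one(self):
        mapping, unmapped = map_identifiers(self.TABLE, ["HGNC:1"])
        assert mapping == {"HGNC:1": "P1"} and unmapped == []

    def test_absent_gene_reported_not_dropped(self):
        mapping, unmapped = map_identifiers(self.TABLE, ["HGNC:1", "HGNC:9"])
        assert unmapped == ["HGNC:9"] and "HGNC:1" in mapping

    def test_conflicting_mapping_error(self):
        table = pd.DataFrame(
            {"hgnc_id": ["HGNC:1", "HGNC:1"], "uniprot_id": ["P1", "P9"]}
        )
        with pytest.raises(ValueError, match="HGNC:1"):
            map_identifiers(table, ["HGNC:1"])

    def test_duplicate_consistent_rows_fine(self):
        table = pd.DataFrame(
            {"hgnc_id": ["HGNC:1", "HGNC:1"], "uniprot_id": ["P1", "P1"]}
        )
        mapping, _ = map_identifiers(table, ["HGNC:1"])
        assert mapping == {"HGNC:1": "P1"}


class TestGoClassMembers:
    def _graph(self):
        g = nx.DiGraph()
        # child -> parent: nucleobase tree with an excludable acyl-CoA branch
        g.add_edges_from([
            ("purine", "nucleobase"), ("pyrimidine", "nucleobase"),
            ("acylcoa", "nucleobase"), ("coa", "acylcoa"),
            ("nucleobase", "metabolism"), ("redox", "metabolism"),
        ])
        return g

    def test_exclusion_is_gene_level(self):
        g = self._graph()
        annot = {
            "pA": {"purine"},
            "pB": {"purine", "coa"},   # touches excluded subtree: removed
            "pC": {"acylcoa"},
            "pD": {"redox"},
        }
        members = go_class_members(g, annot, "nucleobase", ["acylcoa"])
        assert members == {"pA"}

    def test_no_exclusions_is_plain_closure(self):
        g = self._graph()
        annot = {"pA": {"purine"}, "pD": {"redox"}}
        assert go_class_members(g, annot, "nucleobase") == {"pA"}
        assert go_class_members(g, annot, "redox") == {"pD"}

    def test_unknown_term_error(self):
        with pytest.raises(KeyError):
            go_class_members(self._graph(), {}, "nope")

    def test_exclusion_shrinks_membership(self):
        rng = np.random.default_rng(41)
        for _ in range(20):
            n = int(rng.integers(5, 15))
            g = nx.DiGraph()
            g.add_nodes_from(range(n))
            for child in range(1, n):
                g.add_edge(child, int(rng.integers(0, child)))
            annot = {
                f"p{i}": {int(t) for t in rng.choice(n, size=2)}
                for i in range(12)
            }
            root = 0
            ex = [int(rng.integers(1, n))]
            full = go_class_members(g, annot, root)
            reduced = go_class_members(g, annot, root, ex)
            assert reduced <= full
            # oracle by explicit closure algebra
            below_root = {root} | nx.ancestors(g, root)
            below_ex = {ex[0]} | nx.ancestors(g, ex[0])
            expected = {
                p for p, ts in annot.items()
                if ts & below_root and not ts & below_ex
            }
            assert reduced == expected


def _full(subject, query):
    return FullLengthCall(subject, query, 0.9, 0.9, 30.0, 100.0)


def _split(subject, genome, members, contig="c1"):
    return SplitCall(subject_id=subject, genome_id=genome, contig_id=contig,
                     strand="+", members=tuple(members), joint_coverage=0.8,
                     max_member_coverage=0.4)


class TestSummarizeCounts:
    CASES = [
        (0, 200, "split-only"),
        (24, 26, "split-majority"),
        (5, 5, "full-majority"),   # tie: not split-majority (strict rule)
        (3, 0, "full-only"),
        (0, 0, "none"),
    ]

    @pytest.mark.parametrize("n_full, n_split, category", CASES)
    def test_category_rules(self, n_full, n_split, category):
        s = HomologCountSummary("H", n_full, n_split)
        assert s.category == category
        assert s.split_majority is (n_split > n_full)

    def test_distinct_cluster_counting(self):
        full = [_full("H1", "C1"), _full("H1", "C1"), _full("H1", "C2")]
        split = [
            _split("H1", "g1", [("S1", 1), ("S2", 2)]),
            _split("H1", "g2", [("S1", 5), ("S3", 6)]),
        ]
        (s,) = summarize_counts(full, split)
        assert (s.n_full, s.n_split) == (2, 3)  # C1,C2 / S1,S2,S3

    def test_neighborhood_counting(self):
        split = [
            _split("H1", "g1", [("S1", 1), ("S2", 2)]),
            _split("H1", "g2", [("S1", 5), ("S3", 6)]),
        ]
        (s,) = summarize_counts([], split, counting_unit="distinct-neighborhoods")
        assert s.n_split == 2 and s.category == "split-only"

    def test_order_invariance_and_partition(self):
        rng = np.random.default_rng(47)
        full = [_full(f"H{int(rng.integers(0, 6))}", f"C{i}") for i in range(30)]
        split = [
            _split(f"H{int(rng.integers(0, 6))}", f"g{i}", [(f"S{i}", 1), (f"S{i}b", 2)])
            for i in range(20)
        ]
        a = summarize_counts(full, split)
        b = summarize_counts(list(reversed(full)), list(reversed(split)))
        assert a == b
        cats = {s.category for s in a}
        assert cats <= {"full-only", "full-majority", "split-majority", "split-only"}
        chosen = select_split_majority(a)
        assert all(s.n_split > s.n_full for s in chosen)
        assert all(s.n_split <= s.n_full for s in a if s not in chosen)


class TestReferenceTables:
    def test_split_majority_table_counts(self):
        df = load_reference_split_majority()
        summaries = [
            HomologCountSummary(r.entry, int(r.n_full), int(r.n_split))
            for r in df.itertuples()
        ]
        assert len(select_split_majority(summaries)) == 23
        assert sum(1 for s in summaries if s.n_full == 0) == 16
        assert {s.category for s in summaries} <= {"split-majority", "split-only"}

    def test_drug_enzyme_table_all_split_majority(self):
        df = load_reference_drug_enzymes()
        assert len(df) == 4
        assert (df.n_split > df.n_full).all()
        fu = df[df.drugs.str.contains("fluorouracil")]
        assert set(fu.enzyme) == {"DPYD", "UMPS"}

    def test_survey_percentages(self):
        counts = load_reference_survey_counts()
        pct_any = 100 * counts["proteins_with_homolog"] / counts["proteins_screened"]
        pct_full = 100 * counts["proteins_full_majority"] / counts["proteins_with_homolog"]
        assert round(pct_any) == 82
        assert round(pct_full) == 97
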