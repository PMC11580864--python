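"""Drug-metabolism annotation layer.

Connects the homolog calls to pharmacogenomic knowledge: which chemicals are
actual drugs, prodrugs or drug metabolites (as opposed to endogenous
intermediates), which curated reactions represent genuine enzymatic
transformations of those chemicals, how gene symbols map to protein
accessions, which proteins fall into ontology-defined enzyme classes
(nucleobase-compound metabolism with exclusions; oxidoreductases), and
per-human-protein counts of full-length vs split homologs with a categorical
classification (full-only / full-majority / split-majority / split-only).

A small reference table of published split-majority homolog counts ships
with the package (``splithom/data``) for worked examples and summary
arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .formats_io import GenomeFeature
from .fulllength import FullLengthCall
from .splitdetect import SplitCall

__all__ = [
    "ChemicalRecord",
    "ReactionRecord",
    "HomologCountSummary",
    "CHEMICAL_CLASSES_OF_INTEREST",
    "chemicals_of_interest",
    "filter_reactions",
    "map_identifiers",
    "go_class_members",
    "summarize_counts",
    "select_split_majority",
    "load_reference_split_majority",
    "load_reference_drug_enzymes",
    "load_reference_survey_counts",
]

#: Chemical classes counted as "of interest": pharmaceutical agents and their
#: downstream metabolites. Endogenous "Biological Intermediate" entries are
#: deliberately absent.
CHEMICAL_CLASSES_OF_INTEREST = frozenset(
    {"Drug", "Drug Class", "Prodrug", "Metabolite"}
)


@dataclass(frozen=True)
class ChemicalRecord:
    chemical_id: str
    name: str
    chem_class: str


@dataclass(frozen=True)
class ReactionRecord:
    reaction_id: str
    reactant_id: str
    product_id: str
    controller: str  # gene/enzyme id, or "" / "unknown" when not curated
    reaction_type: str

    @property
    def controller_known(self) -> bool:
        return self.controller.strip().lower() not in {"", "unknown", "na", "n/a"}


@dataclass(frozen=True)
class HomologCountSummary:
    """Per human protein: how many full-length and split homologs, and the
    resulting category.

    Categories partition all proteins with >= 1 homolog plus "none":
    full-only (n_split == 0 < n_full), full-majority (0 < n_split <= n_full),
    split-majority (n_full in (0, n_split)), split-only (n_full == 0 < n_split).
    """

    human_id: str
    n_full: int
    n_split: int

    @property
    def category(self) -> str:
        if self.n_full == 0 and self.n_split == 0:
            return "none"
        if self.n_split == 0:
            return "full-only"
        if self.n_full == 0:
            return "split-only"
        return "split-majority" if self.n_split > self.n_full else "full-majority"

    @property
    def split_majority(self) -> bool:
        """Strictly more split than full-length homologs (includes
        split-only)."""
        return self.n_split > self.n_full


def chemicals_of_interest(chemicals: Iterable[ChemicalRecord]) -> set[str]:
    """Ids of chemicals whose class (exact match after whitespace trimming)
    is Drug, Drug Class, Prodrug, or Metabolite."""
    return {
        c.chemical_id
        for c in chemicals
        if c.chem_class.strip() in CHEMICAL_CLASSES_OF_INTEREST
    }


def filter_reactions(
    reactions: Iterable[ReactionRecord], interest: set[str]
) -> list[ReactionRecord]:
    """Keep reactions that (i) transform (reactant != product), (ii) are not
    Transport, (iii) have a known controller, and (iv) touch at least one
    chemical of interest. All four predicates apply conjunctively."""
    return [
        r
        for r in reactions
        if r.reactant_id != r.product_id
        and r.reaction_type.strip() != "Transport"
        and r.controller_known
        and (r.reactant_id in interest or r.product_id in interest)
    ]


def map_identifiers(
    hgnc_table: pd.DataFrame,
    genes: Iterable[str],
    gene_col: str = "hgnc_id",
    accession_col: str = "uniprot_id",
) -> tuple[dict[str, str], list[str]]:
    """Map gene identifiers to protein accessions via a lookup table.

    Returns (mapping, unmapped). A gene mapped to two different accessions
    raises ValueError naming the conflicts; genes absent from the table are
    returned in ``unmapped`` rather than dropped silently.
    """
    table = hgnc_table[[gene_col, accession_col]].dropna()
    grouped = table.groupby(gene_col)[accession_col].agg(lambda s: sorted(set(s)))
    conflicts = {g: accs for g, accs in grouped.items() if len(accs) > 1}
    if conflicts:
        listing = "; ".join(f"{g} -> {accs}" for g, accs in sorted(conflicts.items()))
        raise ValueError(f"conflicting identifier mappings: {listing}")
    lookup = {g: accs[0] for g, accs in grouped.items()}
    mapping: dict[str, str] = {}
    unmapped: list[str] = []
    for g in genes:
        if g in lookup:
            mapping[g] = lookup[g]
        else:
            unmapped.append(g)
    return mapping, unmapped


def _closure_below(graph: nx.DiGraph, root: str) -> set[str]:
    """Root plus every term below it (graph edges run child -> parent, so
    terms below the root are its graph ancestors)."""
    if root not in graph:
        raise KeyError(f"unknown ontology term: {root}")
    return {root} | nx.ancestors(graph, root)


def go_class_members(
    graph: nx.DiGraph,
    annot_closed: Mapping[str, set[str]],
    root_term: str,
    excluded_roots: Sequence[str] = (),
) -> set[str]:
    """Proteins annotated within a term's subtree, minus those annotated
    anywhere within any excluded subtree.

    Exclusion is gene-level: one annotation inside an excluded subtree
    removes the protein entirely. With no exclusions this is a plain
    ontology-class membership query.
    """
    include = _closure_below(graph, root_term)
    exclude: set[str] = set()
    for ex in excluded_roots:
        exclude |= _closure_below(graph, ex)
    members = {
        p for p, terms in annot_closed.items() if terms & include
    }
    return {p for p in members if not (annot_closed[p] & exclude)}


def summarize_counts(
    full_calls: Sequence[FullLengthCall],
    split_calls: Sequence[SplitCall],
    counting_unit: str = "distinct-clusters",
    features: Sequence[GenomeFeature] | None = None,
) -> list[HomologCountSummary]:
    """Count full-length and split homologs per human protein.

    ``counting_unit``:

    distinct-clusters
        full: clusters with an accepted call; split: clusters participating
        in >= 1 split neighborhood (default).
    distinct-genomes
        genomes carrying >= 1 call (full-length counting needs ``features``
        to resolve clusters to genomes).
    distinct-neighborhoods
        split: accepted neighborhoods; full: accepted calls.

    Output is ordered by descending n_split, then descending n_full, then
    accession, and is invariant to input order.
    """
    if counting_unit not in {
        "distinct-clusters", "distinct-genomes", "distinct-neighborhoods"
    }:
        raise ValueError(f"unknown counting unit {counting_unit!r}")

    full_units: dict[str, set] = {}
    split_units: dict[str, set] = {}

    if counting_unit == "distinct-genomes":
        if features is None:
            raise ValueError("distinct-genomes counting requires the feature table")
        genomes_of: dict[str, set[str]] = {}
        for f in features:
            genomes_of.setdefault(f.cluster_id, set()).add(f.genome_id)

    for c in full_calls:
        units = full_units.setdefault(c.subject_id, set())
        if counting_unit == "distinct-genomes":
            units |= genomes_of.get(c.query_id, set())
        else:
            units.add(c.query_id)
    for s in split_calls:
        units = split_units.setdefault(s.subject_id, set())
        if counting_unit == "distinct-clusters":
            units |= set(s.cluster_ids)
        elif counting_unit == "distinct-genomes":
            units.add(s.genome_id)
        else:
            units.add((s.genome_id, s.contig_id, s.min_feature_index))

    summaries = [
        HomologCountSummary(
            human_id=h,
            n_full=len(full_units.get(h, ())),
            n_split=len(split_units.get(h, ())),
        )
        for h in sorted(set(full_units) | set(split_units))
    ]
    summaries.sort(key=lambda s: (-s.n_split, -s.n_full, s.human_id))
    return summaries


def select_split_majority(
    summaries: Iterable[HomologCountSummary],
) -> list[HomologCountSummary]:
    """Proteins with strictly more split than full-length homologs."""
    return [s for s in summaries if s.split_majority]


# ---------------------------------------------------------------------------
# Packaged reference tables


def _load_data_tsv(name: str) -> pd.DataFrame:
    with resources.files("splithom.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def load_reference_split_majority() -> pd.DataFrame:
    """Published reference table of the human proteins with more split than
    full-length gut microbial homologs (accession, entry name, description,
    n_full, n_split)."""
    return _load_data_tsv("split_majority_proteins.tsv")


def load_reference_drug_enzymes() -> pd.DataFrame:
    """Published reference table of drug-metabolizing enzymes with more
    split than full-length gut homologs and the drugs they act on."""
    return _load_data_tsv("split_majority_drug_enzymes.tsv")


def load_reference_survey_counts() -> dict[str, int]:
    """Headline counts of the published drug-metabolizing-enzyme survey:
    how many curated drug-metabolism proteins were screened, how many had
    any gut homolog, how many of those were full-majority, and how many
    drugs that full-majority set metabolizes."""
    df = _load_data_tsv("drug_enzyme_survey_counts.tsv")
    return dict(zip(df["quantity"], df["count"].astype(int)))
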