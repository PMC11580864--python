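"""Xenobiotic enzyme-family classification and phylogenetic diversity.

Human proteins are assigned to broad xenobiotic-enzyme classes (short-chain
reductases, aldo-keto reductases, cytochrome P450s, ...) by regular-
expression matches against their curated protein-family description strings.
For each class, the set of microbial species carrying at least one
full-length homolog is summarized by Faith's phylogenetic diversity (PD):
the sum of branch lengths of the minimal subtree spanning those species on a
midpoint-rooted species tree. A class found only in one small clade has low
PD however many species carry it; a class scattered across the tree has
high PD.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd

from .fulllength import FullLengthCall

__all__ = [
    "FamilyRule",
    "DEFAULT_FAMILY_RULES",
    "classify_family",
    "midpoint_root",
    "faith_pd",
    "presence_counts",
    "pd_ranking",
]


@dataclass(frozen=True)
class FamilyRule:
    class_code: str
    pattern: str

    def matches(self, family_string: str) -> bool:
        return re.search(self.pattern, family_string) is not None


#: Default rule set, in declared priority order: ten classic xenobiotic
#: enzyme families recognized by their protein-family description strings,
#: plus the aldehyde dehydrogenases. First match wins.
DEFAULT_FAMILY_RULES: tuple[FamilyRule, ...] = (
    FamilyRule("akr", r"Aldo/keto reductase family"),
    FamilyRule("udp", r"UDP-glycosyltransferase family"),
    FamilyRule("gst", r"GST superfamily"),
    FamilyRule("aryl", r"Arylamine N-acetyltransferase family"),
    FamilyRule("gdxg", r"'GDXG' lipolytic enzyme family"),
    FamilyRule("cyto", r"Cytochrome P450 family"),
    FamilyRule("ester", r"Type-B carboxylesterase/lipase family"),
    FamilyRule("flavin", r"Flavin monoamine oxidase family|FMO family"),
    FamilyRule("sdr", r"Short-chain dehydrogenases/reductases \(SDR\)"),
    FamilyRule("quin", r"Quinone oxidoreductase subfamily"),
    FamilyRule("aldh", r"Aldehyde dehydrogenase family"),
)


def classify_family(
    family_string: str,
    rules: Sequence[FamilyRule] = DEFAULT_FAMILY_RULES,
) -> str | None:
    """Return the class code of the first rule matching the family
    description string, or None."""
    for rule in rules:
        if rule.matches(family_string):
            return rule.class_code
    return None


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Midpoint-root a copy of the tree: the root is placed halfway along the
    longest tip-to-tip path. Total branch length is preserved."""
    tips = [leaf for leaf in tree.leaf_node_iter()]
    if len(tips) < 2:
        raise ValueError("midpoint rooting requires >= 2 tips")
    total = tree.length()
    if total == 0:
        raise ValueError("tree has zero total branch length")
    rooted = tree.clone(depth=1)
    # collapse a pre-existing bifurcating root so rerooting starts from the
    # unrooted topology (rerooting at an edge incident to the old root is
    # otherwise degenerate)
    if len(rooted.seed_node.child_nodes()) == 2:
        rooted.collapse_basal_bifurcation()
    rooted.is_rooted = True
    rooted.reroot_at_midpoint(update_bipartitions=False)
    new_total = rooted.length()
    if abs(new_total - total) > 1e-9 * max(1.0, total):
        raise AssertionError(
            f"midpoint rooting changed total branch length: {total} -> {new_total}"
        )
    return rooted


def faith_pd(
    tree: dendropy.Tree, tips: Iterable[str], include_root: bool = True
) -> float:
    """Faith's phylogenetic diversity of a tip set.

    Root-inclusive by default (the convention of the classic R
    implementation): the sum of branch lengths of the union of root-to-tip
    paths. With ``include_root=False`` the edges between the root and the
    most recent common ancestor of the tip set are excluded, so a single tip
    has PD 0.
    """
    wanted = set(tips)
    if not wanted:
        raise ValueError("tip set must be nonempty")
    label_to_leaf = {
        leaf.taxon.label: leaf for leaf in tree.leaf_node_iter() if leaf.taxon
    }
    missing = sorted(wanted - set(label_to_leaf))
    if missing:
        raise KeyError(f"tips not in tree: {', '.join(missing)}")

    used: set[int] = set()  # ids of nodes whose incident (parent) edge counts
    pd_sum = 0.0
    for label in sorted(wanted):
        node = label_to_leaf[label]
        while node.parent_node is not None and id(node) not in used:
            used.add(id(node))
            pd_sum += node.edge.length or 0.0
            node = node.parent_node

    if not include_root:
        # deepest common ancestor of the tip set, computed on root paths so
        # the result does not depend on dendropy's rooted/unrooted semantics
        paths = []
        for label in sorted(wanted):
            path = []
            node = label_to_leaf[label]
            while node is not None:
                path.append(node)
                node = node.parent_node
            paths.append(list(reversed(path)))  # root first
        depth = 0
        while all(len(p) > depth for p in paths) and len(
            {id(p[depth]) for p in paths}
        ) == 1:
            depth += 1
        mrca = paths[0][depth - 1]
        node = mrca
        while node.parent_node is not None:
            pd_sum -= node.edge.length or 0.0
            node = node.parent_node
    return pd_sum


def presence_counts(
    full_calls: Sequence[FullLengthCall],
    cluster_species: Mapping[str, set[str]],
    family_map: Mapping[str, str | None],
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Species-presence and homolog-count matrices per xenobiotic class.

    ``cluster_species`` maps a microbial cluster id to the species encoding
    it; ``family_map`` maps a human protein accession to its class code (or
    None for unclassified, which is skipped). Returns (species_counts,
    homolog_counts, warnings): species_counts has one row per species and
    one column per class with cells in {0,1} aggregable to "number of unique
    species per class"; homolog_counts counts distinct cluster ids per
    (species, class). Calls whose cluster resolves to no species are
    reported in the warning list.
    """
    rows: list[tuple[str, str, str]] = []
    warnings: list[str] = []
    for call in full_calls:
        code = family_map.get(call.subject_id)
        if code is None:
            continue
        species = cluster_species.get(call.query_id)
        if not species:
            warnings.append(
                f"cluster {call.query_id} (human {call.subject_id}) has no species"
            )
            continue
        for sp in sorted(species):
            rows.append((sp, code, call.query_id))
    if not rows:
        empty = pd.DataFrame()
        return empty, empty, warnings
    df = pd.DataFrame(rows, columns=["species", "class_code", "cluster_id"])
    species_counts = (
        df.drop_duplicates(["species", "class_code"])
        .assign(present=1)
        .pivot_table(index="species", columns="class_code", values="present",
                     fill_value=0, aggfunc="sum")
        .astype(int)
    )
    homolog_counts = (
        df.pivot_table(index="species", columns="class_code", values="cluster_id",
                       aggfunc=lambda s: s.nunique(), fill_value=0)
        .astype(int)
    )
    return species_counts, homolog_counts, warnings


def pd_ranking(
    species_counts: pd.DataFrame,
    tree: dendropy.Tree,
    include_root: bool = True,
) -> pd.DataFrame:
    """Rank classes by descending Faith's PD of the species that carry them.

    Returns a DataFrame (class_code, n_species, faith_pd) sorted by
    descending PD, ties broken by class code.
    """
    records = []
    for code in species_counts.columns:
        spp = set(species_counts.index[species_counts[code] > 0])
        value = faith_pd(tree, spp, include_root=include_root) if spp else 0.0
        records.append({"class_code": code, "n_species": len(spp), "faith_pd": value})
    out = pd.DataFrame(records)
    return out.sort_values(
        ["faith_pd", "class_code"], ascending=[False, True]
    ).reset_index(drop=True)
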