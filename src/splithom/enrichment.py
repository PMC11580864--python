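"""Term enrichment and subcellular-localization statistics.

Given the sets of human proteins carrying full-length or split microbial
homologs, this module asks what those proteins do (term over-representation,
one-sided Fisher's exact test on annotations propagated up the ontology DAG
under the true-path rule, Benjamini-Hochberg corrected) and where they live
(mitochondrial-localization odds ratio from a 2x2 Fisher table, optionally
stratified by how frequently the homologs were detected).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import scipy.stats as st
from scipy.stats.contingency import odds_ratio as _cond_odds_ratio
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentResult",
    "OddsRatioResult",
    "propagate_annotations",
    "fisher_enrichment",
    "bh_adjust",
    "mitochondrial_flags",
    "localization_odds_ratio",
    "stratified_enrichment",
    "MITO_REGEX",
]

#: Cellular-component term names matching this pattern mark a protein as
#: mitochondrially localized.
MITO_REGEX = re.compile(r"[Mm]itochondr")


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    study_count: int
    study_total: int
    background_count: int
    background_total: int
    p_value: float
    p_adjusted: float


@dataclass(frozen=True)
class OddsRatioResult:
    """2x2 association result.

    ``odds_ratio`` is the conditional maximum-likelihood estimate (the value
    R's fisher.test reports), with its exact conditional confidence interval;
    ``sample_odds_ratio`` is the plain cross-product ad/bc, computed with a
    Haldane-Anscombe 0.5 correction (and flagged) when any cell is zero.
    The p-value is the two-sided Fisher exact test.
    """

    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    sample_odds_ratio: float
    haldane_corrected: bool = False


def propagate_annotations(
    graph: nx.DiGraph, annot: Mapping[str, set[str]]
) -> dict[str, set[str]]:
    """Close each protein's term set upward under the true-path rule.

    ``graph`` has child->parent edges, so a term's ancestors are its
    descendants in the graph. Terms absent from the graph are kept as-is
    (they have no known ancestors). Idempotent.
    """
    ancestor_cache: dict[str, set[str]] = {}

    def ancestors(term: str) -> set[str]:
        if term not in ancestor_cache:
            ancestor_cache[term] = (
                nx.descendants(graph, term) if term in graph else set()
            )
        return ancestor_cache[term]

    closed: dict[str, set[str]] = {}
    for protein, terms in annot.items():
        full = set(terms)
        for t in terms:
            full |= ancestors(t)
        closed[protein] = full
    return closed


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved,
    clipped to [0,1]."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_enrichment(
    study: set[str],
    background: set[str],
    annot_closed: Mapping[str, set[str]],
    min_background_count: int = 1,
    algorithm: str = "classic",
) -> list[EnrichmentResult]:
    """Per-term over-representation of ``study`` within ``background``.

    For each term annotating >= ``min_background_count`` background proteins,
    the one-sided (greater) Fisher exact p-value of the 2x2 table
    (in study & in term, ...) is the hypergeometric upper tail; BH adjustment
    is applied across all tested terms. ``algorithm="elim"`` processes terms
    from most to least specific (fewest background annotations first) and
    removes the proteins of any term significant at p < 0.01 from its
    ancestors before they are tested, a decorrelation of the DAG; the default
    "classic" tests every term independently.
    """
    if not study <= background:
        raise ValueError("study set must be a subset of the background set")
    term_proteins: dict[str, set[str]] = {}
    for protein in background:
        for term in annot_closed.get(protein, ()):
            term_proteins.setdefault(term, set()).add(protein)
    terms = sorted(
        t for t, ps in term_proteins.items() if len(ps) >= min_background_count
    )

    N = len(background)
    n = len(study)
    removed: dict[str, set[str]] = {t: set() for t in terms}

    if algorithm == "elim":
        order = sorted(terms, key=lambda t: (len(term_proteins[t]), t))
    elif algorithm == "classic":
        order = terms
    else:
        raise ValueError(f"unknown enrichment algorithm {algorithm!r}")

    raw: dict[str, tuple[float, int, int]] = {}
    for term in order:
        proteins = term_proteins[term] - removed[term]
        K = len(proteins)
        k = len(proteins & study)
        # hypergeometric upper tail P(X >= k) == one-sided Fisher "greater"
        p = float(st.hypergeom.sf(k - 1, N, K, n))
        raw[term] = (min(p, 1.0), k, K)
        if algorithm == "elim" and p < 0.01:
            # remove this term's proteins from every more general term
            for other in terms:
                if other != term and term_proteins[term] <= term_proteins[other]:
                    removed[other] |= term_proteins[term]

    pvals = [raw[t][0] for t in terms]
    padj = bh_adjust(pvals)
    results = [
        EnrichmentResult(
            term=t,
            study_count=raw[t][1],
            study_total=n,
            background_count=raw[t][2],
            background_total=N,
            p_value=raw[t][0],
            p_adjusted=float(max(pa, raw[t][0])),
        )
        for t, pa in zip(terms, padj)
    ]
    results.sort(key=lambda r: (r.p_adjusted, r.p_value, r.term))
    return results


def mitochondrial_flags(
    annot: Mapping[str, set[tuple[str, str]]], graph: nx.DiGraph
) -> dict[str, bool]:
    """Flag proteins whose cellular-component annotations (direct, by term
    name) match the mitochondrial regex."""
    flags: dict[str, bool] = {}
    for protein, terms in annot.items():
        hit = False
        for term, namespace in terms:
            if namespace != "cellular_component":
                continue
            name = graph.nodes[term].get("name", term) if term in graph else term
            if MITO_REGEX.search(name):
                hit = True
                break
        flags[protein] = hit
    return flags


def localization_odds_ratio(
    group: set[str],
    is_mito: Mapping[str, bool],
    background: set[str],
) -> OddsRatioResult:
    """2x2 test of mitochondrial localization of ``group`` vs the rest of
    the background."""
    if not group:
        raise ValueError("empty group")
    if not group <= background:
        raise ValueError("group must be a subset of the background set")
    rest = background - group
    a = sum(1 for p in group if is_mito.get(p, False))
    b = len(group) - a
    c = sum(1 for p in rest if is_mito.get(p, False))
    d = len(rest) - c
    return odds_ratio_from_table(((a, b), (c, d)))


def odds_ratio_from_table(
    table: tuple[tuple[int, int], tuple[int, int]],
) -> OddsRatioResult:
    (a, b), (c, d) = table
    arr = np.array(table, dtype=int)
    _, p = st.fisher_exact(arr, alternative="two-sided")
    res = _cond_odds_ratio(arr)
    try:
        ci = res.confidence_interval(0.95)
        ci_low, ci_high = float(ci.low), float(ci.high)
    except Exception:  # degenerate margins
        ci_low, ci_high = 0.0, np.inf
    haldane = min(a, b, c, d) == 0
    if haldane:
        sample = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        sample = (a * d) / (b * c)
    return OddsRatioResult(
        table=((a, b), (c, d)),
        odds_ratio=float(res.statistic),
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=float(p),
        sample_odds_ratio=float(sample),
        haldane_corrected=haldane,
    )


def stratified_enrichment(
    groups: Sequence[set[str]],
    is_mito: Mapping[str, bool],
    background: set[str],
) -> tuple[list[OddsRatioResult | None], float]:
    """Localization odds ratio per ordered bin (e.g. proteins binned by how
    many genomes carry their homolog), plus a Spearman trend of the sample
    odds ratio against bin rank.

    Empty bins yield None (skipped with a warning in the CLI layer) and are
    excluded from the trend. With fewer than two non-empty bins the trend is
    NaN.
    """
    results: list[OddsRatioResult | None] = []
    for g in groups:
        results.append(localization_odds_ratio(g, is_mito, background) if g else None)
    ranks = [i for i, r in enumerate(results) if r is not None]
    ors = [results[i].sample_odds_ratio for i in ranks]
    if len(ranks) < 2 or len(set(ors)) == 1:
        trend = float("nan")
    else:
        trend = float(st.spearmanr(ranks, ors).statistic)
    return results, trend
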