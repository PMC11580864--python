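"""Seeded synthetic-data generator with known ground truth.

The generator emulates the statistical structure the homolog-calling
pipeline assumes, standing in for a real protein-catalog-vs-proteome search:

* planted full-length homologs — one microbial cluster whose single HSP
  covers the human protein and itself with margin above the thresholds,
  percent identity drawn from a truncated Normal on [10, 50] whose
  post-truncation moments match (identity_mean, identity_sd);
* planted split homologs — a human protein's span partitioned over 2-3
  adjacent same-strand genes in one genome, jointly covering >= 70% of the
  human protein while each fragment alone covers well under 70%;
* labeled decoy configurations, one mechanism per class, each designed to be
  rejected by exactly one filter: strand-flip, contig-split, gap-4 (gene
  ranks four apart), undercoverage (joint coverage ~0.5), individual-cover
  (one member alone covers >= 70%), and contaminant (identity drawn from the
  same Normal truncated to [90, 100], emulating human reads assembled into
  microbial genomes).

Alongside the alignment and feature tables the generator emits the fixtures
the downstream statistics consume: a small ontology DAG with annotations
whose mitochondrial-localization rate is elevated among proteins with
planted full-length homologs, protein-family description strings drawn from
the xenobiotic class vocabulary, a random bifurcating species tree with
exponential branch lengths, a genome-to-species map, and drug/reaction/gene
tables in the pharmacogenomics dialect.

Everything is derived from one master seed through independent per-table
streams, so outputs are byte-identical across runs and adding one table does
not perturb the others.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
from scipy import optimize
from scipy import stats as st

from . import formats_io
from .formats_io import AlignmentRecord, GenomeFeature, file_sha256
from .fulllength import FullLengthCall
from .splitdetect import SplitCall

__all__ = [
    "GeneratorParams",
    "GroundTruth",
    "SplitTruth",
    "SyntheticBundle",
    "DECOY_CLASSES",
    "generate",
    "write_fixture_bundle",
    "evaluate_calls",
    "BUNDLE_FILES",
]

DECOY_CLASSES = (
    "strand-flip",
    "contig-split",
    "gap-4",
    "undercoverage",
    "individual-cover",
    "contaminant",
)

#: Canonical file names of a written fixture bundle.
BUNDLE_FILES = {
    "alignments": "alignments.tsv",
    "features": "features.tsv",
    "ontology_edges": "ontology_edges.tsv",
    "ontology_terms": "ontology_terms.tsv",
    "annotations": "annotations.tsv",
    "families": "families.tsv",
    "tree": "species_tree.nwk",
    "species_map": "species_map.tsv",
    "chemicals": "chemicals.tsv",
    "reactions": "reactions.tsv",
    "hgnc": "hgnc.tsv",
    "truth": "truth.json",
}


@dataclass(frozen=True)
class GeneratorParams:
    """Study conditions for one synthetic dataset.

    ``p_full`` is the probability, per (human protein, genome), of planting
    a full-length homolog; ``p_split`` likewise for a split neighborhood of
    ``n_fragments`` (drawn uniformly from the given inclusive range) genes.
    ``decoy_rates`` maps decoy class to the per-human-protein probability of
    planting one decoy instance of that class.
    """

    n_genomes: int = 50
    n_human_proteins: int = 100
    human_len_range: tuple[int, int] = (300, 700)
    p_full: float = 0.3
    p_split: float = 0.2
    n_fragments: tuple[int, int] = (2, 3)
    identity_mean: float = 30.0
    identity_sd: float = 7.27
    identity_bounds: tuple[float, float] = (10.0, 50.0)
    contaminant_bounds: tuple[float, float] = (90.0, 100.0)
    decoy_rates: Mapping[str, float] = field(default_factory=dict)
    secondary_hit_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_full", "p_split", "secondary_hit_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.identity_sd < 0:
            raise ValueError("identity_sd must be >= 0")
        for cls, rate in self.decoy_rates.items():
            if cls not in DECOY_CLASSES:
                raise ValueError(f"unknown decoy class {cls!r}")
            if not 0 <= rate <= 1:
                raise ValueError(f"decoy rate for {cls} must be in [0,1]")
        if self.human_len_range[0] < 250:
            raise ValueError(
                "human_len_range minimum must be >= 250 aa so that three "
                "fragments can each satisfy the microbe-coverage filter"
            )
        if not (2 <= self.n_fragments[0] <= self.n_fragments[1] <= 3):
            raise ValueError("n_fragments must lie within [2, 3]")


@dataclass(frozen=True)
class SplitTruth:
    human: str
    genome: str
    contig: str
    strand: str
    members: tuple[tuple[str, int], ...]  # (cluster_id, feature_index)


@dataclass
class GroundTruth:
    """What was planted, for exact precision/recall scoring."""

    full_pairs: set[tuple[str, str]] = field(default_factory=set)  # (human, cluster)
    split_neighborhoods: list[SplitTruth] = field(default_factory=list)
    decoys: dict[str, list[dict]] = field(
        default_factory=lambda: {c: [] for c in DECOY_CLASSES}
    )
    #: individual-cover decoys contain one genuinely full-length member;
    #: it is a correct full-length call, not a leak.
    expected_full_from_decoys: set[tuple[str, str]] = field(default_factory=set)


@dataclass
class SyntheticBundle:
    params: GeneratorParams
    alignments: list[AlignmentRecord]
    features: list[GenomeFeature]
    truth: GroundTruth
    ontology_edges: list[tuple[str, str]]
    ontology_terms: list[tuple[str, str, str]]  # (term, namespace, name)
    annotations: list[tuple[str, str, str]]  # (protein, term, namespace)
    family_strings: dict[str, str]
    tree: dendropy.Tree
    species_map: dict[str, str]  # genome -> species
    chemicals: list[tuple[str, str, str]]  # (chemical_id, name, chem_class)
    reactions: list[tuple[str, str, str, str, str]]
    hgnc: list[tuple[str, str]]  # (hgnc_id, uniprot_id)
    human_lengths: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# identity distributions


import functools


@functools.lru_cache(maxsize=64)
def _truncnorm_params(mean: float, sd: float, lo: float, hi: float):
    """Find (loc, scale) of a Normal whose truncation to [lo, hi] has the
    requested mean and SD, so the sample moments stay interpretable."""
    if sd == 0:
        return mean, 0.0
    loc = mean
    scale = sd
    for _ in range(25):
        def sd_err(s: float, loc=loc) -> float:
            a, b = (lo - loc) / s, (hi - loc) / s
            return st.truncnorm.std(a, b, loc=loc, scale=s) - sd

        hi_scale = sd * 8
        if sd_err(hi_scale) < 0:  # target unreachable: bounds too tight
            raise ValueError(
                f"identity_sd {sd} not attainable under truncation to [{lo},{hi}]"
            )
        scale = optimize.brentq(sd_err, sd * 0.5, hi_scale, xtol=1e-10)
        a, b = (lo - loc) / scale, (hi - loc) / scale
        shift = mean - st.truncnorm.mean(a, b, loc=loc, scale=scale)
        loc += shift
        if abs(shift) < 1e-10:
            break
    return loc, scale


def _genuine_identities(
    rng: np.random.Generator, n: int, params: GeneratorParams
) -> np.ndarray:
    lo, hi = params.identity_bounds
    loc, scale = _truncnorm_params(params.identity_mean, params.identity_sd, lo, hi)
    if scale == 0:
        return np.full(n, loc)
    a, b = (lo - loc) / scale, (hi - loc) / scale
    return st.truncnorm.rvs(a, b, loc=loc, scale=scale, size=n, random_state=rng)


def _contaminant_identities(
    rng: np.random.Generator, n: int, params: GeneratorParams
) -> np.ndarray:
    lo, hi = params.contaminant_bounds
    a = (lo - params.identity_mean) / params.identity_sd
    b = (hi - params.identity_mean) / params.identity_sd
    return st.truncnorm.rvs(
        a, b, loc=params.identity_mean, scale=params.identity_sd, size=n,
        random_state=rng,
    )


# ---------------------------------------------------------------------------
# generator internals


class _FeatureAllocator:
    """Hands out gene ranks per (genome, contig); successive allocations are
    separated by a buffer wider than any neighborhood gap so independently
    planted items can never chain into one component."""

    BUFFER = 8

    def __init__(self) -> None:
        self._cursor: dict[tuple[str, str], int] = {}

    def take(self, genome: str, contig: str, gaps: Sequence[int]) -> list[int]:
        """Allocate len(gaps)+1 ranks; consecutive ranks differ by gaps[i]."""
        start = self._cursor.get((genome, contig), 1)
        indices = [start]
        for g in gaps:
            indices.append(indices[-1] + g)
        self._cursor[(genome, contig)] = indices[-1] + self.BUFFER
        return indices


def _mk_alignment(
    cluster: str, human: str, s_start: int, s_end: int, s_len: int,
    pct_id: float, rng: np.random.Generator,
    q_cov: float | None = None, min_q_len: int = 80,
) -> AlignmentRecord:
    """Build one HSP whose query coverage passes the microbe filter."""
    span = s_end - s_start + 1
    u = q_cov if q_cov is not None else rng.uniform(0.75, 0.92)
    q_len = max(min_q_len, int(round(span / u)))
    q_span = min(span, q_len)
    q_start = int(rng.integers(1, q_len - q_span + 2))
    bitscore = round(2.0 * span * pct_id / 100.0, 1)
    evalue = float(f"{10 ** -min(180.0, bitscore / 4.0):.3e}")
    return AlignmentRecord(
        query_id=cluster, subject_id=human, pct_identity=round(float(pct_id), 1),
        aln_len=span, q_start=q_start, q_end=q_start + q_span - 1,
        s_start=s_start, s_end=s_end, evalue=evalue, bitscore=bitscore,
        q_len=q_len, s_len=s_len,
    )


def _plant_fragments(
    human: str, s_len: int, n_frag: int, identities: np.ndarray,
    cluster_prefix: str, rng: np.random.Generator,
    joint_frac: float,
) -> tuple[list[tuple[str, int, int, float]], None]:
    """Partition a covered span of joint_frac * s_len into n_frag contiguous
    fragments; returns [(cluster, s_start, s_end, identity)]."""
    covered = int(round(joint_frac * s_len))
    weights = rng.uniform(0.9, 1.1, size=n_frag)
    sizes = np.maximum(1, np.round(covered * weights / weights.sum())).astype(int)
    sizes[-1] = covered - int(sizes[:-1].sum())
    offset = int(rng.integers(1, s_len - covered + 2))
    frags = []
    pos = offset
    for k in range(n_frag):
        frags.append(
            (f"{cluster_prefix}_{k}", pos, pos + int(sizes[k]) - 1, float(identities[k]))
        )
        pos += int(sizes[k])
    return frags, None


def generate(params: GeneratorParams) -> SyntheticBundle:
    """Generate one synthetic dataset; deterministic under ``params.seed``."""
    ss = np.random.SeedSequence(params.seed)
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ["human", "full", "split", "decoy", "annot", "tree", "pharm"],
            np.random.SeedSequence(params.seed).spawn(7),
        )
    }
    del ss
    H, G = params.n_human_proteins, params.n_genomes
    humans = [f"H{i:04d}" for i in range(H)]
    genomes = [f"G{j:04d}" for j in range(G)]
    rng_h = streams["human"]
    lengths = {
        h: int(rng_h.integers(params.human_len_range[0], params.human_len_range[1] + 1))
        for h in humans
    }

    alloc = _FeatureAllocator()
    alignments: list[AlignmentRecord] = []
    features: list[GenomeFeature] = []
    truth = GroundTruth()

    # --- full-length homologs -------------------------------------------
    rng_f = streams["full"]
    plant_full = rng_f.random((H, G)) < params.p_full
    n_full = int(plant_full.sum())
    full_ids = _genuine_identities(rng_f, n_full, params)
    idx = 0
    for i, h in enumerate(humans):
        for j, g in enumerate(genomes):
            if not plant_full[i, j]:
                continue
            cluster = f"F_{h}_{g}"
            s_len = lengths[h]
            cov = rng_f.uniform(0.75, 0.95)
            span = int(round(cov * s_len))
            s_start = int(rng_f.integers(1, s_len - span + 2))
            rec = _mk_alignment(
                cluster, h, s_start, s_start + span - 1, s_len,
                full_ids[idx], rng_f, q_cov=float(rng_f.uniform(0.75, 0.92)),
                min_q_len=max(80, int(rng_f.integers(90, 140))),
            )
            idx += 1
            alignments.append(rec)
            contig = f"c{int(rng_f.integers(1, 3))}"
            strand = "+" if rng_f.random() < 0.5 else "-"
            fi = alloc.take(g, contig, [])[0]
            features.append(GenomeFeature(g, contig, strand, fi, cluster))
            truth.full_pairs.add((h, cluster))
            if rng_f.random() < params.secondary_hit_rate and H > 1:
                other = humans[(i + 1 + int(rng_f.integers(0, H - 1))) % H]
                if other != h:
                    o_len = lengths[other]
                    o_span = max(30, int(round(0.3 * o_len)))
                    o_start = int(rng_f.integers(1, o_len - o_span + 2))
                    weak = _mk_alignment(
                        cluster, other, o_start, o_start + o_span - 1, o_len,
                        min(50.0, full_ids[idx - 1]), rng_f, q_cov=0.4,
                        min_q_len=rec.q_len,
                    )
                    weak = dataclasses.replace(
                        weak, bitscore=round(rec.bitscore * 0.5, 1),
                        q_len=rec.q_len,
                        q_start=1, q_end=max(1, int(rec.q_len * 0.4)),
                    )
                    alignments.append(weak)

    # --- split homologs --------------------------------------------------
    rng_s = streams["split"]
    plant_split = rng_s.random((H, G)) < params.p_split
    for i, h in enumerate(humans):
        for j, g in enumerate(genomes):
            if not plant_split[i, j]:
                continue
            s_len = lengths[h]
            n_frag = int(rng_s.integers(params.n_fragments[0], params.n_fragments[1] + 1))
            ids = _genuine_identities(rng_s, n_frag, params)
            frags, _ = _plant_fragments(
                h, s_len, n_frag, ids, f"P_{h}_{g}", rng_s,
                joint_frac=float(rng_s.uniform(0.78, 0.95)),
            )
            contig = f"c{int(rng_s.integers(1, 3))}"
            strand = "+" if rng_s.random() < 0.5 else "-"
            gaps = [int(rng_s.integers(1, 4)) for _ in range(n_frag - 1)]
            indices = alloc.take(g, contig, gaps)
            members = []
            for (cluster, s0, s1, pid), fi in zip(frags, indices):
                alignments.append(
                    _mk_alignment(cluster, h, s0, s1, s_len, pid, rng_s)
                )
                features.append(GenomeFeature(g, contig, strand, fi, cluster))
                members.append((cluster, fi))
            truth.split_neighborhoods.append(
                SplitTruth(
                    human=h, genome=g, contig=contig, strand=strand,
                    members=tuple(sorted(members, key=lambda m: (m[1], m[0]))),
                )
            )

    # --- decoys ----------------------------------------------------------
    rng_d = streams["decoy"]
    for cls in DECOY_CLASSES:
        rate = params.decoy_rates.get(cls, 0.0)
        if rate == 0:
            continue
        for i, h in enumerate(humans):
            if rng_d.random() >= rate:
                continue
            g = genomes[int(rng_d.integers(0, G))]
            s_len = lengths[h]
            _plant_decoy(cls, h, g, s_len, params, rng_d, alloc,
                         alignments, features, truth)

    # --- annotations / ontology -----------------------------------------
    rng_a = streams["annot"]
    ontology_terms, ontology_edges = _fixed_ontology()
    has_full = {h for h, _ in truth.full_pairs}
    annotations: list[tuple[str, str, str]] = []
    family_strings: dict[str, str] = {}
    family_pool = [
        "Aldo/keto reductase family",
        "UDP-glycosyltransferase family",
        "GST superfamily",
        "Arylamine N-acetyltransferase family",
        "'GDXG' lipolytic enzyme family",
        "Cytochrome P450 family",
        "Type-B carboxylesterase/lipase family",
        "FMO family",
        "Short-chain dehydrogenases/reductases (SDR) family",
        "Quinone oxidoreductase subfamily",
        "Aldehyde dehydrogenase family",
    ]
    for h in humans:
        full = h in has_full
        p_mito = 0.45 if full else 0.12
        cc = "GO:CC0002" if rng_a.random() < p_mito else "GO:CC0001"
        annotations.append((h, cc, "cellular_component"))
        if rng_a.random() < (0.5 if full else 0.1):
            annotations.append((h, "GO:BP0002", "biological_process"))
        if rng_a.random() < 0.25:
            annotations.append((h, "GO:BP0011", "biological_process"))
            if rng_a.random() < 0.3:
                annotations.append((h, "GO:BP0012", "biological_process"))
        if rng_a.random() < 0.2:
            annotations.append((h, "GO:MF0002", "molecular_function"))
        if full and rng_a.random() < 0.6:
            family_strings[h] = family_pool[int(rng_a.integers(0, len(family_pool)))]
        else:
            family_strings[h] = "Uncharacterized protein family"

    # --- species tree & map ---------------------------------------------
    rng_t = streams["tree"]
    species = [f"S{j:04d}" for j in range(G)]
    species_map = dict(zip(genomes, species))
    tree = _random_bifurcating_tree(species, rng_t)

    # --- pharm fixtures ---------------------------------------------------
    rng_p = streams["pharm"]
    chemicals, reactions, hgnc = _pharm_fixtures(humans, rng_p)

    return SyntheticBundle(
        params=params, alignments=alignments, features=features, truth=truth,
        ontology_edges=ontology_edges, ontology_terms=ontology_terms,
        annotations=annotations, family_strings=family_strings,
        tree=tree, species_map=species_map,
        chemicals=chemicals, reactions=reactions, hgnc=hgnc,
        human_lengths=lengths,
    )


def _plant_decoy(
    cls: str, h: str, g: str, s_len: int, params: GeneratorParams,
    rng: np.random.Generator, alloc: _FeatureAllocator,
    alignments: list, features: list, truth: GroundTruth,
) -> None:
    tag = f"D{cls.replace('-', '')}_{h}_{g}"
    strand = "+" if rng.random() < 0.5 else "-"
    flip = "-" if strand == "+" else "+"
    contig = "c1"

    if cls == "contaminant":
        pid = float(_contaminant_identities(rng, 1, params)[0])
        cov = rng.uniform(0.75, 0.9)
        span = int(round(cov * s_len))
        s0 = int(rng.integers(1, s_len - span + 2))
        cluster = f"{tag}_0"
        alignments.append(_mk_alignment(cluster, h, s0, s0 + span - 1, s_len, pid, rng))
        fi = alloc.take(g, contig, [])[0]
        features.append(GenomeFeature(g, contig, strand, fi, cluster))
        truth.decoys[cls].append(
            {"human": h, "genome": g, "clusters": (cluster,)}
        )
        return

    if cls == "undercoverage":
        joint = 0.50
    elif cls == "individual-cover":
        joint = 0.95
    else:
        joint = float(rng.uniform(0.78, 0.92))
    ids = _genuine_identities(rng, 2, params)
    if cls == "individual-cover":
        # one member alone covers >= 70%: belongs to the full-length branch
        big = int(round(0.75 * s_len))
        small = int(round(0.20 * s_len))
        s0 = int(rng.integers(1, s_len - big - small + 2))
        frags = [
            (f"{tag}_0", s0, s0 + big - 1, float(ids[0])),
            (f"{tag}_1", s0 + big, s0 + big + small - 1, float(ids[1])),
        ]
    else:
        frags, _ = _plant_fragments(h, s_len, 2, ids, tag, rng, joint_frac=joint)

    if cls == "gap-4":
        gaps = [4]
    else:
        gaps = [int(rng.integers(1, 4))]
    if cls == "contig-split":
        indices = [alloc.take(g, "c1", [])[0], alloc.take(g, "c2", [])[0]]
        contigs = ["c1", "c2"]
        strands = [strand, strand]
    else:
        indices = alloc.take(g, contig, gaps)
        contigs = [contig, contig]
        strands = [strand, flip] if cls == "strand-flip" else [strand, strand]

    clusters = []
    for (cluster, s0, s1, pid), fi, ctg, strd in zip(frags, indices, contigs, strands):
        alignments.append(_mk_alignment(cluster, h, s0, s1, s_len, pid, rng))
        features.append(GenomeFeature(g, ctg, strd, fi, cluster))
        clusters.append(cluster)
    truth.decoys[cls].append({"human": h, "genome": g, "clusters": tuple(clusters)})
    if cls == "individual-cover":
        truth.expected_full_from_decoys.add((h, frags[0][0]))


def _fixed_ontology() -> tuple[list[tuple[str, str, str]], list[tuple[str, str]]]:
    """A small fixed DAG: a biological-process branch with a xenobiotic term
    and a nucleobase-compound subtree (with an excludable acyl-CoA child), a
    cellular-component branch with a mitochondrion term, and a molecular-
    function branch with an oxidoreductase term."""
    terms = [
        ("GO:BP0001", "biological_process", "biological_process"),
        ("GO:BP0002", "biological_process", "xenobiotic metabolic process"),
        ("GO:BP0010", "biological_process", "metabolic process"),
        ("GO:BP0011", "biological_process", "nucleobase-containing compound metabolic process"),
        ("GO:BP0012", "biological_process", "purine metabolic process"),
        ("GO:BP0013", "biological_process", "acyl-CoA metabolic process"),
        ("GO:BP0014", "biological_process", "coenzyme A metabolic process"),
        ("GO:CC0000", "cellular_component", "cellular_component"),
        ("GO:CC0001", "cellular_component", "cytoplasm"),
        ("GO:CC0002", "cellular_component", "mitochondrion"),
        ("GO:CC0003", "cellular_component", "mitochondrial matrix"),
        ("GO:MF0001", "molecular_function", "catalytic activity"),
        ("GO:MF0002", "molecular_function", "oxidoreductase activity"),
    ]
    edges = [
        ("GO:BP0002", "GO:BP0010"),
        ("GO:BP0010", "GO:BP0001"),
        ("GO:BP0011", "GO:BP0010"),
        ("GO:BP0012", "GO:BP0011"),
        ("GO:BP0013", "GO:BP0011"),
        ("GO:BP0014", "GO:BP0013"),
        ("GO:CC0001", "GO:CC0000"),
        ("GO:CC0002", "GO:CC0001"),
        ("GO:CC0003", "GO:CC0002"),
        ("GO:MF0002", "GO:MF0001"),
    ]
    return terms, edges


def _random_bifurcating_tree(
    species: Sequence[str], rng: np.random.Generator, rate: float = 10.0
) -> dendropy.Tree:
    """Random topology by iteratively joining two subtrees; branch lengths
    Exponential(rate)."""
    nodes = [f"{s}:{rng.exponential(1 / rate):.6f}" for s in species]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        merged = f"({a},{b}):{rng.exponential(1 / rate):.6f}"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(merged)
    newick = nodes[0]
    newick = newick.rsplit(":", 1)[0] + ";"  # root has no branch
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


def _pharm_fixtures(humans: Sequence[str], rng: np.random.Generator):
    """Small chemical/reaction/gene tables exercising each reaction filter."""
    chemicals = [
        ("CH0001", "drugA", "Drug"),
        ("CH0002", "drugB", "Prodrug"),
        ("CH0003", "metabolite-of-A", "Metabolite"),
        ("CH0004", "drug-class-X", "Drug Class"),
        ("CH0005", "endogenous-intermediate", "Biological Intermediate"),
        ("CH0006", "cofactor", "Biological Intermediate"),
    ]
    n = min(12, len(humans))
    genes = [f"HGNC:{1000 + k}" for k in range(n)]
    hgnc = list(zip(genes, humans[:n]))
    reactions = []
    for k in range(n):
        reactions.append(
            (f"RX{k:03d}", "CH0001", "CH0003", genes[k], "Biochemical")
        )
    # decoy reactions, one per rejected predicate
    reactions += [
        ("RX900", "CH0001", "CH0001", genes[0], "Biochemical"),   # same reactant/product
        ("RX901", "CH0001", "CH0003", genes[0], "Transport"),     # transport
        ("RX902", "CH0001", "CH0003", "unknown", "Biochemical"),  # unknown controller
        ("RX903", "CH0005", "CH0006", genes[0], "Biochemical"),   # no chemical of interest
    ]
    return chemicals, reactions, hgnc


# ---------------------------------------------------------------------------
# bundle I/O


def write_fixture_bundle(bundle: SyntheticBundle, outdir: str | Path) -> Path:
    """Write every table of the bundle in its external format plus a manifest
    TSV (file name, sha256) carrying the generator parameters as '#'
    comments. Returns the manifest path."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    fi = formats_io
    fi.write_blast_tab(bundle.alignments, out / BUNDLE_FILES["alignments"])
    fi.write_feature_table(bundle.features, out / BUNDLE_FILES["features"])
    fi.write_tsv(
        [{"child": c, "parent": p} for c, p in bundle.ontology_edges],
        ["child", "parent"], out / BUNDLE_FILES["ontology_edges"],
    )
    fi.write_tsv(
        [{"term": t, "namespace": ns, "name": nm} for t, ns, nm in bundle.ontology_terms],
        ["term", "namespace", "name"], out / BUNDLE_FILES["ontology_terms"],
    )
    fi.write_tsv(
        [{"protein": p, "term": t, "namespace": ns} for p, t, ns in bundle.annotations],
        ["protein", "term", "namespace"], out / BUNDLE_FILES["annotations"],
    )
    fi.write_tsv(
        [{"protein": p, "family": f} for p, f in bundle.family_strings.items()],
        ["protein", "family"], out / BUNDLE_FILES["families"],
    )
    fi.write_newick(bundle.tree, out / BUNDLE_FILES["tree"])
    fi.write_tsv(
        [{"genome_id": g, "species": s} for g, s in bundle.species_map.items()],
        ["genome_id", "species"], out / BUNDLE_FILES["species_map"],
    )
    fi.write_tsv(
        [{"chemical_id": c, "name": n, "chem_class": k} for c, n, k in bundle.chemicals],
        ["chemical_id", "name", "chem_class"], out / BUNDLE_FILES["chemicals"],
    )
    fi.write_tsv(
        [
            {"reaction_id": r, "reactant_id": a, "product_id": b,
             "controller": c, "reaction_type": t}
            for r, a, b, c, t in bundle.reactions
        ],
        ["reaction_id", "reactant_id", "product_id", "controller", "reaction_type"],
        out / BUNDLE_FILES["reactions"],
    )
    fi.write_tsv(
        [{"hgnc_id": g, "uniprot_id": u} for g, u in bundle.hgnc],
        ["hgnc_id", "uniprot_id"], out / BUNDLE_FILES["hgnc"],
    )
    truth_json = {
        "full_pairs": sorted(list(p) for p in bundle.truth.full_pairs),
        "split_neighborhoods": [
            {
                "human": t.human, "genome": t.genome, "contig": t.contig,
                "strand": t.strand,
                "members": [list(m) for m in t.members],
            }
            for t in bundle.truth.split_neighborhoods
        ],
        "decoys": {
            cls: [
                {"human": d["human"], "genome": d["genome"],
                 "clusters": list(d["clusters"])}
                for d in ds
            ]
            for cls, ds in bundle.truth.decoys.items()
        },
        "expected_full_from_decoys": sorted(
            list(p) for p in bundle.truth.expected_full_from_decoys
        ),
    }
    (out / BUNDLE_FILES["truth"]).write_text(
        json.dumps(truth_json, indent=1, sort_keys=True) + "\n"
    )

    names = sorted(BUNDLE_FILES.values())
    manifest = out / "manifest.tsv"
    with open(manifest, "w") as fh:
        fh.write(f"# generator params: {bundle.params}\n")
        fh.write("file\tsha256\n")
        for name in names:
            fh.write(f"{name}\t{file_sha256(out / name)}\n")
    return manifest


def load_truth(path: str | Path) -> GroundTruth:
    """Read back a truth.json written by :func:`write_fixture_bundle`."""
    data = json.loads(Path(path).read_text())
    truth = GroundTruth()
    truth.full_pairs = {tuple(p) for p in data["full_pairs"]}
    truth.split_neighborhoods = [
        SplitTruth(
            human=t["human"], genome=t["genome"], contig=t["contig"],
            strand=t["strand"],
            members=tuple(tuple(m) for m in t["members"]),
        )
        for t in data["split_neighborhoods"]
    ]
    truth.decoys = {
        cls: [
            {"human": d["human"], "genome": d["genome"],
             "clusters": tuple(d["clusters"])}
            for d in ds
        ]
        for cls, ds in data["decoys"].items()
    }
    truth.expected_full_from_decoys = {
        tuple(p) for p in data["expected_full_from_decoys"]
    }
    return truth


# ---------------------------------------------------------------------------
# scoring


def evaluate_calls(
    truth: GroundTruth,
    full_calls: Sequence[FullLengthCall],
    split_calls: Sequence[SplitCall],
) -> dict[str, float | dict[str, int]]:
    """Score pipeline output against the planted truth.

    Full-length calls are compared as (human, cluster) pairs (planted pairs
    plus the genuinely full-length members of individual-cover decoys);
    split calls as (human, genome, member set) triples. Decoy leaks count,
    per class, planted decoy clusters appearing in any split call — or, for
    the contaminant class, in any full-length call.
    """
    pred_full = {(c.subject_id, c.query_id) for c in full_calls}
    exp_full = truth.full_pairs | truth.expected_full_from_decoys
    tp_full = len(pred_full & exp_full)
    pred_split = {(s.subject_id, s.genome_id, s.members) for s in split_calls}
    exp_split = {(t.human, t.genome, t.members) for t in truth.split_neighborhoods}
    tp_split = len(pred_split & exp_split)

    split_member_clusters = {c for s in split_calls for c in s.cluster_ids}
    full_clusters = {c.query_id for c in full_calls}
    leaks: dict[str, int] = {}
    totals: dict[str, int] = {}
    for cls, decoys in truth.decoys.items():
        totals[cls] = len(decoys)
        n_leak = 0
        for d in decoys:
            pool = full_clusters if cls == "contaminant" else split_member_clusters
            if any(c in pool for c in d["clusters"]):
                n_leak += 1
        leaks[cls] = n_leak

    def _ratio(num: int, den: int) -> float:
        return 1.0 if den == 0 else num / den

    return {
        "full_precision": _ratio(tp_full, len(pred_full)),
        "full_recall": _ratio(tp_full, len(exp_full)),
        "split_precision": _ratio(tp_split, len(pred_split)),
        "split_recall": _ratio(tp_split, len(exp_split)),
        "decoy_totals": totals,
        "decoy_leaks": leaks,
    }
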