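"""Readers, writers, and the domain types every other module consumes.

All coordinates are 1-based inclusive, as in BLAST tabular output; converting
a record's subject interval to a half-open interval and back is the identity.
Readers are strict: a malformed row raises with its line number rather than
being dropped silently, and annotation references to unknown ontology terms
are collected into a warning report instead of disappearing.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import networkx as nx

__all__ = [
    "AlignmentRecord",
    "GenomeFeature",
    "PipelineThresholds",
    "ParseError",
    "read_blast_tab",
    "write_blast_tab",
    "read_feature_table",
    "write_feature_table",
    "read_newick",
    "write_newick",
    "read_ontology",
    "read_annotations",
    "read_family_strings",
    "write_tsv",
    "read_tsv",
]

#: Column order of the expected BLAST tabular dialect: the 12 standard
#: ``outfmt 6`` columns followed by query length and subject length.
BLAST_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore qlen slen"
).split()


class ParseError(ValueError):
    """A malformed input file; the message names the offending line or id."""


@dataclass(frozen=True, order=True)
class AlignmentRecord:
    """One local-alignment HSP between a microbial cluster representative
    (query) and a human protein (subject)."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_len: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float
    q_len: int
    s_len: int

    def __post_init__(self) -> None:
        if not (1 <= self.q_start <= self.q_end <= self.q_len):
            raise ValueError(
                f"invalid query coordinates {self.q_start}-{self.q_end} "
                f"for qlen {self.q_len} ({self.query_id}->{self.subject_id})"
            )
        if not (1 <= self.s_start <= self.s_end <= self.s_len):
            raise ValueError(
                f"invalid subject coordinates {self.s_start}-{self.s_end} "
                f"for slen {self.s_len} ({self.query_id}->{self.subject_id})"
            )
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError(f"pct_identity out of [0,100]: {self.pct_identity}")
        if self.evalue < 0:
            raise ValueError(f"negative evalue: {self.evalue}")

    @property
    def query_coverage(self) -> Fraction:
        """Fraction of the microbial (query) sequence covered by this HSP."""
        return Fraction(self.q_end - self.q_start + 1, self.q_len)

    @property
    def subject_coverage(self) -> Fraction:
        """Fraction of the human (subject) sequence covered by this HSP."""
        return Fraction(self.s_end - self.s_start + 1, self.s_len)

    @property
    def subject_interval(self) -> tuple[int, int]:
        """1-based inclusive [start, end] on the human protein."""
        return (self.s_start, self.s_end)


@dataclass(frozen=True, order=True)
class GenomeFeature:
    """One gene occurrence: where a protein cluster is encoded in a genome.

    ``feature_index`` is the ordinal rank of the gene along its contig (gene
    order, not base pairs); neighborhood distances are differences of ranks.
    """

    genome_id: str
    contig_id: str
    strand: str
    feature_index: int
    cluster_id: str

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.feature_index < 1:
            raise ValueError(f"feature_index must be >= 1, got {self.feature_index}")


@dataclass(frozen=True)
class PipelineThresholds:
    """Filter thresholds for the homolog-calling pipeline.

    Defaults: a single HSP must cover >= 2/3 of the microbial protein
    (exact rational comparison) and the microbial protein must be >= 80 aa;
    individual (full-length) or joint (split) coverage of the human protein
    must be >= 0.70; split neighborhoods may span gaps of at most 3 gene
    ranks; the contamination ceiling is mean + 3 SD of the percent-identity
    distribution of full-length survivors.
    """

    microbe_cov: Fraction | float = Fraction(2, 3)
    human_cov: float = 0.70
    min_microbe_len: int = 80
    max_feature_gap: int = 3
    contamination_sd: float = 3.0

    def __post_init__(self) -> None:
        for name in ("microbe_cov", "human_cov"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.min_microbe_len < 1:
            raise ValueError("min_microbe_len must be >= 1")
        if self.max_feature_gap < 1:
            raise ValueError("max_feature_gap must be >= 1")
        if self.contamination_sd < 0:
            raise ValueError("contamination_sd must be >= 0")


# ---------------------------------------------------------------------------
# BLAST tabular


def _data_lines(path: str | Path) -> Iterable[tuple[int, str]]:
    """Yield (1-based line number, stripped line), skipping '#' comments and
    blank lines."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def read_blast_tab(path: str | Path) -> list[AlignmentRecord]:
    """Read a 14-column BLAST tabular file (std outfmt 6 + qlen + slen).

    Row order is preserved; coordinates are kept 1-based inclusive exactly as
    in the file. A row with the wrong column count, a non-numeric field, or
    inverted coordinates raises :class:`ParseError` naming the line.
    """
    records: list[AlignmentRecord] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != len(BLAST_COLUMNS):
            raise ParseError(
                f"{path}:{lineno}: expected {len(BLAST_COLUMNS)} columns, "
                f"got {len(fields)}"
            )
        try:
            rec = AlignmentRecord(
                query_id=fields[0],
                subject_id=fields[1],
                pct_identity=float(fields[2]),
                aln_len=int(fields[3]),
                q_start=int(fields[6]),
                q_end=int(fields[7]),
                s_start=int(fields[8]),
                s_end=int(fields[9]),
                evalue=float(fields[10]),
                bitscore=float(fields[11]),
                q_len=int(fields[12]),
                s_len=int(fields[13]),
            )
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        records.append(rec)
    return records


def write_blast_tab(
    records: Iterable[AlignmentRecord], path: str | Path, comment: str | None = None
) -> None:
    """Write records in the same 14-column dialect read_blast_tab expects."""
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        for r in records:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        r.query_id, r.subject_id, r.pct_identity, r.aln_len,
                        0, 0,  # mismatch/gapopen: not consumed downstream
                        r.q_start, r.q_end, r.s_start, r.s_end,
                        r.evalue, r.bitscore, r.q_len, r.s_len,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Genome feature tables

_FEATURE_TSV_COLUMNS = ["genome_id", "contig_id", "strand", "feature_index", "cluster_id"]
_ID_SUFFIX_RE = re.compile(r"_(\d+)$")


def _check_feature_invariants(features: list[GenomeFeature]) -> list[GenomeFeature]:
    seen: set[tuple[str, str, int]] = set()
    for f in features:
        key = (f.genome_id, f.contig_id, f.feature_index)
        if key in seen:
            raise ParseError(
                f"duplicate feature index {f.feature_index} on "
                f"{f.genome_id}/{f.contig_id}"
            )
        seen.add(key)
    features.sort(key=lambda f: (f.genome_id, f.contig_id, f.feature_index))
    return features


def feature_index_from_gene_id(gene_id: str) -> int:
    """Parse gene-order rank from a trailing zero-padded integer suffix
    (e.g. ``GUT_GENOME228173_01934`` -> 1934)."""
    m = _ID_SUFFIX_RE.search(gene_id)
    if m is None:
        raise ParseError(f"gene id {gene_id!r} has no trailing integer suffix")
    return int(m.group(1))


def read_feature_table(
    path: str | Path,
    format: str = "tsv",
    genome_id: str | None = None,
) -> list[GenomeFeature]:
    """Read gene occurrences in one of three dialects.

    ``tsv``
        Columns genome_id, contig_id, strand, feature_index, cluster_id
        (header optional).
    ``id-suffix``
        Columns gene_id, genome_id, contig_id, strand, cluster_id; the
        feature index is parsed from the gene id's trailing integer suffix,
        the convention of gut protein-catalog gene identifiers.
    ``gff3``
        Standard GFF3; the feature index is the rank of each CDS start within
        its contig, the cluster id comes from a ``cluster_id=`` (fall back
        ``ID=``) attribute, and ``genome_id`` must be supplied by the caller.

    Output is sorted by (genome, contig, feature_index); duplicate
    (genome, contig, feature_index) triples raise :class:`ParseError`.
    """
    if format == "tsv":
        return _read_feature_tsv(path)
    if format == "id-suffix":
        return _read_feature_id_suffix(path)
    if format == "gff3":
        if genome_id is None:
            raise ValueError("gff3 mode requires genome_id")
        return _read_feature_gff3(path, genome_id)
    raise ValueError(f"unknown feature-table format: {format!r}")


def _read_feature_tsv(path: str | Path) -> list[GenomeFeature]:
    features = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if fields[:4] == _FEATURE_TSV_COLUMNS[:4]:  # header
            continue
        if len(fields) != 5:
            raise ParseError(f"{path}:{lineno}: expected 5 columns, got {len(fields)}")
        try:
            features.append(
                GenomeFeature(fields[0], fields[1], fields[2], int(fields[3]), fields[4])
            )
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return _check_feature_invariants(features)


def _read_feature_id_suffix(path: str | Path) -> list[GenomeFeature]:
    features = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if fields[0] == "gene_id":  # header
            continue
        if len(fields) != 5:
            raise ParseError(f"{path}:{lineno}: expected 5 columns, got {len(fields)}")
        gene_id, genome, contig, strand, cluster = fields
        try:
            idx = feature_index_from_gene_id(gene_id)
            features.append(GenomeFeature(genome, contig, strand, idx, cluster))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return _check_feature_invariants(features)


def _read_feature_gff3(path: str | Path, genome_id: str) -> list[GenomeFeature]:
    rows: list[tuple[str, int, str, str]] = []  # (contig, start, strand, cluster)
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 9:
            raise ParseError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(fields)}")
        seqid, _source, ftype, start, _end, _score, strand, _phase, attrs = fields
        if ftype != "CDS":
            continue
        attr_map = dict(
            kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
        )
        cluster = attr_map.get("cluster_id", attr_map.get("ID"))
        if cluster is None:
            raise ParseError(f"{path}:{lineno}: CDS has neither cluster_id= nor ID=")
        try:
            rows.append((seqid, int(start), strand, cluster))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    features = []
    by_contig: dict[str, list[tuple[int, str, str]]] = {}
    for contig, start, strand, cluster in rows:
        by_contig.setdefault(contig, []).append((start, strand, cluster))
    for contig, entries in by_contig.items():
        for rank, (_start, strand, cluster) in enumerate(sorted(entries), start=1):
            features.append(GenomeFeature(genome_id, contig, strand, rank, cluster))
    return _check_feature_invariants(features)


def write_feature_table(
    features: Iterable[GenomeFeature], path: str | Path, comment: str | None = None
) -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write("\t".join(_FEATURE_TSV_COLUMNS) + "\n")
        for f in features:
            fh.write(
                f"{f.genome_id}\t{f.contig_id}\t{f.strand}\t"
                f"{f.feature_index}\t{f.cluster_id}\n"
            )


# ---------------------------------------------------------------------------
# Trees

PhyloTree = dendropy.Tree


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a Newick tree with branch lengths; tip labels must be unique."""
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse exception types
        raise ParseError(f"cannot parse Newick file {path}: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ParseError(f"duplicate tip labels in {path}")
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(
        path=str(path),
        schema="newick",
        unquoted_underscores=True,
        suppress_rooting=True,
    )


# ---------------------------------------------------------------------------
# Ontology, annotations, family strings

def read_ontology(
    edges_path: str | Path, terms_path: str | Path | None = None
) -> nx.DiGraph:
    """Read a child->parent (is_a) edge TSV into a directed acyclic graph.

    Optional terms TSV (term, namespace, name) attaches namespaces and
    human-readable names as node attributes. A cyclic edge set raises
    :class:`ParseError`.
    """
    graph = nx.DiGraph()
    for lineno, line in _data_lines(edges_path):
        fields = line.split("\t")
        if fields[0] in {"child", "term"}:  # header
            continue
        if len(fields) < 2:
            raise ParseError(f"{edges_path}:{lineno}: expected child<TAB>parent")
        graph.add_edge(fields[0], fields[1])
    if terms_path is not None:
        for lineno, line in _data_lines(terms_path):
            fields = line.split("\t")
            if fields[0] == "term":
                continue
            if len(fields) < 3:
                raise ParseError(
                    f"{terms_path}:{lineno}: expected term<TAB>namespace<TAB>name"
                )
            term, namespace, name = fields[0], fields[1], fields[2]
            graph.add_node(term, namespace=namespace, name=name)
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise ParseError(f"ontology edge set contains a cycle: {cycle}")
    return graph


def read_annotations(
    path: str | Path, graph: nx.DiGraph | None = None
) -> tuple[dict[str, set[tuple[str, str]]], list[str]]:
    """Read protein -> {(term, namespace)} from a 3-column TSV.

    If ``graph`` is given, annotations to terms absent from the graph are
    kept in the mapping but reported in the returned warning list, so they
    can be excluded from graph queries without being silently dropped.
    """
    annot: dict[str, set[tuple[str, str]]] = {}
    warnings: list[str] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if fields[0] == "protein":
            continue
        if len(fields) != 3:
            raise ParseError(f"{path}:{lineno}: expected protein<TAB>term<TAB>namespace")
        protein, term, namespace = fields
        annot.setdefault(protein, set()).add((term, namespace))
        if graph is not None and term not in graph:
            warnings.append(f"{path}:{lineno}: unknown term {term} (protein {protein})")
    return annot, warnings


def read_family_strings(path: str | Path) -> dict[str, str]:
    """Read protein -> protein-family description string from a 2-column TSV."""
    out: dict[str, str] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if fields[0] == "protein":
            continue
        if len(fields) != 2:
            raise ParseError(f"{path}:{lineno}: expected protein<TAB>family")
        out[fields[0]] = fields[1]
    return out


# ---------------------------------------------------------------------------
# Generic TSV helpers (all pipeline outputs are header + '#' provenance TSV)


def write_tsv(
    rows: Sequence[Mapping[str, object]],
    columns: Sequence[str],
    path: str | Path,
    comment: str | None = None,
) -> None:
    """Write rows as TSV with a header line and optional '#' provenance line."""
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in columns) + "\n")


def read_tsv(path: str | Path) -> list[dict[str, str]]:
    """Read a header + '#'-comment TSV written by :func:`write_tsv`."""
    rows: list[dict[str, str]] = []
    header: list[str] | None = None
    for _lineno, line in _data_lines(path):
        fields = line.split("\t")
        if header is None:
            header = fields
            continue
        rows.append(dict(zip(header, fields)))
    return rows


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
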