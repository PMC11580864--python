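"""Split-homolog detection.

A split homolog is a set of >= 2 neighboring genes — same genome, contig and
strand, at most ``max_feature_gap`` gene ranks apart — whose alignments to a
single human protein jointly, but not individually, cover >= 70% of it: the
microbial counterpart of a eukaryotic gene fusion's parts, typically an
operon encoding the domains of a multidomain human protein as separate
polypeptides.

The branch consumes alignments that already passed the best-human-hit and
microbe-coverage steps, and the contamination ceiling frozen by the
full-length branch. Stages:

S3  place alignments onto every genome encoding the cluster; keep only
    (human, genome) groups with >= 2 distinct clusters;
S4  joint subject coverage of the group >= human_cov;
S5  neighborhood formation (connected components under the gene-rank gap,
    per contig and strand, chaining transitively), joint coverage re-checked
    per component;
S6  drop members above the contamination ceiling, re-form neighborhoods and
    re-check joint coverage once more.

A final predicate enforces "jointly but not individually": the best single
member must cover strictly less than human_cov, otherwise the case belongs
to the full-length branch.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

from .formats_io import AlignmentRecord, GenomeFeature, PipelineThresholds
from .fulllength import ContaminationCutoff, human_coverage

__all__ = [
    "GenomePlacedAlignment",
    "SplitCall",
    "expand_to_genomes",
    "joint_coverage",
    "find_neighborhoods",
    "call_split",
]


@dataclass(frozen=True)
class GenomePlacedAlignment:
    """An alignment attached to one concrete gene occurrence in a genome."""

    base: AlignmentRecord
    feature: GenomeFeature

    def __post_init__(self) -> None:
        if self.feature.cluster_id != self.base.query_id:
            raise ValueError(
                f"feature cluster {self.feature.cluster_id} does not match "
                f"alignment query {self.base.query_id}"
            )


@dataclass(frozen=True)
class SplitCall:
    """An accepted split-homolog neighborhood for one human protein."""

    subject_id: str
    genome_id: str
    contig_id: str
    strand: str
    members: tuple[tuple[str, int], ...]  # (cluster_id, feature_index), sorted by index
    joint_coverage: float
    max_member_coverage: float

    @property
    def cluster_ids(self) -> frozenset[str]:
        return frozenset(c for c, _ in self.members)

    @property
    def min_feature_index(self) -> int:
        return min(i for _, i in self.members)


def expand_to_genomes(
    records: Iterable[AlignmentRecord],
    features: Iterable[GenomeFeature],
) -> tuple[list[GenomePlacedAlignment], list[str]]:
    """S3: attach each alignment to every gene occurrence of its cluster.

    One placed alignment is produced per (record, feature occurrence); a
    cluster occurring twice in one genome yields two placed alignments.
    Genomes encoding < 2 distinct clusters aligning to a given human protein
    are dropped (a lone gene cannot be a split homolog). Clusters with no
    feature at all are reported in the returned warning list.
    """
    by_cluster: dict[str, list[GenomeFeature]] = {}
    for f in features:
        by_cluster.setdefault(f.cluster_id, []).append(f)

    placed: list[GenomePlacedAlignment] = []
    warnings: list[str] = []
    for r in records:
        occurrences = by_cluster.get(r.query_id)
        if not occurrences:
            warnings.append(f"cluster {r.query_id} has no genome feature; dropped")
            continue
        for f in occurrences:
            placed.append(GenomePlacedAlignment(base=r, feature=f))

    # keep only (human, genome) groups with >= 2 distinct clusters
    clusters_per_group: dict[tuple[str, str], set[str]] = {}
    for p in placed:
        key = (p.base.subject_id, p.feature.genome_id)
        clusters_per_group.setdefault(key, set()).add(p.base.query_id)
    placed = [
        p
        for p in placed
        if len(clusters_per_group[(p.base.subject_id, p.feature.genome_id)]) >= 2
    ]
    return placed, warnings


def joint_coverage(
    intervals: Iterable[tuple[int, int]], s_len: int
) -> Fraction:
    """Fraction of subject positions covered by the union of 1-based
    inclusive intervals; exact under overlap and containment."""
    ivs = sorted(intervals)
    covered = 0
    cur_start: int | None = None
    cur_end = 0
    for start, end in ivs:
        if not (1 <= start <= end <= s_len):
            raise ValueError(f"interval [{start},{end}] outside [1,{s_len}]")
        if cur_start is None:
            cur_start, cur_end = start, end
        elif start <= cur_end + 1:
            cur_end = max(cur_end, end)
        else:
            covered += cur_end - cur_start + 1
            cur_start, cur_end = start, end
    if cur_start is not None:
        covered += cur_end - cur_start + 1
    return Fraction(covered, s_len)


def find_neighborhoods(
    placed: Sequence[GenomePlacedAlignment], max_gap: int
) -> list[list[GenomePlacedAlignment]]:
    """S5: group placed alignments (all one human protein and genome) into
    neighborhoods.

    Alignments are restricted to identical (contig, strand); two are linked
    when their gene ranks differ by at most ``max_gap``, and linkage chains
    transitively (connected components). Components containing >= 2 distinct
    clusters are returned, ordered by (contig, strand, smallest rank).
    """
    by_cs: dict[tuple[str, str], list[GenomePlacedAlignment]] = {}
    for p in placed:
        by_cs.setdefault((p.feature.contig_id, p.feature.strand), []).append(p)

    components: list[list[GenomePlacedAlignment]] = []
    for key in sorted(by_cs):
        group = sorted(by_cs[key], key=lambda p: p.feature.feature_index)
        # sorted sweep: on a line, components under |delta rank| <= gap are
        # maximal runs of sorted ranks with consecutive differences <= gap
        current = [group[0]]
        for p in group[1:]:
            if p.feature.feature_index - current[-1].feature.feature_index <= max_gap:
                current.append(p)
            else:
                components.append(current)
                current = [p]
        components.append(current)
    return [
        comp
        for comp in components
        if len({p.base.query_id for p in comp}) >= 2
    ]


def _component_to_call(
    comp: Sequence[GenomePlacedAlignment],
) -> SplitCall:
    members = tuple(
        sorted(
            {(p.base.query_id, p.feature.feature_index) for p in comp},
            key=lambda m: (m[1], m[0]),
        )
    )
    jc = joint_coverage(
        [p.base.subject_interval for p in comp], comp[0].base.s_len
    )
    mc = max(human_coverage(p.base) for p in comp)
    f = comp[0].feature
    return SplitCall(
        subject_id=comp[0].base.subject_id,
        genome_id=f.genome_id,
        contig_id=f.contig_id,
        strand=f.strand,
        members=members,
        joint_coverage=float(jc),
        max_member_coverage=float(mc),
    )


def call_split(
    records: Iterable[AlignmentRecord],
    features: Iterable[GenomeFeature],
    thresholds: PipelineThresholds = PipelineThresholds(),
    cutoff: ContaminationCutoff | None = None,
) -> tuple[list[SplitCall], list[str]]:
    """Run S3 -> S4 -> S5 -> S6 and emit split calls.

    ``records`` must already have passed the shared best-human-hit and
    microbe-coverage steps; ``cutoff`` is the ceiling frozen by the
    full-length branch (None skips the contamination stage, e.g. when no
    full-length candidates existed to estimate it). Joint coverage is
    re-checked after neighborhood formation and again after contamination
    removal, because removing members can drop a set below threshold.
    Output is ordered by (human protein, genome, smallest gene rank).
    """
    placed, warnings = expand_to_genomes(records, features)

    groups: dict[tuple[str, str], list[GenomePlacedAlignment]] = {}
    for p in placed:
        groups.setdefault((p.base.subject_id, p.feature.genome_id), []).append(p)

    calls: list[SplitCall] = []
    for key in sorted(groups):
        group = groups[key]
        s_len = group[0].base.s_len
        # S4: joint coverage over the whole (human, genome) group
        if joint_coverage(
            [p.base.subject_interval for p in group], s_len
        ) < thresholds.human_cov:
            continue
        # S5: neighborhoods, then joint-coverage re-check per component
        for comp in find_neighborhoods(group, thresholds.max_feature_gap):
            if joint_coverage(
                [p.base.subject_interval for p in comp], s_len
            ) < thresholds.human_cov:
                continue
            # S6: contamination removal, then re-form and re-check
            if cutoff is not None:
                survivors = [p for p in comp if cutoff.accepts(p.base.pct_identity)]
            else:
                survivors = list(comp)
            if len(survivors) < len(comp):
                subcomps = find_neighborhoods(survivors, thresholds.max_feature_gap)
            else:
                subcomps = [survivors] if survivors else []
            for sub in subcomps:
                if len({p.base.query_id for p in sub}) < 2:
                    continue
                if joint_coverage(
                    [p.base.subject_interval for p in sub], s_len
                ) < thresholds.human_cov:
                    continue
                call = _component_to_call(sub)
                # jointly but NOT individually: strict, so boundary cases
                # route to the full-length branch
                if call.max_member_coverage >= thresholds.human_cov:
                    continue
                calls.append(call)

    calls.sort(key=lambda c: (c.subject_id, c.genome_id, c.min_feature_index))
    return calls, warnings
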