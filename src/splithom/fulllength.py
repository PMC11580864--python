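"""Full-length homolog calling.

A full-length homolog is a single microbial protein whose best-scoring human
hit covers >= 70% of the human protein, while the alignment also covers
>= 2/3 of the microbial protein (which must itself be >= 80 aa), at a percent
identity below a contamination ceiling. The ceiling is estimated from the
data as mean + k*SD (default k=3) of the identity distribution of the
alignments surviving the coverage filters: near-identical alignments are far
likelier to be human contamination of microbial assemblies than genuine
ancient homology.

Filter order: best human hit per microbial cluster (F1) -> microbe coverage
and minimum length (F2) -> human coverage (F3) -> contamination ceiling
estimated on F3 survivors, then applied (F4). The estimated ceiling is
returned so the split-homolog branch can reuse it frozen.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np

from .formats_io import AlignmentRecord, PipelineThresholds

__all__ = [
    "FullLengthCall",
    "ContaminationCutoff",
    "best_human_hit",
    "microbe_coverage",
    "human_coverage",
    "filter_microbe",
    "filter_human",
    "estimate_contamination_cutoff",
    "call_full_length",
]


@dataclass(frozen=True, order=True)
class FullLengthCall:
    """An accepted full-length homology call (one microbial cluster, one
    human protein)."""

    subject_id: str
    query_id: str
    human_coverage: float
    microbe_coverage: float
    pct_identity: float
    bitscore: float


@dataclass(frozen=True)
class ContaminationCutoff:
    """Percent-identity ceiling: mean + k * sample SD (ddof=1) of the
    identity distribution of full-length-candidate alignments."""

    mean_pct_id: float
    sd_pct_id: float
    k: float
    cutoff: float

    def accepts(self, pct_identity: float) -> bool:
        return pct_identity <= self.cutoff


def microbe_coverage(r: AlignmentRecord) -> Fraction:
    """Fraction of the microbial (query) protein covered by the HSP, as an
    exact rational so threshold comparisons at 2/3 are not subject to
    floating-point rounding."""
    return r.query_coverage


def human_coverage(r: AlignmentRecord) -> Fraction:
    """Fraction of the human (subject) protein covered by the HSP."""
    return r.subject_coverage


def best_human_hit(records: Iterable[AlignmentRecord]) -> list[AlignmentRecord]:
    """F1: keep, per microbial query, only the human subject with the highest
    bitscore.

    Ties are broken by lower e-value, then lexicographically smaller
    subject id, so the result is deterministic regardless of input order.
    Input row order of the surviving queries is preserved.
    """
    best: dict[str, AlignmentRecord] = {}
    order: list[str] = []
    for r in records:
        cur = best.get(r.query_id)
        if cur is None:
            best[r.query_id] = r
            order.append(r.query_id)
        elif (-r.bitscore, r.evalue, r.subject_id) < (
            -cur.bitscore, cur.evalue, cur.subject_id
        ):
            best[r.query_id] = r
    return [best[q] for q in order]


def filter_microbe(
    records: Iterable[AlignmentRecord], thresholds: PipelineThresholds
) -> list[AlignmentRecord]:
    """F2: keep alignments covering >= microbe_cov of the query, with
    q_len >= min_microbe_len. Boundary comparisons are inclusive."""
    return [
        r
        for r in records
        if r.q_len >= thresholds.min_microbe_len
        and microbe_coverage(r) >= thresholds.microbe_cov
    ]


def filter_human(
    records: Iterable[AlignmentRecord], thresholds: PipelineThresholds
) -> list[AlignmentRecord]:
    """F3: keep alignments covering >= human_cov of the human subject."""
    return [r for r in records if human_coverage(r) >= thresholds.human_cov]


def estimate_contamination_cutoff(
    records: Sequence[AlignmentRecord], k: float = 3.0
) -> ContaminationCutoff:
    """Estimate the percent-identity ceiling as mean + k * sample SD.

    The SD uses denominator n-1; fewer than two records raise ValueError
    because the SD is then undefined.
    """
    if len(records) < 2:
        raise ValueError(
            f"need >= 2 records to estimate a contamination cutoff, got {len(records)}"
        )
    ids = np.array([r.pct_identity for r in records], dtype=float)
    mean = float(ids.mean())
    sd = float(ids.std(ddof=1))
    return ContaminationCutoff(mean_pct_id=mean, sd_pct_id=sd, k=k, cutoff=mean + k * sd)


def filter_contamination(
    records: Iterable[AlignmentRecord], cutoff: ContaminationCutoff
) -> list[AlignmentRecord]:
    """F4: drop alignments whose percent identity exceeds the ceiling."""
    return [r for r in records if cutoff.accepts(r.pct_identity)]


def call_full_length(
    records: Iterable[AlignmentRecord],
    features: Sequence["object"] | None = None,
    thresholds: PipelineThresholds = PipelineThresholds(),
    cutoff_before_human_cov: bool = False,
    per_genome_best: bool = False,
) -> tuple[list[FullLengthCall], ContaminationCutoff | None]:
    """Run F1 -> F2 -> F3 -> estimate cutoff -> F4 and emit calls.

    Returns the calls and the estimated :class:`ContaminationCutoff` (reused,
    frozen, by the split-homolog branch). By default the cutoff is estimated
    on the F3 survivors — the distribution of full-length candidates; setting
    ``cutoff_before_human_cov`` estimates it on the F2 survivors instead, for
    sensitivity analyses. With no surviving records the calls are empty and
    the cutoff is None rather than an error.

    Calling is cluster-centric (one call per accepted cluster/human pair).
    With ``per_genome_best=True`` and ``features`` supplied, calls are
    additionally deduplicated to the best-bitscore cluster per
    (human protein, genome) — the "best match per genome" view.
    """
    stage1 = best_human_hit(records)
    stage2 = filter_microbe(stage1, thresholds)
    stage3 = filter_human(stage2, thresholds)
    cutoff_base = stage2 if cutoff_before_human_cov else stage3
    if len(cutoff_base) >= 2:
        cutoff = estimate_contamination_cutoff(cutoff_base, k=thresholds.contamination_sd)
        stage4 = filter_contamination(stage3, cutoff)
    else:
        cutoff = None
        stage4 = stage3
    calls = [
        FullLengthCall(
            subject_id=r.subject_id,
            query_id=r.query_id,
            human_coverage=float(human_coverage(r)),
            microbe_coverage=float(microbe_coverage(r)),
            pct_identity=r.pct_identity,
            bitscore=r.bitscore,
        )
        for r in stage4
    ]
    calls.sort(key=lambda c: (c.subject_id, c.query_id))
    if per_genome_best:
        if features is None:
            raise ValueError("per_genome_best requires the genome feature table")
        genomes_of: dict[str, set[str]] = {}
        for f in features:
            genomes_of.setdefault(f.cluster_id, set()).add(f.genome_id)
        best: dict[tuple[str, str], FullLengthCall] = {}
        for c in calls:
            for g in sorted(genomes_of.get(c.query_id, ())):
                key = (c.subject_id, g)
                cur = best.get(key)
                if cur is None or (-c.bitscore, c.query_id) < (-cur.bitscore, cur.query_id):
                    best[key] = c
        kept = set(best.values())
        calls = [c for c in calls if c in kept]
    return calls, cutoff
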