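import pytest

from splithom.formats_io import AlignmentRecord, GenomeFeature, PipelineThresholds


def mk_record(
    query_id="C1",
    subject_id="H1",
    pct_identity=35.0,
    q_start=1,
    q_end=None,
    s_start=1,
    s_end=None,
    evalue=1e-30,
    bitscore=150.0,
    q_len=100,
    s_len=100,
):
    """AlignmentRecord with sensible defaults: full-span on both sides."""
    if q_end is None:
        q_end = q_len
    if s_end is None:
        s_end = s_len
    return AlignmentRecord(
        query_id=query_id,
        subject_id=subject_id,
        pct_identity=pct_identity,
        aln_len=max(q_end - q_start + 1, s_end - s_start + 1),
        q_start=q_start,
        q_end=q_end,
        s_start=s_start,
        s_end=s_end,
        evalue=evalue,
        bitscore=bitscore,
        q_len=q_len,
        s_len=s_len,
    )


def mk_feature(genome="g1", contig="c1", strand="+", index=1, cluster="C1"):
    return GenomeFeature(genome, contig, strand, index, cluster)


@pytest.fixture
def thresholds():
    return PipelineThresholds()
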