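import shutil

import pytest

from gapspan.io import AlignmentRecord


def make_aln(
    query_id="r1",
    query_len=20_000,
    query_start=0,
    query_end=10_000,
    strand="+",
    target_id="c1",
    target_len=50_000,
    target_start=0,
    target_end=10_000,
    matches=None,
    block_len=None,
    mapq=60,
) -> AlignmentRecord:
    span = max(query_end - query_start, target_end - target_start)
    if block_len is None:
        block_len = span
    if matches is None:
        matches = int(block_len * 0.95)
    return AlignmentRecord(
        query_id, query_len, query_start, query_end, strand,
        target_id, target_len, target_start, target_end,
        matches, block_len, mapq,
    )


@pytest.fixture
def aln_factory():
    return make_aln


have_minimap2 = shutil.which("minimap2") is not None

requires_minimap2 = pytest.mark.skipif(
    not have_minimap2, reason="minimap2 not on PATH"
)
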