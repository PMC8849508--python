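import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gapspan.align import (
    BundledEdge,
    ProperAlignment,
    Rejection,
    bundle_links,
    classify_proper,
    default_min_support,
    extract_links,
    filter_proper,
    select_best,
)
from tests._oracles import brute_select_best
from tests.conftest import make_aln


class TestSelectBest:
    def test_dominance_same_target(self):
        a = make_aln(query_start=0, query_end=6000, matches=5800)
        b = make_aln(query_start=100, query_end=6100, matches=4000)
        assert select_best([a, b]) == [a]

    def test_disjoint_intervals_both_kept(self):
        a = make_aln(query_start=0, query_end=6000, target_id="c1")
        b = make_aln(query_start=7000, query_end=13000, target_id="c2")
        assert select_best([a, b]) == [a, b]

    def test_cross_target_dominance(self):
        a = make_aln(query_start=0, query_end=6000, target_id="c1", matches=5900)
        b = make_aln(query_start=1000, query_end=7000, target_id="c2", matches=4000)
        assert select_best([a, b]) == [a]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force(self, seed):
        rng = random.Random(seed)
        alns = []
        for _ in range(rng.randint(1, 40)):
            qs = rng.randrange(0, 15_000)
            span = rng.randrange(1000, 8000)
            alns.append(
                make_aln(
                    query_id=f"r{rng.randrange(3)}",
                    query_len=40_000,
                    query_start=qs,
                    query_end=qs + span,
                    target_id=f"c{rng.randrange(4)}",
                    target_len=60_000,
                    target_start=0,
                    target_end=span,
                    matches=rng.randrange(100, span + 100),
                    block_len=span + 200,
                )
            )
        assert select_best(alns) == brute_select_best(alns)


class TestClassifyProper:
    def test_overhang_within_bound_accepted(self):
        # alignment stops 500 bp before the contig end; read continues
        aln = make_aln(
            query_len=20_000, query_start=0, query_end=6000,
            target_len=50_000, target_start=43_500, target_end=49_500,
            block_len=6000,
        )
        res = classify_proper(aln)
        assert isinstance(res, ProperAlignment)
        assert res.overhang_bp == 500
        assert res.contig_end_touched == "end"

    def test_too_short_rejected(self):
        aln = make_aln(query_end=4999, target_end=4999, block_len=4999)
        res = classify_proper(aln)
        assert isinstance(res, Rejection) and res.reason == "too_short"

    def test_block_exactly_5000_accepted_inclusive(self):
        aln = make_aln(
            query_len=20_000, query_start=0, query_end=5000,
            target_len=50_000, target_start=45_000, target_end=50_000,
            block_len=5000,
        )
        assert isinstance(classify_proper(aln), ProperAlignment)

    def test_overhang_exceeded_rejected(self):
        aln = make_aln(
            query_len=20_000, query_start=0, query_end=8000,
            target_len=50_000, target_start=40_500, target_end=48_500,
            block_len=8000,
        )
        res = classify_proper(aln)
        assert isinstance(res, Rejection) and res.reason == "overhang_exceeded"

    def test_internal_rejected(self):
        # read entirely inside the contig: terminates before either end
        aln = make_aln(
            query_len=8000, query_start=100, query_end=7900,
            target_len=100_000, target_start=40_000, target_end=47_800,
            block_len=7800,
        )
        res = classify_proper(aln)
        assert isinstance(res, Rejection) and res.reason == "internal"

    def test_read_terminates_before_end_no_overhang(self):
        # 500 bp of unaligned read vs 2000 bp of unaligned contig: the
        # read never reaches the contig end, so no overhang constraint
        aln = make_aln(
            query_len=6500, query_start=0, query_end=6000,
            target_len=50_000, target_start=0, target_end=6000,
            block_len=6000,
        )
        res = classify_proper(aln)
        assert isinstance(res, ProperAlignment)
        assert res.contig_end_touched == "begin"
        assert res.overhang_bp == 0

    @pytest.mark.parametrize("strand", "+-")
    def test_geometry_enumeration(self, strand):
        """Compare against a directly-stated geometric predicate over a
        grid of read placements around a contig."""
        contig_len, read_len, block = 30_000, 12_000, 6000
        for t_start in range(0, contig_len - block + 1, 1500):
            for q_start in range(0, read_len - block + 1, 1500):
                aln = make_aln(
                    query_len=read_len, query_start=q_start, query_end=q_start + block,
                    target_len=contig_len, target_start=t_start,
                    target_end=t_start + block, block_len=block, strand=strand,
                )
                if strand == "+":
                    ext_b, ext_e = q_start, read_len - (q_start + block)
                else:
                    ext_b, ext_e = read_len - (q_start + block), q_start
                dist_b, dist_e = t_start, contig_len - (t_start + block)
                touch_b, touch_e = ext_b >= dist_b, ext_e >= dist_e
                expect_proper = (touch_b or touch_e) and all(
                    d <= 1000 for t, d in [(touch_b, dist_b), (touch_e, dist_e)] if t
                )
                res = classify_proper(aln)
                assert isinstance(res, ProperAlignment) == expect_proper, (
                    t_start, q_start, strand,
                )


class TestExtractLinks:
    def _spanning_pair(self):
        # read crosses from c1's end into c2's begin with a 700 bp gap
        a1 = make_aln(
            query_id="r1", query_len=13_000, query_start=0, query_end=6000,
            target_id="c1", target_len=40_000, target_start=34_000, target_end=40_000,
            block_len=6000,
        )
        a2 = make_aln(
            query_id="r1", query_len=13_000, query_start=6700, query_end=12_700,
            target_id="c2", target_len=40_000, target_start=0, target_end=6000,
            block_len=6000,
        )
        return a1, a2

    def test_simple_forward_link(self):
        proper, rej = filter_proper(self._spanning_pair())
        assert not rej
        (link,) = extract_links(proper)
        assert link.key == ("c1", "end", "c2", "begin")
        assert link.relative_orientation == "forward"
        assert link.gap_estimate == 700

    def test_single_contig_no_links(self):
        a1, _ = self._spanning_pair()
        proper, _ = filter_proper([a1])
        assert extract_links(proper) == []

    def test_three_contigs_two_links(self):
        alns = []
        for i, cid in enumerate(["c1", "c2", "c3"]):
            alns.append(
                make_aln(
                    query_id="r1", query_len=20_000,
                    query_start=i * 6500, query_end=i * 6500 + 6000,
                    target_id=cid, target_len=30_000,
                    target_start=24_000 if i == 0 else 0,
                    target_end=30_000 if i == 0 else 6000,
                    block_len=6000,
                )
            )
        # middle contig: read enters at begin and leaves at end
        alns[1] = make_aln(
            query_id="r1", query_len=20_000, query_start=6500, query_end=12_500,
            target_id="c2", target_len=6000, target_start=0, target_end=6000,
            block_len=6000,
        )
        proper, _ = filter_proper(alns)
        links = extract_links(proper)
        assert [l.key for l in links] == [
            ("c1", "end", "c2", "begin"),
            ("c2", "end", "c3", "begin"),
        ]

    def test_reverse_traversal_canonicalized(self):
        # same junction read from the other direction: strands flipped,
        # order reversed -> identical canonical key, flipped interval
        a1 = make_aln(
            query_id="r2", query_len=13_000, query_start=0, query_end=6000,
            strand="-",
            target_id="c2", target_len=40_000, target_start=0, target_end=6000,
            block_len=6000,
        )
        a2 = make_aln(
            query_id="r2", query_len=13_000, query_start=6700, query_end=12_700,
            strand="-",
            target_id="c1", target_len=40_000, target_start=34_000, target_end=40_000,
            block_len=6000,
        )
        proper, _ = filter_proper([a1, a2])
        (link,) = extract_links(proper)
        assert link.key == ("c1", "end", "c2", "begin")
        assert link.flipped


class TestBundleLinks:
    def _link(self, join_id="r1", gap=500):
        a1 = make_aln(
            query_id=join_id, query_len=13_000, query_start=0, query_end=6000,
            target_id="c1", target_len=40_000, target_start=34_000, target_end=40_000,
            block_len=6000,
        )
        a2 = make_aln(
            query_id=join_id, query_len=13_000,
            query_start=6000 + gap, query_end=12_000 + gap,
            target_id="c2", target_len=40_000, target_start=0, target_end=6000,
            block_len=6000,
        )
        proper, _ = filter_proper([a1, a2])
        (link,) = extract_links(proper)
        return link

    def test_concordant_bundle(self):
        links = [self._link(f"r{i}") for i in range(3)]
        (bundle,) = bundle_links(links, min_support=2)
        assert bundle.support == 3
        assert bundle.key == ("c1", "end", "c2", "begin")

    def test_single_link_dropped_below_min_support(self):
        assert bundle_links([self._link()], min_support=2) == []

    def test_gap_median(self):
        links = [self._link(f"r{i}", gap) for i, gap in enumerate([400, 500, 900])]
        (bundle,) = bundle_links(links, min_support=2)
        assert bundle.gap_estimate == 500

    def test_default_min_support_per_mode(self):
        assert default_min_support("ont") == 2
        assert default_min_support("pbclr") == 2
        assert default_min_support("asm") == 1


aln_strategy = st.builds(
    lambda qlen_extra, qs, span, ts, t_extra, strand, m_frac: make_aln(
        query_len=qs + span + qlen_extra,
        query_start=qs,
        query_end=qs + span,
        strand=strand,
        target_len=ts + span + t_extra,
        target_start=ts,
        target_end=ts + span,
        matches=int(span * m_frac),
        block_len=span,
    ),
    qlen_extra=st.integers(0, 8000),
    qs=st.integers(0, 8000),
    span=st.integers(1000, 12_000),
    ts=st.integers(0, 3000),
    t_extra=st.integers(0, 3000),
    strand=st.sampled_from("+-"),
    m_frac=st.floats(0.5, 1.0),
)


@given(st.lists(aln_strategy, max_size=30))
@settings(max_examples=100, deadline=None)
def test_proper_invariants(alns):
    """Every accepted alignment satisfies both thresholds."""
    accepted, rejected = filter_proper(alns, min_aln_len=5000, max_overhang=1000)
    for p in accepted:
        assert p.aln.block_len >= 5000
        assert 0 <= p.overhang_bp <= 1000
    assert len(accepted) + len(rejected) == len(alns)


@given(st.lists(aln_strategy, max_size=30))
@settings(max_examples=50, deadline=None)
def test_links_require_two_proper_alignments(alns):
    accepted, _ = filter_proper(alns)
    links = extract_links(accepted)
    per_join = {}
    for p in accepted:
        per_join.setdefault(p.aln.query_id, []).append(p)
    for link in links:
        assert len(per_join[link.join_id]) >= 2
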