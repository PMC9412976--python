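import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dinoarch.architecture import (
    block_occupancy,
    find_blocks,
    find_disruptors,
    interblock_regions,
    order_genes,
    orientation_histogram,
    region_counts,
)
from dinoarch.model import AnnotationSet, GeneRecord

from conftest import annotation_from_strands

strand_lists = st.lists(st.sampled_from("+-"), min_size=0, max_size=60)


def brute_force_window_changes(strands, w):
    """Independent oracle: count adjacent mismatches in each w-window."""
    out = []
    for i in range(len(strands) - w + 1):
        win = strands[i : i + w]
        out.append(sum(win[j] != win[j + 1] for j in range(w - 1)))
    return out


def test_order_genes_sort_key_start_end_id():
    genes = [
        GeneRecord("a", "s", 10, 20, "+"),
        GeneRecord("b", "s", 5, 9, "+"),
        GeneRecord("c", "s", 5, 7, "+"),
    ]
    ann = AnnotationSet(scaffolds=["s"], genes=genes)
    ordered = order_genes(ann)["s"]
    assert [(g.start, g.end) for g in ordered] == [(5, 7), (5, 9), (10, 20)]


def test_order_genes_shuffle_invariant():
    rng = random.Random(0)
    genes = [
        GeneRecord(f"g{i}", "s", i * 100, i * 100 + 50, "+") for i in range(50)
    ]
    ann1 = AnnotationSet(scaffolds=["s"], genes=list(genes))
    shuffled = list(genes)
    rng.shuffle(shuffled)
    ann2 = AnnotationSet(scaffolds=["s"], genes=shuffled)
    assert order_genes(ann1) == order_genes(ann2)


def test_histogram_hand_derived_window():
    # one 10-gene window: + + + - - + + + + +  -> 2 strand changes
    ann = annotation_from_strands(list("+++--+++++"))
    hist = orientation_histogram(order_genes(ann), w=10)
    assert hist.counts == {2: 1}


def test_histogram_uniform_strand():
    ann = annotation_from_strands(["+"] * 15)
    hist = orientation_histogram(order_genes(ann), w=10)
    assert hist.counts == {0: 6}
    assert hist.conserved_fraction == 1.0


def test_histogram_short_scaffold_contributes_nothing():
    ann = annotation_from_strands(list("+-+"))
    hist = orientation_histogram(order_genes(ann), w=10)
    assert hist.total_windows == 0
    with pytest.raises(ValueError):
        hist.conserved_fraction


@settings(deadline=None, max_examples=100, derandomize=True)
@given(strands=strand_lists, w=st.integers(2, 12))
def test_histogram_matches_brute_force(strands, w):
    ann = annotation_from_strands(strands) if strands else None
    if ann is None:
        return
    hist = orientation_histogram(order_genes(ann), w=w)
    oracle = brute_force_window_changes(strands, w) if len(strands) >= w else []
    assert hist.total_windows == len(oracle)
    for c, n in hist.counts.items():
        assert oracle.count(c) == n


def test_find_blocks_run_length_examples():
    ann = annotation_from_strands(list("++---+"))
    blocks = find_blocks(order_genes(ann))
    assert [(b.size, b.strand) for b in blocks] == [(2, "+"), (3, "-"), (1, "+")]

    alt = annotation_from_strands(list("+-+-"))
    assert [b.size for b in find_blocks(order_genes(alt))] == [1, 1, 1, 1]

    uni = annotation_from_strands(["-"] * 7)
    assert [(b.size, b.strand) for b in find_blocks(order_genes(uni))] == [(7, "-")]


@settings(deadline=None, max_examples=100, derandomize=True)
@given(strands=strand_lists)
def test_blocks_partition_and_window_closed_form(strands):
    """counts[0] == sum over blocks of max(0, size - w + 1)."""
    if not strands:
        return
    ann = annotation_from_strands(strands)
    ordered = order_genes(ann)
    blocks = find_blocks(ordered)
    assert sum(b.size for b in blocks) == len(strands)
    w = 10
    hist = orientation_histogram(ordered, w=w)
    assert hist.counts.get(0, 0) == sum(max(0, b.size - w + 1) for b in blocks)


def test_occupancy_direct_counts():
    ann = annotation_from_strands(list("++---+"))
    occ = block_occupancy(find_blocks(order_genes(ann)))
    assert occ[3] == pytest.approx(50.0)  # 3 of 6 genes in blocks >= 3
    assert occ[1] == pytest.approx(100.0)
    assert 10 not in occ  # largest block is 3

    one = annotation_from_strands(["+"] * 12)
    occ1 = block_occupancy(find_blocks(order_genes(one)))
    assert all(occ1[s] == pytest.approx(100.0) for s in range(1, 13))


def test_interblock_regions_qualification_and_class():
    # sizes/strands (2,+),(3,-),(1,+): at N=2 one converging pair qualifies
    ann = annotation_from_strands(list("++---+"))
    ordered = order_genes(ann)
    regions = interblock_regions(find_blocks(ordered), ordered, n_values=(2,))
    assert len(regions) == 2
    counts = region_counts(regions, n_values=(2,))
    assert counts[(2, "converging")] == 1
    assert counts[(2, "diverging")] == 0

    # (4,-),(4,+) at N=4 -> 1 diverging
    ann2 = annotation_from_strands(list("----++++"))
    ordered2 = order_genes(ann2)
    regions2 = interblock_regions(find_blocks(ordered2), ordered2, n_values=(4,))
    assert len(regions2) == 1
    assert regions2[0].orientation_class == "diverging"
    assert regions2[0].qualifies(4)


def test_interblock_interval_spans_flanking_genes():
    ann = annotation_from_strands(list("+-"), gene_len=100, gap=50)
    ordered = order_genes(ann)
    regions = interblock_regions(find_blocks(ordered), ordered)
    (r,) = regions
    assert (r.start, r.end) == (100, 150)
    assert r.length == 50


@settings(deadline=None, max_examples=100, derandomize=True)
@given(strands=strand_lists)
def test_region_invariants(strands):
    """One region per adjacent pair; qualifying counts non-increasing in N."""
    if len(strands) < 2:
        return
    ann = annotation_from_strands(strands)
    ordered = order_genes(ann)
    blocks = find_blocks(ordered)
    n_values = (1, 2, 4, 6, 8, 10)
    regions = interblock_regions(blocks, ordered, n_values=n_values)
    assert len(regions) == len(blocks) - 1
    counts = region_counts(regions, n_values=n_values)
    totals = [counts[(n, "converging")] + counts[(n, "diverging")] for n in n_values]
    assert totals == sorted(totals, reverse=True)
    for n in n_values:
        expected = sum(
            1
            for left, right in zip(blocks, blocks[1:])
            if left.size >= n and right.size >= n
        )
        assert totals[n_values.index(n)] == expected


def test_disruptor_definition_examples():
    called = find_disruptors(order_genes(annotation_from_strands(list("+-+"))))
    assert [c.gene_id for c in called] == ["s1.g1"]
    assert called[0].flanking_strand == "+"

    assert find_disruptors(order_genes(annotation_from_strands(list("+--")))) == []
    # terminal genes never called
    assert find_disruptors(order_genes(annotation_from_strands(list("-+")))) == []


@settings(deadline=None, max_examples=100, derandomize=True)
@given(strands=strand_lists)
def test_disruptors_are_unit_blocks_with_same_strand_flanks(strands):
    ann = annotation_from_strands(strands)
    ordered = order_genes(ann)
    calls = {c.gene_id for c in find_disruptors(ordered)}
    blocks = find_blocks(ordered)
    expected = set()
    for prev, mid, nxt in zip(blocks, blocks[1:], blocks[2:]):
        if mid.size == 1 and prev.strand == nxt.strand:
            expected.add(ordered[mid.scaffold][mid.first_index].gene_id)
    assert calls == expected
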