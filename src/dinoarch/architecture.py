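"""Gene-orientation architecture: windows, blocks, inter-block regions.

Unidirectional gene blocks are maximal runs of consecutive same-strand
genes along a scaffold's gene order. The interval between two adjacent
blocks is *converging* when transcription points inward (left block '+',
right block '-') — a putative TAD boundary — and *diverging* when it
points outward — a putative TAD central region. Orientation-disrupting
genes are single genes breaking an otherwise unidirectional run.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Sequence

from dinoarch.model import (
    AnnotationSet,
    DisruptorCall,
    GeneRecord,
    InterBlockRegion,
    OrientationHistogram,
    UnidirectionalBlock,
)

logger = logging.getLogger("dinoarch")

DEFAULT_N_VALUES: tuple[int, ...] = (4, 6, 8, 10)


def order_genes(annotation: AnnotationSet) -> dict[str, list[GeneRecord]]:
    """Per-scaffold gene lists sorted by start, ties by end then id.

    This order is the sole positional basis for all downstream analyses;
    overlapping genes simply retain the sort order.
    """
    ordered: dict[str, list[GeneRecord]] = {s: [] for s in annotation.scaffolds}
    for gene in annotation.genes:
        ordered[gene.scaffold].append(gene)
    for genes in ordered.values():
        genes.sort(key=lambda g: (g.start, g.end, g.gene_id))
    return ordered


def orientation_histogram(
    ordered: dict[str, list[GeneRecord]], w: int = 10
) -> OrientationHistogram:
    """Count strand changes in every sliding w-gene window.

    Windows advance one gene at a time within each scaffold; scaffolds
    with fewer than ``w`` genes contribute none. A window's change count
    is the number of adjacent gene pairs with differing strand, so the
    ``0`` bin collects windows of fully conserved orientation.
    """
    if w < 2:
        raise ValueError("window size must be >= 2")
    counts: Counter[int] = Counter()
    for genes in ordered.values():
        n = len(genes)
        if n < w:
            continue
        strands = [g.strand for g in genes]
        # changes[i] == 1 iff strands[i] != strands[i+1]; window sum via prefix
        changes = [int(strands[i] != strands[i + 1]) for i in range(n - 1)]
        window_sum = sum(changes[: w - 1])
        counts[window_sum] += 1
        for i in range(1, n - w + 1):
            window_sum += changes[i + w - 2] - changes[i - 1]
            counts[window_sum] += 1
    if not counts:
        logger.warning("no scaffold reaches %d genes; empty orientation histogram", w)
    return OrientationHistogram(window_size=w, counts=dict(counts))


def find_blocks(ordered: dict[str, list[GeneRecord]]) -> list[UnidirectionalBlock]:
    """Maximal same-strand runs; block sizes partition each scaffold's genes."""
    blocks: list[UnidirectionalBlock] = []
    for scaffold, genes in ordered.items():
        if not genes:
            continue
        run_start = 0
        for i in range(1, len(genes) + 1):
            if i == len(genes) or genes[i].strand != genes[run_start].strand:
                blocks.append(
                    UnidirectionalBlock(
                        scaffold=scaffold,
                        strand=genes[run_start].strand,
                        first_index=run_start,
                        last_index=i - 1,
                    )
                )
                run_start = i
    return blocks


def block_occupancy(blocks: Sequence[UnidirectionalBlock]) -> dict[int, float]:
    """Cumulative percentage of genes found in blocks of size >= s.

    Keys run from 1 to the largest block size; the value at s=1 is 100
    and the curve is non-increasing.
    """
    if not blocks:
        raise ValueError("no blocks")
    sizes = [b.size for b in blocks]
    total_genes = sum(sizes)
    max_size = max(sizes)
    genes_at = Counter()
    for s in sizes:
        genes_at[s] += s
    out: dict[int, float] = {}
    cumulative = 0
    for s in range(max_size, 0, -1):
        cumulative += genes_at.get(s, 0)
        out[s] = 100.0 * cumulative / total_genes
    return dict(sorted(out.items()))


def interblock_regions(
    blocks: Sequence[UnidirectionalBlock],
    ordered: dict[str, list[GeneRecord]],
    n_values: Sequence[int] = DEFAULT_N_VALUES,
) -> list[InterBlockRegion]:
    """One region per adjacent block pair on each scaffold.

    The bp interval runs from the end of the left block's last gene to
    the start of the right block's first gene (length clamped at 0 for
    abutting/overlapping flanks). A region qualifies at minimum block
    size N when both flanking blocks hold >= N genes.
    """
    by_scaffold: dict[str, list[UnidirectionalBlock]] = {}
    for b in blocks:
        by_scaffold.setdefault(b.scaffold, []).append(b)
    regions: list[InterBlockRegion] = []
    for scaffold, sblocks in by_scaffold.items():
        sblocks.sort(key=lambda b: b.first_index)
        genes = ordered[scaffold]
        for left, right in zip(sblocks, sblocks[1:]):
            start = genes[left.last_index].end
            end = genes[right.first_index].start
            if end < start:
                start = end  # overlapping flanks: zero-length placeholder
            qualified = tuple(n for n in n_values if left.size >= n and right.size >= n)
            regions.append(
                InterBlockRegion(
                    scaffold=scaffold,
                    left_block=left,
                    right_block=right,
                    start=start,
                    end=end,
                    orientation_class="converging" if left.strand == "+" else "diverging",
                    min_block_size_qualified=qualified,
                )
            )
    return regions


def region_counts(
    regions: Sequence[InterBlockRegion], n_values: Sequence[int] = DEFAULT_N_VALUES
) -> dict[tuple[int, str], int]:
    """Qualifying-region counts per (N, orientation class)."""
    counts = {(n, cls): 0 for n in n_values for cls in ("converging", "diverging")}
    for r in regions:
        for n in n_values:
            if r.qualifies(n):
                counts[(n, r.orientation_class)] += 1
    return counts


def find_disruptors(ordered: dict[str, list[GeneRecord]]) -> list[DisruptorCall]:
    """Genes whose strand differs from both neighbours, which agree.

    First and last genes of a scaffold are never called. Equivalently,
    these are the size-1 blocks flanked by two blocks of one strand.
    """
    calls: list[DisruptorCall] = []
    for scaffold, genes in ordered.items():
        for i in range(1, len(genes) - 1):
            left, mid, right = genes[i - 1], genes[i], genes[i + 1]
            if left.strand == right.strand != mid.strand:
                calls.append(
                    DisruptorCall(
                        gene_id=mid.gene_id,
                        scaffold=scaffold,
                        flanking_strand=left.strand,
                    )
                )
    return calls
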