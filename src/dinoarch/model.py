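"""Domain types shared across the pipeline.

Coordinate convention: every in-memory interval is 0-based half-open.
GFF3 (1-based inclusive) is converted on read; BED output needs no
conversion. ``GeneRecord.gff_start``/``gff_end`` recover the original
1-based inclusive coordinates where they are needed for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

Strand = str  # '+' or '-'


@dataclass(frozen=True)
class GeneRecord:
    """A stranded gene on a scaffold (0-based half-open coordinates)."""

    gene_id: str
    scaffold: str
    start: int
    end: int
    strand: Strand

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: invalid strand {self.strand!r}")

    @property
    def gff_start(self) -> int:
        return self.start + 1

    @property
    def gff_end(self) -> int:
        return self.end


@dataclass
class AnnotationSet:
    """Gene models read from one GFF3 file."""

    scaffolds: list[str]
    genes: list[GeneRecord]
    source_path: str = ""
    n_rejected_strandless: int = 0

    def __post_init__(self) -> None:
        known = set(self.scaffolds)
        for g in self.genes:
            if g.scaffold not in known:
                raise ValueError(f"gene {g.gene_id} on unknown scaffold {g.scaffold}")
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate gene ids in annotation")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class UnidirectionalBlock:
    """A maximal run of consecutive same-strand genes on one scaffold.

    ``first_index``/``last_index`` index into the ordered gene list of the
    scaffold (inclusive); ``size`` is the gene count.
    """

    scaffold: str
    strand: Strand
    first_index: int
    last_index: int

    @property
    def size(self) -> int:
        return self.last_index - self.first_index + 1


@dataclass(frozen=True)
class InterBlockRegion:
    """The interval between two adjacent unidirectional blocks.

    ``converging`` (left '+', right '-') marks a putative TAD boundary;
    ``diverging`` (left '-', right '+') a putative TAD central region.
    The bp interval runs from the end of the left block's last gene to the
    start of the right block's first gene (clamped to length >= 0 when the
    flanking genes abut or overlap).
    """

    scaffold: str
    left_block: UnidirectionalBlock
    right_block: UnidirectionalBlock
    start: int
    end: int
    orientation_class: str  # 'converging' | 'diverging'
    min_block_size_qualified: tuple[int, ...]

    @property
    def length(self) -> int:
        return self.end - self.start

    def qualifies(self, n: int) -> bool:
        return n in self.min_block_size_qualified


@dataclass(frozen=True)
class DisruptorCall:
    """A gene whose strand differs from both same-strand neighbours."""

    gene_id: str
    scaffold: str
    flanking_strand: Strand


@dataclass
class OrientationHistogram:
    """Counts of strand changes in sliding w-gene windows."""

    window_size: int
    counts: dict[int, int]

    @property
    def total_windows(self) -> int:
        return sum(self.counts.values())

    @property
    def conserved_fraction(self) -> float:
        total = self.total_windows
        if total == 0:
            raise ValueError("no windows: no scaffold reaches the window size")
        return self.counts.get(0, 0) / total


@dataclass(frozen=True)
class GCWindow:
    """GC fraction of one sliding window (0-based half-open)."""

    scaffold: str
    start: int
    width: int
    gc: float

    @property
    def end(self) -> int:
        return self.start + self.width


@dataclass(frozen=True)
class GCDipRegion:
    """A maximal run of below-background windows passing the dip criteria.

    ``max_deviation`` is (background - minimum window GC) in percentage
    points over the run. ``[start, end)`` is the interval whose every
    position is covered only by below-background windows (the run's span
    eroded by one window width per side).
    """

    scaffold: str
    start: int
    end: int
    max_deviation: float
    background_gc: float

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GeneTree:
    """A support-annotated, effectively unrooted gene tree.

    ``leaves`` are taxon labels (optionally ``taxon|sequence_id``);
    ``supports`` holds internal-node bootstrap percentages in [0, 100].
    """

    tree_id: str
    tree: object  # dendropy.Tree
    leaves: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.leaves)


@dataclass
class TreeSet:
    trees: list[GeneTree]
    support_scale: str = "percent"  # scale detected in the source files

    def __len__(self) -> int:
        return len(self.trees)


@dataclass(frozen=True)
class SupportedClade:
    """One side of an internal edge whose support meets the threshold."""

    leaves: frozenset[str]
    support: float

    def __len__(self) -> int:
        return len(self.leaves)


@dataclass(frozen=True)
class SortingRule:
    """One step of the staged tree-sorting strategy.

    A rule matches a supported clade that (i) is exclusive to
    ``subject_groups`` plus all groups named in ``target_slots``, (ii)
    contains at least one Dinophyceae leaf and at least
    ``min_prop_subject`` of the tree's subject-group leaves, and (iii)
    contains, for every slot, at least one non-subject leaf belonging to
    that slot's groups. Multi-group categories (e.g. red+green algae)
    therefore require every constituent partner to be present.
    """

    ordinal: int
    stage: str  # 'a' (plastid/Archaeplastida), 'b' (vertical), 'c' (remote)
    subject_groups: frozenset[str]
    target_slots: tuple[frozenset[str], ...]
    category: str

    @property
    def target_groups(self) -> frozenset[str]:
        out: set[str] = set()
        for slot in self.target_slots:
            out |= slot
        return frozenset(out)


@dataclass(frozen=True)
class SortOutcome:
    """Category assigned to one tree at one bootstrap threshold."""

    tree_id: str
    threshold: float
    category: str  # 'A'..'O' or 'unclassified'
    evidence: Optional[SupportedClade] = None
    rule_ordinal: Optional[int] = None

    def __post_init__(self) -> None:
        if (self.category == "unclassified") != (self.evidence is None):
            raise ValueError("evidence present iff classified")


@dataclass
class HomologSet:
    """An orthogroup: (taxon, sequence id) members across taxa."""

    set_id: str
    members: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"homolog set {self.set_id} is empty")

    @property
    def taxa(self) -> set[str]:
        return {t for t, _ in self.members}

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class SpecificityClass:
    """Lineage-specificity assignment of one query protein."""

    kind: str  # species_specific | clade_specific | exclusive_two_phylum | multi_phylum
    level: Optional[str] = None  # clade level or partner phylum
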