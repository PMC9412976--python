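"""Synthetic inputs with planted, machine-readable truth.

Every generator is a pure function of its spec and a single integer
seed. Each generator derives its own named random stream from the seed,
so adding one generator never perturbs another's output.

The generated data emulate the statistical structure of a Symbiodiniaceae
genome as seen by this pipeline: scaffolds carrying genes in same-strand
runs (geometric block-size distribution tuned to the ~33% occupancy of
blocks of ten or more genes observed in real assemblies) interrupted by
orientation-disrupting genes; genome sequence at ~44.4% background GC
with GC-dip segments planted at converging inter-block regions; gene
trees with one strongly supported planted clade per origin category; and
orthogroup tables realizing an explicit composition plan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from dinoarch.architecture import find_blocks, interblock_regions, order_genes
from dinoarch.model import AnnotationSet, GeneRecord, GeneTree
from dinoarch.taxonomy import TaxonGroupMap

_STREAMS = {"annotation": 1, "sequence": 2, "trees": 3, "orthogroups": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[stream], seed])


def default_taxon_map() -> TaxonGroupMap:
    """A broadly sampled synthetic taxon set mirroring the real database:
    dinoflagellates (Suessiales and others), other alveolates, the rest
    of SAR, haptophytes, cryptophytes, the three Archaeplastida phyla,
    opisthokonts, other eukaryotes, bacteria and archaea."""
    taxa = {
        "Cladocopium_goreaui": "Suessiales",
        "Breviolum_minutum": "Suessiales",
        "Symbiodinium_microadriaticum": "Suessiales",
        "Fugacium_kawagutii": "Suessiales",
        "Polarella_glacialis": "Suessiales",
        "Alexandrium_tamarense": "Dinophyceae",
        "Prorocentrum_minimum": "Dinophyceae",
        "Perkinsus_marinus": "Perkinsea",
        "Vitrella_brassicaformis": "Chromerida",
        "Tetrahymena_thermophila": "Ciliophora",
        "Plasmodium_falciparum": "Apicomplexa",
        "Thalassiosira_pseudonana": "Stramenopiles",
        "Phaeodactylum_tricornutum": "Stramenopiles",
        "Bigelowiella_natans": "Rhizaria",
        "Emiliania_huxleyi": "Haptophyta",
        "Chrysochromulina_tobinii": "Haptophyta",
        "Guillardia_theta": "Cryptophyta",
        "Porphyridium_purpureum": "Rhodophyta",
        "Chondrus_crispus": "Rhodophyta",
        "Chlamydomonas_reinhardtii": "Viridiplantae",
        "Volvox_carteri": "Viridiplantae",
        "Cyanophora_paradoxa": "Glaucophyta",
        "Homo_sapiens": "Metazoa",
        "Drosophila_melanogaster": "Metazoa",
        "Saccharomyces_cerevisiae": "Fungi",
        "Dictyostelium_discoideum": "Amoebozoa",
        "Naegleria_gruberi": "Excavata",
        "Escherichia_coli": "Bacteria",
        "Bacillus_subtilis": "Bacteria",
        "Sulfolobus_solfataricus": "Archaea",
        "Methanococcus_jannaschii": "Archaea",
    }
    return TaxonGroupMap(taxon_to_group=taxa)


def taxon_map_to_tsv(taxon_map: TaxonGroupMap) -> str:
    lines = ["taxon\tgroup"]
    lines += [f"{t}\t{g}" for t, g in taxon_map.taxon_to_group.items()]
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# annotation


@dataclass
class ArchitectureSpec:
    """Layout of a synthetic stranded annotation.

    ``block_sizes`` (explicit run lengths, cycled) overrides the
    geometric draw. Strand runs alternate; each interior gene is then
    independently flipped with ``disruptor_rate``. Gene lengths and
    intergenic gaps are drawn uniformly from the given bp ranges.
    """

    n_scaffolds: int = 5
    genes_per_scaffold: int = 200
    block_size_geometric_p: float = 0.22
    block_sizes: Sequence[int] | None = None
    disruptor_rate: float = 0.05
    gene_length_bp: tuple[int, int] = (1000, 3000)
    intergenic_bp: tuple[int, int] = (200, 2000)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.disruptor_rate <= 1:
            raise ValueError("disruptor_rate must be in [0, 1]")
        if self.n_scaffolds < 1 or self.genes_per_scaffold < 1:
            raise ValueError("counts must be >= 1")
        if self.block_sizes is None and not 0 < self.block_size_geometric_p <= 1:
            raise ValueError("geometric p must be in (0, 1]")


def _run_length_encode(strands: Sequence[str]) -> list[tuple[str, int]]:
    runs: list[tuple[str, int]] = []
    for s in strands:
        if runs and runs[-1][0] == s:
            runs[-1] = (s, runs[-1][1] + 1)
        else:
            runs.append((s, 1))
    return runs


def gen_annotation(spec: ArchitectureSpec) -> tuple[AnnotationSet, dict]:
    """Generate a stranded annotation plus its truth table.

    Truth records, per scaffold, the pre-flip run sizes, the flipped
    (disruptor) gene indices, and the post-flip block sizes and strands
    the analyzer is expected to recover.
    """
    rng = _rng(spec.seed, "annotation")
    genes: list[GeneRecord] = []
    scaffolds: list[str] = []
    truth: dict = {"scaffolds": {}}
    for si in range(spec.n_scaffolds):
        scaffold = f"scaffold_{si + 1}"
        scaffolds.append(scaffold)
        n = spec.genes_per_scaffold
        # planted strand runs, alternating strand
        run_sizes: list[int] = []
        remaining = n
        while remaining > 0:
            if spec.block_sizes is not None:
                size = int(spec.block_sizes[len(run_sizes) % len(spec.block_sizes)])
            else:
                size = int(rng.geometric(spec.block_size_geometric_p))
            size = min(size, remaining)
            run_sizes.append(size)
            remaining -= size
        strands: list[str] = []
        strand = "+" if rng.integers(2) == 0 else "-"
        for size in run_sizes:
            strands.extend([strand] * size)
            strand = "-" if strand == "+" else "+"
        # Disruptor flips: Binomial(n, rate) many, placed >= 2 genes from
        # both ends of a planted run (else the run's edge gene itself
        # becomes a second disruptor), pairwise >= 3 apart and not
        # scaffold-terminal — so each flip is, by construction, exactly
        # one callable orientation disruptor.
        flipped: list[int] = []
        if spec.disruptor_rate > 0:
            eligible: set[int] = set()
            offset = 0
            for size in run_sizes:
                eligible.update(range(offset + 2, offset + size - 2))
                offset += size
            eligible.discard(0)
            eligible.discard(n - 1)
            n_flips = int(rng.binomial(n, spec.disruptor_rate))
            pool = sorted(eligible)
            for _ in range(n_flips):
                if not pool:
                    raise ValueError(
                        "infeasible spec: not enough eligible positions for disruptors"
                    )
                i = pool[int(rng.integers(len(pool)))]
                flipped.append(i)
                pool = [j for j in pool if abs(j - i) > 2]
            flipped.sort()
            for i in flipped:
                strands[i] = "-" if strands[i] == "+" else "+"
        # coordinates: non-overlapping, left to right
        pos = int(rng.integers(spec.intergenic_bp[0], spec.intergenic_bp[1] + 1))
        for gi in range(n):
            length = int(rng.integers(spec.gene_length_bp[0], spec.gene_length_bp[1] + 1))
            genes.append(
                GeneRecord(
                    gene_id=f"{scaffold}.g{gi + 1}",
                    scaffold=scaffold,
                    start=pos,
                    end=pos + length,
                    strand=strands[gi],
                )
            )
            pos += length + int(rng.integers(spec.intergenic_bp[0], spec.intergenic_bp[1] + 1))
        post = _run_length_encode(strands)
        truth["scaffolds"][scaffold] = {
            "pre_flip_runs": run_sizes,
            "flipped_indices": flipped,
            "post_flip_blocks": [size for _, size in post],
            "post_flip_strands": [s for s, _ in post],
        }
    annotation = AnnotationSet(scaffolds=scaffolds, genes=genes, source_path="<synthetic>")
    return annotation, truth


def annotation_to_gff3(annotation: AnnotationSet) -> str:
    """Serialize as GFF3 (converting back to 1-based inclusive)."""
    lines = ["##gff-version 3"]
    for g in annotation.genes:
        lines.append(
            "\t".join(
                [
                    g.scaffold,
                    "dinoarch_sim",
                    "gene",
                    str(g.gff_start),
                    str(g.gff_end),
                    ".",
                    g.strand,
                    ".",
                    f"ID={g.gene_id}",
                ]
            )
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# sequence


@dataclass
class SequenceSpec:
    """Genome sequence with planted GC dips.

    ``background_gc`` defaults to 0.444 (the ~44.4% GC of the genomes
    emulated). Dips of depth ``dip_depth_pp`` percentage points and
    length ``dip_length_bp`` are planted centred on the midpoints of a
    fraction ``dip_placement`` of qualifying converging inter-block
    regions (both flanking blocks >= ``boundary_min_n`` genes; the 0.68
    default placement mirrors the flagged fraction seen in real data).
    ``noise`` is ``iid`` (independent per-base draws) or ``exact``
    (deterministic error-diffusion base placement with no sampling
    noise).
    """

    background_gc: float = 0.444
    dip_depth_pp: float = 5.0
    dip_length_bp: int = 8000
    dip_placement: float = 0.68
    boundary_min_n: int = 10
    noise: str = "iid"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.background_gc < 1:
            raise ValueError("background_gc must be in (0, 1)")
        if self.dip_depth_pp < 0:
            raise ValueError("dip_depth_pp must be >= 0")
        if not 0 <= self.dip_placement <= 1:
            raise ValueError("dip_placement must be in [0, 1]")
        if self.noise not in ("iid", "exact"):
            raise ValueError("noise must be 'iid' or 'exact'")


_BASES_GC = np.frombuffer(b"GC", dtype=np.uint8)
_BASES_AT = np.frombuffer(b"AT", dtype=np.uint8)


def gen_sequence(
    annotation: AnnotationSet, spec: SequenceSpec
) -> tuple[dict[str, str], dict]:
    """Generate genome sequence for an annotation, planting GC dips.

    Returns ({scaffold: sequence}, truth). Truth lists the planted dip
    coordinates and, for every qualifying converging boundary, whether a
    planted dip overlaps its interval (the association the analyzer is
    expected to recover).
    """
    rng = _rng(spec.seed, "sequence")
    ordered = order_genes(annotation)
    blocks = find_blocks(ordered)
    regions = interblock_regions(blocks, ordered, n_values=(spec.boundary_min_n,))
    candidates = [
        r
        for r in regions
        if r.orientation_class == "converging"
        and r.qualifies(spec.boundary_min_n)
        and r.length > 0
    ]
    n_planted = int(round(spec.dip_placement * len(candidates)))
    chosen_idx = sorted(
        rng.choice(len(candidates), size=n_planted, replace=False)
    ) if n_planted else []
    chosen = [candidates[i] for i in chosen_idx]

    lengths = {s: 0 for s in annotation.scaffolds}
    for g in annotation.genes:
        lengths[g.scaffold] = max(lengths[g.scaffold], g.end)
    for s in lengths:
        lengths[s] += 2000  # tail margin

    dips_by_scaffold: dict[str, list[tuple[int, int]]] = {s: [] for s in annotation.scaffolds}
    planted: list[dict] = []
    for r in chosen:
        mid = (r.start + r.end) // 2
        start = max(0, mid - spec.dip_length_bp // 2)
        end = min(lengths[r.scaffold], start + spec.dip_length_bp)
        if end - start < spec.dip_length_bp:
            raise ValueError(f"dip longer than scaffold {r.scaffold}")
        dips_by_scaffold[r.scaffold].append((start, end))
        planted.append({"scaffold": r.scaffold, "start": start, "end": end})

    seqs: dict[str, str] = {}
    for scaffold in annotation.scaffolds:
        n = lengths[scaffold]
        p = np.full(n, spec.background_gc)
        for start, end in dips_by_scaffold[scaffold]:
            p[start:end] = spec.background_gc - spec.dip_depth_pp / 100.0
        if spec.noise == "iid":
            is_gc = rng.random(n) < p
        else:
            # error diffusion: GC bases placed wherever the cumulative
            # target crosses an integer — locally exact composition
            cum = np.floor(np.concatenate(([0.0], np.cumsum(p))))
            is_gc = np.diff(cum) > 0
        # alternate G/C and A/T deterministically within each class
        out = np.empty(n, dtype=np.uint8)
        idx_gc = np.flatnonzero(is_gc)
        idx_at = np.flatnonzero(~is_gc)
        out[idx_gc] = _BASES_GC[np.arange(len(idx_gc)) % 2]
        out[idx_at] = _BASES_AT[np.arange(len(idx_at)) % 2]
        seqs[scaffold] = out.tobytes().decode("ascii")

    boundary_truth = []
    for r in candidates:
        flagged = any(
            d["scaffold"] == r.scaffold and d["start"] < r.end and r.start < d["end"]
            for d in planted
        )
        boundary_truth.append(
            {
                "scaffold": r.scaffold,
                "start": r.start,
                "end": r.end,
                "expected_flag": flagged,
            }
        )
    truth = {
        "planted_dips": planted,
        "boundaries": boundary_truth,
        "background_gc": spec.background_gc,
        "dip_depth_pp": spec.dip_depth_pp,
    }
    return seqs, truth


def sequences_to_fasta(seqs: Mapping[str, str], width: int = 80) -> str:
    lines = []
    for name, seq in seqs.items():
        lines.append(f">{name}")
        for i in range(0, len(seq), width):
            lines.append(seq[i : i + width])
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# trees


@dataclass
class TreeSpec:
    """One synthetic gene tree with a planted category clade.

    The planted clade is a flat multifurcation (no supported internal
    structure) holding every dinoflagellate leaf plus the partner leaves
    the category requires, attached at the requested support; remaining
    taxa hang off the root individually.
    """

    category: str
    support: float = 95.0
    n_dino: int = 3
    n_partner: int = 2
    n_outgroup: int = 3


# partner groups whose taxa join the dinoflagellates inside the planted
# clade, per category; None -> dinoflagellates only
_CATEGORY_PARTNERS: dict[str, tuple[str, ...]] = {
    "A": (),
    "B": ("Perkinsea", "Chromerida"),
    "C": ("Stramenopiles",),
    "D": ("Rhizaria",),
    "E": ("Stramenopiles", "Haptophyta", "Cryptophyta"),
    "F": ("Rhodophyta",),
    "G": ("Viridiplantae",),
    "H": ("Rhodophyta", "Viridiplantae"),
    "I": ("Rhodophyta", "Viridiplantae", "Glaucophyta"),
    "J": ("Haptophyta",),
    "K": ("Cryptophyta",),
    "L": ("Metazoa", "Fungi"),
    "M": ("Amoebozoa", "Excavata"),
    "N": ("Bacteria",),
    "O": ("Archaea",),
}

CATEGORIES: tuple[str, ...] = tuple(_CATEGORY_PARTNERS)


def _taxa_in_group(taxon_map: TaxonGroupMap, group: str) -> list[str]:
    return [t for t in taxon_map.taxa if taxon_map.in_group(t, group)]


def gen_trees(
    specs: Sequence[TreeSpec],
    taxon_map: TaxonGroupMap,
    seed: int = 0,
) -> tuple[list[GeneTree], list[dict]]:
    """Generate one tree per spec; truth lists (tree_id, category, support)."""
    import dendropy

    rng = _rng(seed, "trees")
    trees: list[GeneTree] = []
    truth: list[dict] = []
    for i, spec in enumerate(specs):
        if spec.category not in _CATEGORY_PARTNERS:
            raise ValueError(f"unknown category {spec.category!r}")
        partner_groups = _CATEGORY_PARTNERS[spec.category]
        dinos = _taxa_in_group(taxon_map, "Dinophyceae")
        clade_leaves = list(dinos[: max(spec.n_dino, 2)])
        # every dinoflagellate leaf of the tree goes inside the clade, so
        # the matched rule's subject-proportion requirement always holds
        used_groups = {"Dinophyceae"}
        for g in partner_groups:
            used_groups.add(g)
            members = _taxa_in_group(taxon_map, g)
            if not members:
                raise ValueError(f"category {spec.category}: no taxa for group {g!r}")
            clade_leaves.extend(members[: spec.n_partner])
        out_pool = [
            t
            for t in taxon_map.taxa
            if not any(taxon_map.in_group(t, g) for g in used_groups)
        ]
        out_pool = [out_pool[j] for j in rng.permutation(len(out_pool))]
        outgroup = out_pool[: max(spec.n_outgroup, 2)]
        clade = ",".join(clade_leaves)
        newick = f"(({clade}){spec.support:g},{','.join(outgroup)});"
        tree = dendropy.Tree.get(
            data=newick, schema="newick", suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
        tree_id = f"tree_{i + 1:04d}_{spec.category}"
        leaves = tuple(l.taxon.label for l in tree.leaf_node_iter())
        trees.append(GeneTree(tree_id=tree_id, tree=tree, leaves=leaves))
        truth.append({"tree_id": tree_id, "category": spec.category, "support": spec.support})
    return trees, truth


def trees_to_newick(trees: Sequence[GeneTree]) -> dict[str, str]:
    return {
        t.tree_id: t.tree.as_string(schema="newick", suppress_rooting=True,
                                    unquoted_underscores=True).strip()
        for t in trees
    }


# ---------------------------------------------------------------------------
# orthogroups


def gen_orthogroups(
    plan: Sequence[Mapping[str, int]],
    taxon_map: TaxonGroupMap,
    seed: int = 0,
) -> tuple[str, list[dict]]:
    """Realize a composition plan as an Orthogroups.tsv text + truth.

    ``plan`` lists, per set, ``{taxon: member_count}``. Truth carries
    each set's intended phylum composition and total size so the
    sharing analyses can be checked exactly.
    """
    _rng(seed, "orthogroups")  # reserved stream; layout is deterministic
    columns = list(taxon_map.taxa)
    lines = ["Orthogroup\t" + "\t".join(columns)]
    truth: list[dict] = []
    counter = 0
    for row in plan:
        counter += 1
        set_id = f"OG{counter:07d}"
        cells = []
        for taxon in columns:
            k = row.get(taxon, 0)
            cells.append(
                ", ".join(f"{taxon}_p{counter}_{j + 1}" for j in range(k)) if k else ""
            )
        lines.append(set_id + "\t" + "\t".join(cells))
        phyla = sorted({taxon_map.phylum_of(t) for t, k in row.items() if k > 0})
        truth.append(
            {
                "set_id": set_id,
                "phyla": phyla,
                "n_members": sum(row.values()),
                "taxa": sorted(t for t, k in row.items() if k > 0),
            }
        )
    return "\n".join(lines) + "\n", truth
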