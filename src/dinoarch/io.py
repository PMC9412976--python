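"""Readers and writers for the external formats the pipeline touches.

Inputs: GFF3 gene models, FASTA genome, newick gene trees with
internal-node support labels, OrthoFinder-style ``Orthogroups.tsv``, and a
taxon->group TSV. Outputs: BED (0-based half-open), TSV tables and a JSON
run summary, each stamped with the config hash.

GFF3 coordinates (1-based inclusive) are converted to the internal 0-based
half-open convention here and nowhere else; BED shares the internal
convention, so ``start_bed = start_gff - 1`` and ``end_bed = end_gff``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import pandas as pd
from Bio import SeqIO
from gffutils.feature import feature_from_line

from dinoarch.model import AnnotationSet, GeneRecord, GeneTree, HomologSet, TreeSet
from dinoarch.taxonomy import DEFAULT_HIERARCHY, TaxonGroupMap

logger = logging.getLogger("dinoarch")


def read_gff3_genes(path: str | Path, feature_type: str = "gene") -> AnnotationSet:
    """Read one GeneRecord per GFF3 feature of ``feature_type``.

    Features with no strand ('.' or '?') are rejected with a counted
    warning — orientation is the analyte, so imputing a strand would bias
    every downstream block statistic. Malformed lines raise with the line
    number.
    """
    path = Path(path)
    genes: list[GeneRecord] = []
    scaffolds: list[str] = []
    seen_scaffolds: set[str] = set()
    n_strandless = 0
    n_anon = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):  # embedded ##FASTA section
                break
            if line.count("\t") != 8:
                raise ValueError(
                    f"{path}: malformed GFF3 at line {lineno}: expected 9 tab-separated columns"
                )
            try:
                feat = feature_from_line(line)
            except Exception as exc:
                raise ValueError(f"{path}: malformed GFF3 at line {lineno}: {exc}") from exc
            if feat.featuretype != feature_type:
                continue
            if feat.strand not in ("+", "-"):
                n_strandless += 1
                logger.warning(
                    "%s line %d: feature without strand (%r) excluded from orientation analysis",
                    path,
                    lineno,
                    feat.strand,
                )
                continue
            gene_id = feat.attributes.get("ID", [None])[0]
            if gene_id is None:
                n_anon += 1
                gene_id = f"{path.stem}.line{lineno}"
            if feat.seqid not in seen_scaffolds:
                seen_scaffolds.add(feat.seqid)
                scaffolds.append(feat.seqid)
            genes.append(
                GeneRecord(
                    gene_id=gene_id,
                    scaffold=feat.seqid,
                    start=feat.start - 1,  # GFF3 1-based inclusive -> 0-based half-open
                    end=feat.end,
                    strand=feat.strand,
                )
            )
    if not genes:
        logger.warning("%s: no %r features found", path, feature_type)
    return AnnotationSet(
        scaffolds=scaffolds,
        genes=genes,
        source_path=str(path),
        n_rejected_strandless=n_strandless,
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA into ``{scaffold_id: sequence}``.

    Ids are the header token before the first whitespace, matching the
    GFF3 scaffold column. Duplicate ids and empty files are errors.
    """
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seqs:
            raise ValueError(f"{path}: duplicate FASTA id {record.id!r}")
        seqs[record.id] = str(record.seq).upper()
    if not seqs:
        raise ValueError(f"{path}: empty FASTA")
    return seqs


def _support_of(label: str | None) -> float | None:
    if label is None or label == "":
        return None
    try:
        return float(label)
    except ValueError:
        raise ValueError(f"non-numeric internal node label {label!r}")


def read_newick_trees(path: str | Path) -> TreeSet:
    """Read newick trees from a file (one per line) or a directory.

    Internal node labels are bootstrap supports. The scale is
    auto-detected over the whole set: all supports <= 1 -> fractions,
    otherwise percentages; everything is normalized to percent. A file
    mixing the two scales would silently corrupt every threshold, so a
    fraction-scaled set containing any support > 1 is an error.
    """
    path = Path(path)
    entries: list[tuple[str, str]] = []  # (tree_id, newick)
    if path.is_dir():
        for f in sorted(path.iterdir()):
            if f.is_file():
                text = f.read_text().strip()
                if text:
                    entries.append((f.stem, text))
    else:
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                line = line.strip()
                if line:
                    entries.append((f"{path.stem}.{i}", line))

    trees: list[GeneTree] = []
    all_supports: list[float] = []
    for tree_id, newick in entries:
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
        leaves = tuple(l.taxon.label for l in tree.leaf_node_iter())
        for node in tree.preorder_internal_node_iter():
            s = _support_of(node.label)
            if s is not None:
                all_supports.append(s)
        trees.append(GeneTree(tree_id=tree_id, tree=tree, leaves=leaves))

    scale = "fraction" if all_supports and max(all_supports) <= 1.0 else "percent"
    if scale == "fraction":
        for gt in trees:
            for node in gt.tree.preorder_internal_node_iter():
                s = _support_of(node.label)
                if s is not None:
                    node.label = repr(s * 100.0)
    for s in all_supports:
        if s < 0 or (scale == "percent" and s > 100):
            raise ValueError(f"support {s} outside [0, 100]")
    return TreeSet(trees=trees, support_scale=scale)


def read_orthogroups(path: str | Path) -> list[HomologSet]:
    """Read an OrthoFinder-style ``Orthogroups.tsv``.

    First column is the set id, remaining columns one per taxon holding
    comma-separated sequence ids; empty cells are allowed. All-empty rows
    are dropped with a warning; duplicate set ids are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    id_col = df.columns[0]
    if df[id_col].duplicated().any():
        dup = df[id_col][df[id_col].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate orthogroup id {dup!r}")
    sets: list[HomologSet] = []
    for _, row in df.iterrows():
        members: list[tuple[str, str]] = []
        for taxon in df.columns[1:]:
            cell = row[taxon].strip()
            if not cell:
                continue
            for seq in cell.split(","):
                seq = seq.strip()
                if seq:
                    members.append((taxon, seq))
        if not members:
            logger.warning("%s: orthogroup %s has no members, dropped", path, row[id_col])
            continue
        sets.append(HomologSet(set_id=row[id_col], members=members))
    return sets


def read_taxon_map(
    path: str | Path,
    hierarchy: Mapping[str, str] | None = None,
) -> TaxonGroupMap:
    """Read a two-column ``taxon<TAB>group`` TSV (no header required).

    Lines of the form ``@parent<TAB>child<TAB>parent_group`` extend the
    built-in group hierarchy; otherwise the NCBI-style default is used.
    """
    taxon_to_group: dict[str, str] = {}
    extra_hierarchy: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "@parent":
                if len(parts) != 3:
                    raise ValueError(f"{path} line {lineno}: @parent needs child and parent")
                extra_hierarchy[parts[1]] = parts[2]
                continue
            if len(parts) < 2:
                raise ValueError(f"{path} line {lineno}: expected taxon<TAB>group")
            if parts[0].lower() == "taxon" and lineno == 1:
                continue  # header row
            taxon_to_group[parts[0]] = parts[1]
    h = dict(DEFAULT_HIERARCHY if hierarchy is None else hierarchy)
    h.update(extra_hierarchy)
    return TaxonGroupMap(taxon_to_group=taxon_to_group, hierarchy=h)


def config_hash(config: Mapping) -> str:
    """Short stable hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_bed(intervals: Iterable[tuple[str, int, int, str]], path: str | Path, cfg_hash: str) -> None:
    """Write (scaffold, start, end, name) records as BED (0-based half-open)."""
    with open(path, "w") as fh:
        fh.write(f"#config_hash={cfg_hash}\n")
        for scaffold, start, end, name in intervals:
            fh.write(f"{scaffold}\t{start}\t{end}\t{name}\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            scaffold, start, end, name = line.rstrip("\n").split("\t")[:4]
            out.append((scaffold, int(start), int(end), name))
    return out


def write_reports(results: Mapping[str, object], out_dir: str | Path, cfg_hash: str = "") -> list[Path]:
    """Write result tables and the run summary.

    ``results`` maps names to pandas DataFrames (written as TSV), lists
    of BED tuples (keys ending in ``.bed``) or JSON-serializable objects
    (keys ending in ``.json``). Every file carries the config hash.
    Returns the written paths.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out_dir} is not writable: {exc}") from exc

    written: list[Path] = []
    for name, obj in results.items():
        if name.endswith(".bed"):
            p = out_dir / name
            write_bed(obj, p, cfg_hash)  # type: ignore[arg-type]
        elif name.endswith(".json"):
            p = out_dir / name
            payload = {"config_hash": cfg_hash, **obj}  # type: ignore[dict-item]
            p.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        else:
            p = out_dir / (name if name.endswith(".tsv") else f"{name}.tsv")
            df = obj if isinstance(obj, pd.DataFrame) else pd.DataFrame(obj)
            with open(p, "w") as fh:
                fh.write(f"#config_hash={cfg_hash}\n")
                df.to_csv(fh, sep="\t", index=False)
        written.append(p)
    return written
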