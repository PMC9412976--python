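"""End-to-end orchestration of the analysis stages.

Stages run in dependency order: ``blocks`` (gene-orientation
architecture) feeds ``gcdip`` (GC-dip association); ``trees`` (tree
sorting) and ``sharing`` (orthogroup analysis) are independent. A stage
error aborts only its dependents; independent stages still run and the
consolidated summary marks the failure. Every output file carries the
hash of the serialized configuration, and identical config + inputs
yield byte-identical summaries.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from dinoarch import architecture, gc_profile, gene_sharing, tree_sorting
from dinoarch.io import (
    config_hash,
    read_fasta,
    read_gff3_genes,
    read_newick_trees,
    read_orthogroups,
    read_taxon_map,
    write_reports,
)

logger = logging.getLogger("dinoarch")


@dataclass
class PipelineConfig:
    """All inputs and tunables of one pipeline run."""

    out_dir: str = "dinoarch_out"
    seed: int = 0
    # inputs (a stage is enabled iff its inputs are set)
    gff: str | None = None
    fasta: str | None = None
    trees: str | None = None
    orthogroups: str | None = None
    taxon_map: str | None = None
    query_taxon: str | None = None
    # architecture
    feature_type: str = "gene"
    window: int = 10
    n_values: tuple[int, ...] = (4, 6, 8, 10)
    # gc profile
    gc_width: int = 4000
    gc_step: int = 100
    dip_threshold_pp: float = 0.05
    dip_min_length_bp: int = 5000
    dip_mode: str = "overlap"
    # tree sorting
    thresholds: tuple[float, ...] = (90.0, 70.0, 50.0)
    min_prop_subject: float = 0.7
    rules_path: str | None = None
    # gene sharing
    x_values: tuple[int, ...] = (2, 20, 40, 60)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def hash(self) -> str:
        # output location is not part of the analysis fingerprint
        payload = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        return config_hash(payload)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("n_values", "thresholds", "x_values"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _blocks_stage(config: PipelineConfig, results: dict) -> dict:
    annotation = read_gff3_genes(config.gff, feature_type=config.feature_type)
    ordered = architecture.order_genes(annotation)
    hist = architecture.orientation_histogram(ordered, w=config.window)
    blocks = architecture.find_blocks(ordered)
    occupancy = architecture.block_occupancy(blocks)
    regions = architecture.interblock_regions(blocks, ordered, n_values=config.n_values)
    counts = architecture.region_counts(regions, n_values=config.n_values)
    disruptors = architecture.find_disruptors(ordered)

    results["windows.tsv"] = pd.DataFrame(
        sorted(hist.counts.items()), columns=["n_changes", "n_windows"]
    )
    results["blocks.tsv"] = pd.DataFrame(
        [
            {
                "scaffold": b.scaffold,
                "strand": b.strand,
                "first_index": b.first_index,
                "last_index": b.last_index,
                "size": b.size,
            }
            for b in blocks
        ]
    )
    results["occupancy.tsv"] = pd.DataFrame(
        occupancy.items(), columns=["min_block_size", "pct_genes"]
    )
    results["regions.bed"] = [
        (
            r.scaffold,
            r.start,
            r.end,
            f"{r.orientation_class};N={','.join(map(str, r.min_block_size_qualified))}",
        )
        for r in regions
    ]
    results["disruptors.tsv"] = pd.DataFrame(
        [
            {"gene_id": d.gene_id, "scaffold": d.scaffold, "flanking_strand": d.flanking_strand}
            for d in disruptors
        ]
    )
    n_genes = len(annotation)
    return {
        "n_genes": n_genes,
        "n_windows": hist.total_windows,
        "conserved_window_pct": 100.0 * hist.conserved_fraction if hist.total_windows else None,
        "pct_genes_in_blocks_ge_10": occupancy.get(10, 0.0) if max(occupancy) >= 10 else 0.0,
        "n_blocks": len(blocks),
        "region_counts": {f"N{n}_{cls}": c for (n, cls), c in counts.items()},
        "n_disruptors": len(disruptors),
        "disruptor_pct": 100.0 * len(disruptors) / n_genes if n_genes else None,
        "_regions": regions,  # passed to the gcdip stage, stripped from the summary
    }


def _gcdip_stage(config: PipelineConfig, results: dict, regions) -> dict:
    seqs = read_fasta(config.fasta)
    all_dips = []
    for scaffold, seq in seqs.items():
        try:
            background = gc_profile.scaffold_background_gc(seq)
        except ValueError:
            logger.warning("scaffold %s skipped: background GC undefined", scaffold)
            continue
        windows = gc_profile.sliding_gc(seq, scaffold, config.gc_width, config.gc_step)
        all_dips.extend(
            gc_profile.detect_dips(
                windows, background, config.dip_threshold_pp, config.dip_min_length_bp
            )
        )
    converging = [r for r in regions if r.orientation_class == "converging"]
    flags = gc_profile.associate_dips(converging, all_dips, mode=config.dip_mode)
    summary = gc_profile.boundary_dip_summary(flags, n_values=config.n_values)

    results["dips.bed"] = [
        (d.scaffold, d.start, d.end, f"dev={d.max_deviation:.3f}pp") for d in all_dips
    ]
    results["boundary_flags.tsv"] = pd.DataFrame(
        [
            {
                "scaffold": f["region"].scaffold,
                "start": f["region"].start,
                "end": f["region"].end,
                "qualified_N": ",".join(map(str, f["region"].min_block_size_qualified)),
                "flagged": f["flagged"],
                "reason": f["reason"],
            }
            for f in flags
        ]
    )
    return {
        "n_dips": len(all_dips),
        "boundary_dip_fraction": {
            f"N{n}": {"flagged": fl, "total": tot} for n, (fl, tot) in summary.items()
        },
    }


def _trees_stage(config: PipelineConfig, results: dict) -> dict:
    tree_set = read_newick_trees(config.trees)
    taxon_map = read_taxon_map(config.taxon_map)
    if config.rules_path:
        rules = tree_sorting.load_rule_table(config.rules_path)
    else:
        rules = tree_sorting.default_rule_table(taxon_map)
    outcomes, summary = tree_sorting.sort_tree_set(
        tree_set.trees,
        taxon_map,
        rules=rules,
        thresholds=config.thresholds,
        min_prop_subject=config.min_prop_subject,
    )
    results["sort_outcomes.tsv"] = outcomes
    results["sort_summary.tsv"] = summary
    return {
        "n_trees": len(tree_set),
        "classified": {
            f"BS{int(row.threshold)}": int(row.n_classified) for row in summary.itertuples()
        },
    }


def _sharing_stage(config: PipelineConfig, results: dict) -> dict:
    sets = read_orthogroups(config.orthogroups)
    taxon_map = read_taxon_map(config.taxon_map)
    query = config.query_taxon
    if query is None:
        raise ValueError("sharing stage requires query_taxon")
    per_protein, level_counts = gene_sharing.classify_specificity(sets, taxon_map, query)
    partners = gene_sharing.partner_counts(sets, taxon_map, x_values=config.x_values)
    dinos = [t for t in taxon_map.taxa if taxon_map.in_group(t, "Dinophyceae")]
    single_copy = gene_sharing.select_single_copy(sets, dinos)

    results["specificity.tsv"] = pd.DataFrame(
        [
            {"protein": p, "class": c.kind, "level": c.level or ""}
            for p, c in sorted(per_protein.items())
        ]
    )
    results["partners.tsv"] = partners.reset_index()
    results["single_copy.tsv"] = pd.DataFrame({"set_id": single_copy})
    return {
        "n_sets": len(sets),
        "specificity_counts": level_counts,
        "n_single_copy": len(single_copy),
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every enabled stage; write tables and a consolidated summary.

    Returns the summary dict (also written as ``summary.json``). A
    failed stage is recorded under ``errors`` and non-zero exit is left
    to the CLI; dependent stages are skipped, independent ones run.
    """
    cfg_hash = config.hash
    results: dict = {}
    summary: dict = {"stages": {}, "errors": {}}
    regions = None

    if config.gff:
        t0 = time.monotonic()
        try:
            stage = _blocks_stage(config, results)
            regions = stage.pop("_regions")
            summary["stages"]["blocks"] = stage
            logger.info("blocks stage done in %.1fs", time.monotonic() - t0)
        except Exception as exc:
            logger.error("blocks stage failed: %s", exc)
            summary["errors"]["blocks"] = str(exc)

    if config.fasta:
        if regions is None:
            msg = "gcdip stage requires the blocks stage (gff input) to have run"
            logger.error(msg)
            summary["errors"]["gcdip"] = msg
        else:
            t0 = time.monotonic()
            try:
                summary["stages"]["gcdip"] = _gcdip_stage(config, results, regions)
                logger.info("gcdip stage done in %.1fs", time.monotonic() - t0)
            except Exception as exc:
                logger.error("gcdip stage failed: %s", exc)
                summary["errors"]["gcdip"] = str(exc)

    if config.trees:
        t0 = time.monotonic()
        try:
            summary["stages"]["trees"] = _trees_stage(config, results)
            logger.info("trees stage done in %.1fs", time.monotonic() - t0)
        except Exception as exc:
            logger.error("trees stage failed: %s", exc)
            summary["errors"]["trees"] = str(exc)

    if config.orthogroups:
        t0 = time.monotonic()
        try:
            summary["stages"]["sharing"] = _sharing_stage(config, results)
            logger.info("sharing stage done in %.1fs", time.monotonic() - t0)
        except Exception as exc:
            logger.error("sharing stage failed: %s", exc)
            summary["errors"]["sharing"] = str(exc)

    results["summary.json"] = json.loads(json.dumps(summary))
    write_reports(results, config.out_dir, cfg_hash=cfg_hash)
    return summary
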