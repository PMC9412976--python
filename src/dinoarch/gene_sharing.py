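"""Orthogroup-based lineage specificity and gene-sharing partners.

Query-species proteins are classified by the taxonomic breadth of their
homologous set: specific to the species, to its order (Suessiales), to
the class Dinophyceae, shared exclusively with one other phylum (the
*exclusive gene-sharing partner*), or spread over two or more non-
dinoflagellate phyla. Partner counts are tabulated across minimum set
sizes x, and strictly single-copy orthogroups can be selected for
species-tree inference.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from dinoarch.model import HomologSet, SpecificityClass
from dinoarch.taxonomy import TaxonGroupMap

DEFAULT_X_VALUES: tuple[int, ...] = (2, 20, 40, 60)
DEFAULT_LEVELS: tuple[str, ...] = ("Suessiales", "Dinophyceae")


def classify_specificity(
    sets: Sequence[HomologSet],
    taxon_map: TaxonGroupMap,
    query_taxon: str,
    query_proteome: Iterable[str] | None = None,
    levels: Sequence[str] = DEFAULT_LEVELS,
) -> tuple[dict[str, SpecificityClass], dict[str, int]]:
    """Classify every query protein by its homolog set's taxon breadth.

    Assignment uses the narrowest level containing all the set's taxa:
    query species only -> ``species_specific``; all within the first
    level (Suessiales) -> ``clade_specific(Suessiales)``; all within the
    next (Dinophyceae) -> ``clade_specific(Dinophyceae)``; Dinophyceae
    plus exactly one other phylum -> ``exclusive_two_phylum(partner)``;
    two or more non-dinoflagellate phyla -> ``multi_phylum``. Query
    proteins (from ``query_proteome``) absent from every set are
    species-specific singletons. Returns (per-protein classes, level
    counts); the level counts partition the query proteome.

    A taxon absent from the map raises ``KeyError``.
    """
    per_protein: dict[str, SpecificityClass] = {}
    for hs in sets:
        query_seqs = [seq for taxon, seq in hs.members if taxon == query_taxon]
        if not query_seqs:
            continue
        taxa = hs.taxa
        for t in taxa:
            taxon_map.group_of(t)  # raise early on unmapped taxa
        if taxa == {query_taxon}:
            cls = SpecificityClass("species_specific")
        else:
            cls = None
            for level in levels:
                if all(taxon_map.in_group(t, level) for t in taxa):
                    cls = SpecificityClass("clade_specific", level)
                    break
            if cls is None:
                phyla = {taxon_map.phylum_of(t) for t in taxa}
                other = phyla - {"Dinophyceae"}
                if len(other) == 1:
                    cls = SpecificityClass("exclusive_two_phylum", next(iter(other)))
                else:
                    cls = SpecificityClass("multi_phylum")
        for seq in query_seqs:
            per_protein[seq] = cls

    if query_proteome is not None:
        for seq in query_proteome:
            if seq not in per_protein:
                per_protein[seq] = SpecificityClass("species_specific")

    counts: dict[str, int] = {
        "species_specific": 0,
        **{f"clade_specific:{lv}": 0 for lv in levels},
        "exclusive_two_phylum": 0,
        "multi_phylum": 0,
    }
    for cls in per_protein.values():
        if cls.kind == "clade_specific":
            counts[f"clade_specific:{cls.level}"] += 1
        else:
            counts[cls.kind] += 1
    return per_protein, counts


def partner_counts(
    sets: Sequence[HomologSet],
    taxon_map: TaxonGroupMap,
    x_values: Sequence[int] = DEFAULT_X_VALUES,
    count_mode: str = "sequences",
) -> pd.DataFrame:
    """Exclusive gene-sharing-partner table: partner phylum x minimum size.

    A set qualifies for partner P at minimum size x iff its taxa lie
    entirely within Dinophyceae plus the single phylum P, it has at
    least one member on each side, and its size reaches x. Size is the
    total sequence count by default (``count_mode='sequences'``) or the
    distinct-taxon count (``'taxa'``). Counts are non-increasing in x.
    """
    if count_mode not in ("sequences", "taxa"):
        raise ValueError("count_mode must be 'sequences' or 'taxa'")
    table: dict[str, dict[int, int]] = {}
    for hs in sets:
        phyla = {taxon_map.phylum_of(t) for t in hs.taxa}
        other = phyla - {"Dinophyceae"}
        if "Dinophyceae" not in phyla or len(other) != 1:
            continue
        partner = next(iter(other))
        size = len(hs) if count_mode == "sequences" else len(hs.taxa)
        row = table.setdefault(partner, {x: 0 for x in x_values})
        for x in x_values:
            if size >= x:
                row[x] += 1
    df = pd.DataFrame.from_dict(table, orient="index", columns=None)
    if df.empty:
        df = pd.DataFrame(columns=list(x_values))
    df = df.reindex(columns=list(x_values), fill_value=0).sort_index()
    df.index.name = "partner"
    return df


def exclusive_partner_protein_count(
    sets: Sequence[HomologSet],
    taxon_map: TaxonGroupMap,
    query_taxon: str,
) -> int:
    """Query proteins inside qualifying two-phylum sets (x >= 2 view)."""
    total = 0
    for hs in sets:
        phyla = {taxon_map.phylum_of(t) for t in hs.taxa}
        other = phyla - {"Dinophyceae"}
        if "Dinophyceae" in phyla and len(other) == 1:
            total += sum(1 for t, _ in hs.members if t == query_taxon)
    return total


def select_single_copy(
    sets: Sequence[HomologSet],
    taxa_of_interest: Sequence[str],
    strict: bool = True,
) -> list[str]:
    """Ids of sets in which each taxon of interest occurs at most once.

    In strict mode (default) every taxon of interest must occur exactly
    once — the strictly orthologous single-copy selection used for
    species-tree inference.
    """
    out: list[str] = []
    interest = list(taxa_of_interest)
    for hs in sets:
        tally = {t: 0 for t in interest}
        for taxon, _ in hs.members:
            if taxon in tally:
                tally[taxon] += 1
        if any(c > 1 for c in tally.values()):
            continue
        if strict and any(c == 0 for c in tally.values()):
            continue
        out.append(hs.set_id)
    return out
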