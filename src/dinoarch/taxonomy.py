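"""Taxon -> group mapping and the group hierarchy used throughout sorting.

Each taxon maps to its most specific group label (e.g. ``Suessiales`` for
*Cladocopium goreaui*); a parent relation lifts groups toward supergroups
(Suessiales -> Dinophyceae -> Alveolata -> SAR). Membership queries walk the
parent chain, so a Suessiales taxon is ``in_group`` Dinophyceae, Alveolata
and SAR. The hierarchy follows NCBI Taxonomy at the ranks the analyses
need; it is acyclic by construction and validated on load.
"""

from __future__ import annotations

from dataclasses import dataclass, field

# group -> parent (roots omitted). Eukaryote supergroups per the current
# consensus tree of life; Dinophyceae sit inside Alveolata inside SAR.
DEFAULT_HIERARCHY: dict[str, str] = {
    "Suessiales": "Dinophyceae",
    "Dinophyceae": "Alveolata",
    "Perkinsea": "Alveolata",
    "Chromerida": "Alveolata",
    "Apicomplexa": "Alveolata",
    "Ciliophora": "Alveolata",
    "Alveolata": "SAR",
    "Stramenopiles": "SAR",
    "Rhizaria": "SAR",
    "Rhodophyta": "Archaeplastida",
    "Viridiplantae": "Archaeplastida",
    "Glaucophyta": "Archaeplastida",
    "Metazoa": "Opisthokonta",
    "Fungi": "Opisthokonta",
}

# Labels treated as phylum rank when reporting gene-sharing partners and
# two-phylum exclusivity (Dinophyceae itself counts as the subject phylum).
DEFAULT_PHYLUM_RANK: frozenset[str] = frozenset(
    {
        "Dinophyceae",
        "Perkinsea",
        "Chromerida",
        "Apicomplexa",
        "Ciliophora",
        "Stramenopiles",
        "Rhizaria",
        "Haptophyta",
        "Cryptophyta",
        "Rhodophyta",
        "Viridiplantae",
        "Glaucophyta",
        "Metazoa",
        "Fungi",
        "Amoebozoa",
        "Excavata",
        "Bacteria",
        "Archaea",
    }
)


@dataclass
class TaxonGroupMap:
    """Resolves taxa to groups and groups to their ancestor chain."""

    taxon_to_group: dict[str, str]
    hierarchy: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_HIERARCHY))
    phylum_rank: frozenset[str] = DEFAULT_PHYLUM_RANK

    def __post_init__(self) -> None:
        for group in self.hierarchy:
            seen = set()
            g: str | None = group
            while g is not None:
                if g in seen:
                    raise ValueError(f"cycle in group hierarchy at {g!r}")
                seen.add(g)
                g = self.hierarchy.get(g)

    def group_of(self, taxon: str) -> str:
        """Most specific group of ``taxon``; leaf labels may carry a
        ``taxon|sequence_id`` suffix which is stripped."""
        base = taxon.split("|", 1)[0]
        try:
            return self.taxon_to_group[base]
        except KeyError:
            raise KeyError(f"taxon {taxon!r} absent from the taxon-group map") from None

    def __contains__(self, taxon: str) -> bool:
        return taxon.split("|", 1)[0] in self.taxon_to_group

    def chain(self, group: str) -> tuple[str, ...]:
        """``group`` followed by its ancestors, most specific first."""
        out = [group]
        g = self.hierarchy.get(group)
        while g is not None:
            out.append(g)
            g = self.hierarchy.get(g)
        return tuple(out)

    def in_group(self, taxon: str, group: str) -> bool:
        return group in self.chain(self.group_of(taxon))

    def leaf_in_any(self, taxon: str, groups: frozenset[str] | set[str]) -> bool:
        return any(g in groups for g in self.chain(self.group_of(taxon)))

    def phylum_of(self, taxon: str) -> str:
        """Phylum-rank label on the taxon's ancestor chain.

        Falls back to the top of the chain for groups with no designated
        phylum rank (e.g. a bare supergroup label).
        """
        ch = self.chain(self.group_of(taxon))
        for g in ch:
            if g in self.phylum_rank:
                return g
        return ch[-1]

    @property
    def taxa(self) -> list[str]:
        return list(self.taxon_to_group)
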