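"""Lineage specificity and exclusive gene-sharing partners from orthogroups.

Realizes a small orthogroup composition plan, classifies the query
species' proteins by the taxonomic breadth of their homolog sets, counts
exclusive gene-sharing partners across minimum set sizes, and selects
strictly single-copy sets.
"""

from dinoarch import simulate
from dinoarch.gene_sharing import (
    classify_specificity,
    partner_counts,
    select_single_copy,
)
from dinoarch.io import read_orthogroups
import tempfile
from pathlib import Path

taxon_map = simulate.default_taxon_map()
query = "Cladocopium_goreaui"
plan = [
    {query: 2},                                                # species specific
    {query: 1, "Breviolum_minutum": 2},                        # Suessiales
    {query: 1, "Alexandrium_tamarense": 1},                    # Dinophyceae
    {query: 2, "Emiliania_huxleyi": 25},                       # partner: Haptophyta
    {query: 3, "Chondrus_crispus": 45},                        # partner: Rhodophyta
    {query: 1, "Homo_sapiens": 1, "Escherichia_coli": 1},      # multi-phylum
    {t: 1 for t in taxon_map.taxa if taxon_map.in_group(t, "Dinophyceae")},
]
text, _ = simulate.gen_orthogroups(plan, taxon_map, seed=1)
with tempfile.TemporaryDirectory() as d:
    path = Path(d) / "Orthogroups.tsv"
    path.write_text(text)
    sets = read_orthogroups(path)

proteome = [s for hs in sets for t, s in hs.members if t == query]
per_protein, counts = classify_specificity(sets, taxon_map, query, query_proteome=proteome)
partners = partner_counts(sets, taxon_map)
dinos = [t for t in taxon_map.taxa if taxon_map.in_group(t, "Dinophyceae")]
single_copy = select_single_copy(sets, dinos)

print(f"query proteins: {len(proteome)} in {len(sets)} homologous sets")
for name, n in counts.items():
    print(f"  {name}: {n}")
print("exclusive gene-sharing partners (sets, by minimum set size x):")
print(partners.to_string())
print(f"strictly single-copy sets (each dinoflagellate taxon exactly once): {single_copy}")
print()
print("The specificity classes partition the query proteome; a partner column")
print("counts orthogroups containing only dinoflagellates plus that one phylum,")
print("so its counts can only shrink as the minimum set size x grows.")
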