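import random

import dendropy
import pytest

from dinoarch import simulate
from dinoarch.model import GeneTree, SupportedClade
from dinoarch.tree_sorting import (
    clade_composition,
    default_rule_table,
    extract_supported_clades,
    is_exclusive_to,
    load_rule_table,
    save_rule_table,
    sort_tree,
    sort_tree_set,
)


def make_tree(newick, tree_id="t"):
    tree = dendropy.Tree.get(
        data=newick, schema="newick", suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    leaves = tuple(l.taxon.label for l in tree.leaf_node_iter())
    return GeneTree(tree_id=tree_id, tree=tree, leaves=leaves)


def leafsets(clades):
    return {frozenset(c.leaves) for c in clades}


def test_both_sides_of_supported_edges_emitted():
    # hand-enumerated bipartitions of ((A,B)95,(C,D)98,E);
    clades = extract_supported_clades(make_tree("((A,B)95,(C,D)98,E);"), 90)
    assert leafsets(clades) == {
        frozenset("AB"),
        frozenset("CDE"),
        frozenset("CD"),
        frozenset("ABE"),
    }


def test_threshold_above_all_supports_gives_nothing():
    assert extract_supported_clades(make_tree("((A,B)95,(C,D)98,E);"), 99) == []


def test_star_tree_has_no_internal_edges():
    assert extract_supported_clades(make_tree("(A,B,C,D,E);"), 50) == []


def test_unlabelled_edge_is_support_zero():
    clades = extract_supported_clades(make_tree("((A,B),(C,D)98,E);"), 90)
    assert leafsets(clades) == {frozenset("CD"), frozenset("ABE")}


def test_clade_composition_and_exclusivity(taxon_map):
    clade = SupportedClade(
        frozenset(
            {"Cladocopium_goreaui", "Breviolum_minutum", "Chlamydomonas_reinhardtii"}
        ),
        95,
    )
    comp = clade_composition(clade, taxon_map)
    assert comp == {"Suessiales": 2, "Viridiplantae": 1}
    assert is_exclusive_to(clade, {"Dinophyceae", "Viridiplantae"}, taxon_map)
    bact = SupportedClade(frozenset({"Escherichia_coli", "Bacillus_subtilis"}), 90)
    assert is_exclusive_to(bact, {"Bacteria"}, taxon_map)
    mixed = SupportedClade(
        frozenset({"Cladocopium_goreaui", "Thalassiosira_pseudonana"}), 90
    )
    assert not is_exclusive_to(mixed, {"Dinophyceae", "Viridiplantae"}, taxon_map)


def test_default_table_structure(taxon_map):
    rules = default_rule_table(taxon_map)
    assert len({r.category for r in rules}) == 15
    assert [r.ordinal for r in rules] == list(range(1, len(rules) + 1))
    stages = [r.stage for r in rules]
    assert stages == sorted(stages)  # a-rules before b-rules before c-rules
    assert all("Dinophyceae" in r.subject_groups or r.subject_groups & {"SAR", "Alveolata"}
               for r in rules)


def test_rule_table_serialization_round_trip(taxon_map, tmp_path):
    rules = default_rule_table(taxon_map)
    p = tmp_path / "rules.yaml"
    save_rule_table(rules, p)
    assert load_rule_table(p) == rules


GREEN_TREE = "(((dino1,dino2)99,(chlamy,volvox)98)97,(bactA,bactB));"

SMALL_MAP = {
    "dino1": "Dinophyceae",
    "dino2": "Dinophyceae",
    "chlamy": "Viridiplantae",
    "volvox": "Viridiplantae",
    "bactA": "Bacteria",
    "bactB": "Bacteria",
    "perk1": "Perkinsea",
    "cili1": "Ciliophora",
    "hapto1": "Haptophyta",
    "crypto1": "Cryptophyta",
}


@pytest.fixture(scope="module")
def small_map():
    from dinoarch.taxonomy import TaxonGroupMap

    return TaxonGroupMap(taxon_to_group=dict(SMALL_MAP))


def test_green_algal_clade_sorts_to_category_G(small_map):
    rules = default_rule_table(small_map)
    out = sort_tree(make_tree(GREEN_TREE), small_map, rules, 90)
    assert out.category == "G"
    assert out.evidence.support == 97
    assert out.evidence.leaves == frozenset({"dino1", "dino2", "chlamy", "volvox"})


def test_unsupported_tree_is_unclassified(small_map):
    rules = default_rule_table(small_map)
    weak = "(((dino1,dino2)60,(chlamy,volvox)60)60,(bactA,bactB));"
    out = sort_tree(make_tree(weak), small_map, rules, 90)
    assert out.category == "unclassified"
    assert out.evidence is None


def test_alveolate_clade_sorts_to_category_B(small_map):
    rules = default_rule_table(small_map)
    tree = make_tree("((dino1,dino2)95,(perk1,cili1)92,(hapto1,crypto1)91);")
    out = sort_tree(tree, small_map, rules, 90)
    assert out.category == "B"
    assert out.evidence.leaves == frozenset({"dino1", "dino2", "perk1", "cili1"})


def test_outcome_invariant_under_rerooting_and_leaf_order(small_map):
    rules = default_rule_table(small_map)
    baseline = sort_tree(make_tree(GREEN_TREE), small_map, rules, 90)
    variants = [
        "((bactA,bactB),((chlamy,volvox)98,(dino2,dino1)99)97);",
        "(bactA,(bactB,((volvox,chlamy)98,(dino1,dino2)99)97));",
    ]
    for nwk in variants:
        out = sort_tree(make_tree(nwk), small_map, rules, 90)
        assert out.category == baseline.category
        assert out.evidence.leaves == baseline.evidence.leaves


def test_evidence_clade_satisfies_matched_rule(small_map):
    rules = default_rule_table(small_map)
    out = sort_tree(make_tree(GREEN_TREE), small_map, rules, 90)
    rule = next(r for r in rules if r.ordinal == out.rule_ordinal)
    assert rule.category == out.category
    assert is_exclusive_to(out.evidence, rule.subject_groups | rule.target_groups, small_map)
    comp = clade_composition(out.evidence, small_map)
    assert any("Dinophyceae" in small_map.chain(g) for g in comp)


def test_planted_recovery_respects_threshold(taxon_map):
    rules = default_rule_table(taxon_map)
    trees, truth = simulate.gen_trees(
        [simulate.TreeSpec(category="G", support=85)], taxon_map, seed=1
    )
    assert sort_tree(trees[0], taxon_map, rules, 90).category == "unclassified"
    assert sort_tree(trees[0], taxon_map, rules, 70).category == "G"


def test_threshold_nesting_on_random_trees(taxon_map):
    """classified(90) is a subset of classified(70) is a subset of classified(50)."""
    rng = random.Random(0)
    specs = [
        simulate.TreeSpec(
            category=rng.choice(simulate.CATEGORIES),
            support=rng.uniform(30, 100),
        )
        for _ in range(100)
    ]
    trees, _ = simulate.gen_trees(specs, taxon_map, seed=5)
    outcomes, _ = sort_tree_set(trees, taxon_map, thresholds=(90, 70, 50))
    classified = {
        thr: set(
            outcomes[(outcomes.threshold == thr) & (outcomes.category != "unclassified")].tree_id
        )
        for thr in (90, 70, 50)
    }
    assert classified[90] <= classified[70] <= classified[50]


def test_sort_tree_set_unmapped_leaf_handling(taxon_map):
    tree = make_tree("((Cladocopium_goreaui,MYSTERY_TAXON)95,(Homo_sapiens,Escherichia_coli));")
    with pytest.raises(KeyError):
        sort_tree_set([tree], taxon_map)
    outcomes, _ = sort_tree_set([tree], taxon_map, on_unmapped="drop")
    assert outcomes.empty


def test_determinism_identical_outcome_tables(taxon_map):
    specs = [simulate.TreeSpec(category=c) for c in simulate.CATEGORIES]
    trees, _ = simulate.gen_trees(specs, taxon_map, seed=2)
    out1, sum1 = sort_tree_set(trees, taxon_map)
    out2, sum2 = sort_tree_set(trees, taxon_map)
    assert out1.equals(out2) and sum1.equals(sum2)
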