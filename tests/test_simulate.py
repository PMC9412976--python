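import math

import pytest

from dinoarch import simulate
from dinoarch.architecture import (
    find_blocks,
    find_disruptors,
    interblock_regions,
    order_genes,
    region_counts,
)
from dinoarch.gc_profile import detect_dips, scaffold_background_gc, sliding_gc
from dinoarch.gene_sharing import classify_specificity, partner_counts
from dinoarch.tree_sorting import default_rule_table, sort_tree


def test_noise_free_runs_recovered_exactly():
    spec = simulate.ArchitectureSpec(
        n_scaffolds=1, genes_per_scaffold=8, block_sizes=[4, 4], disruptor_rate=0.0
    )
    ann, truth = simulate.gen_annotation(spec)
    blocks = find_blocks(order_genes(ann))
    assert [b.size for b in blocks] == [4, 4]
    assert truth["scaffolds"]["scaffold_1"]["post_flip_blocks"] == [4, 4]


def test_two_ten_gene_runs_give_one_qualifying_region():
    spec = simulate.ArchitectureSpec(
        n_scaffolds=1, genes_per_scaffold=20, block_sizes=[10, 10], disruptor_rate=0.0
    )
    ann, _ = simulate.gen_annotation(spec)
    ordered = order_genes(ann)
    regions = interblock_regions(find_blocks(ordered), ordered, n_values=(10,))
    counts = region_counts(regions, n_values=(10,))
    assert counts[(10, "converging")] + counts[(10, "diverging")] == 1


def test_annotation_deterministic_gff3_bytes():
    spec = simulate.ArchitectureSpec(seed=11)
    a = simulate.annotation_to_gff3(simulate.gen_annotation(spec)[0])
    b = simulate.annotation_to_gff3(simulate.gen_annotation(spec)[0])
    assert a == b


def test_annotation_truth_matches_analyzer():
    spec = simulate.ArchitectureSpec(seed=3, n_scaffolds=2, genes_per_scaffold=150)
    ann, truth = simulate.gen_annotation(spec)
    ordered = order_genes(ann)
    blocks = find_blocks(ordered)
    for scaffold, st in truth["scaffolds"].items():
        got = [b.size for b in blocks if b.scaffold == scaffold]
        assert got == st["post_flip_blocks"]


def test_disruptor_flips_are_exactly_the_calls():
    spec = simulate.ArchitectureSpec(
        n_scaffolds=2, genes_per_scaffold=200, block_sizes=[10], disruptor_rate=0.05, seed=9
    )
    ann, truth = simulate.gen_annotation(spec)
    ordered = order_genes(ann)
    calls = find_disruptors(ordered)
    by_scaffold = {}
    for c in calls:
        by_scaffold.setdefault(c.scaffold, set()).add(c.gene_id)
    for scaffold, st in truth["scaffolds"].items():
        genes = ordered[scaffold]
        expected = {genes[i].gene_id for i in st["flipped_indices"]}
        assert by_scaffold.get(scaffold, set()) == expected


def test_sequence_no_dip_planted_when_depth_zero():
    ann, _ = simulate.gen_annotation(simulate.ArchitectureSpec(seed=4, n_scaffolds=1))
    seqs, truth = simulate.gen_sequence(
        ann, simulate.SequenceSpec(dip_depth_pp=0.0, dip_placement=0.0, noise="exact", seed=4)
    )
    assert truth["planted_dips"] == []
    for scaffold, seq in seqs.items():
        bg = scaffold_background_gc(seq)
        assert detect_dips(sliding_gc(seq, scaffold), bg, dip_threshold_pp=2.0) == []


def test_sequence_planted_dip_detected():
    spec = simulate.ArchitectureSpec(
        n_scaffolds=1, genes_per_scaffold=24, block_sizes=[12, 12],
        disruptor_rate=0.0, gene_length_bp=(900, 1100), intergenic_bp=(400, 600), seed=5,
    )
    ann, _ = simulate.gen_annotation(spec)
    seqs, truth = simulate.gen_sequence(
        ann, simulate.SequenceSpec(dip_placement=1.0, boundary_min_n=12, seed=5)
    )
    planted = truth["planted_dips"]
    assert len(planted) in (0, 1)
    for d in planted:
        seq = seqs[d["scaffold"]]
        bg = scaffold_background_gc(seq)
        dips = detect_dips(sliding_gc(seq, d["scaffold"]), bg, dip_threshold_pp=2.0)
        assert any(x.start < d["end"] and d["start"] < x.end for x in dips)


def test_sequence_deterministic():
    ann, _ = simulate.gen_annotation(simulate.ArchitectureSpec(seed=6, n_scaffolds=1, genes_per_scaffold=40))
    s1, _ = simulate.gen_sequence(ann, simulate.SequenceSpec(seed=6))
    s2, _ = simulate.gen_sequence(ann, simulate.SequenceSpec(seed=6))
    assert s1 == s2


def test_sequence_background_gc_close_to_spec():
    ann, _ = simulate.gen_annotation(simulate.ArchitectureSpec(seed=7, n_scaffolds=1, genes_per_scaffold=100))
    seqs, _ = simulate.gen_sequence(ann, simulate.SequenceSpec(seed=7, dip_placement=0.0))
    seq = next(iter(seqs.values()))
    n = len(seq)
    se = math.sqrt(0.444 * 0.556 / n)
    assert abs(scaffold_background_gc(seq) - 0.444) < 4 * se


def test_planted_tree_sorts_to_its_category(taxon_map):
    rules = default_rule_table(taxon_map)
    trees, truth = simulate.gen_trees(
        [simulate.TreeSpec(category="G", support=95)], taxon_map, seed=8
    )
    assert sort_tree(trees[0], taxon_map, rules, 90).category == "G"


def test_confusion_matrix_diagonal_at_high_support(taxon_map):
    rules = default_rule_table(taxon_map)
    specs = [simulate.TreeSpec(category=c, support=95) for c in simulate.CATEGORIES]
    trees, truth = simulate.gen_trees(specs, taxon_map, seed=10)
    for thr in (90, 70, 50):
        for gt, t in zip(trees, truth):
            assert sort_tree(gt, taxon_map, rules, thr).category == t["category"]


def test_tree_generation_rejects_unknown_category(taxon_map):
    with pytest.raises(ValueError):
        simulate.gen_trees([simulate.TreeSpec(category="Z")], taxon_map)


def test_orthogroup_plan_realized_exactly(taxon_map, tmp_path):
    from dinoarch.io import read_orthogroups

    plan = [
        {"Cladocopium_goreaui": 2},
        {"Cladocopium_goreaui": 1, "Chlamydomonas_reinhardtii": 44},
    ]
    text, truth = simulate.gen_orthogroups(plan, taxon_map, seed=1)
    p = tmp_path / "Orthogroups.tsv"
    p.write_text(text)
    sets = read_orthogroups(p)
    assert [len(s) for s in sets] == [2, 45]
    assert truth[1]["phyla"] == ["Dinophyceae", "Viridiplantae"]

    per, counts = classify_specificity(sets, taxon_map, "Cladocopium_goreaui")
    assert counts["species_specific"] == 2
    assert counts["exclusive_two_phylum"] == 1
    # 45-member two-phylum set counts at x in {2,20,40} but not 60
    table = partner_counts(sets, taxon_map)
    assert list(table.loc["Viridiplantae"]) == [1, 1, 1, 0]


def test_orthogroup_text_deterministic(taxon_map):
    plan = [{"Cladocopium_goreaui": 1, "Emiliania_huxleyi": 3}]
    t1, _ = simulate.gen_orthogroups(plan, taxon_map, seed=2)
    t2, _ = simulate.gen_orthogroups(plan, taxon_map, seed=2)
    assert t1 == t2
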