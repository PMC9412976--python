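# Methods

`dinoarch` re-implements, as a tested and reusable library, three
analyses developed for studying dinoflagellate (Symbiodiniaceae) genome
architecture and gene origins. This note records the models, the
tunables that matter, the numerical choices, and what the synthetic-data
generator does and does not emulate.

## Gene-orientation architecture

Dinoflagellate genomes encode genes in long unidirectional runs. Blocks
whose transcription converges meet at putative boundaries of
topologically associated domains (TADs); blocks whose transcription
diverges flank putative TAD central regions.

Genes are ordered per scaffold by start coordinate (ties broken by end,
then id; overlapping genes keep the sort order — genome-browser
convention). On that order:

* **Orientation windows.** Every sliding window of `w` consecutive genes
  (default `w = 10`, step one gene) is scored by its number of adjacent
  strand changes. Scaffolds with fewer than `w` genes contribute no
  windows; windows never span scaffolds (no linkage evidence across
  scaffolds). The *conserved fraction* is the share of windows with zero
  changes, which equals `sum over blocks of max(0, size − w + 1)` divided
  by the window count — an identity the test suite uses as a closed-form
  oracle.
* **Unidirectional blocks.** Maximal same-strand runs; block sizes
  partition each scaffold's gene list. The occupancy curve reports the
  percentage of genes in blocks of at least `s` genes.
* **Inter-block regions.** One region per adjacent block pair, spanning
  from the end of the left block's last gene to the start of the right
  block's first gene (clamped to length 0 for abutting or overlapping
  flanks; such regions stay in the counts but carry no sequence to test).
  With `+` meaning transcription toward increasing coordinates, a region
  is *converging* iff the left block is `+`. A region qualifies at
  minimum block size `N` (defaults `N ∈ {4, 6, 8, 10}`) when both flanks
  hold at least `N` genes.
* **Disruptor genes.** A gene is called a disruptor iff it has two
  neighbours, they share a strand, and the gene has the opposite strand
  — equivalently, a size-1 block flanked by two blocks of one strand.
  Scaffold-terminal genes are never called.

## GC-dip detection

TAD boundaries in dinoflagellates show a dip in GC content. Per
scaffold, GC is computed in sliding windows (default 4000 bp wide,
100 bp step, fully contained; GC and denominators count unambiguous
A/C/G/T only) against the scaffold-wide background GC. Maximal runs of
consecutive below-background windows are candidate dips, kept when

1. every window of the run is below background,
2. the run's largest deviation exceeds `dip_threshold_pp` (default 0.05
   percentage points of GC — a deliberately literal, permissive default;
   it is configurable, and analyses of noisy sequence should raise it
   toward half the expected dip depth, as the shipped examples and
   acceptance script do with 2.0 pp for 5 pp dips), and
3. the dip region is longer than `min_length_bp` (default 5000 bp).

**Region extent (a deliberate numerical choice).** The reported region
is the run's bp span *eroded by one window width at each side*: from the
first below-background window's end to the last one's start. This is
exactly the set of positions covered only by below-background windows. A
4 kb averaging kernel smears any deep dip outward by up to 4 kb per
flank, so a span measured window-start-to-window-end would let a 3 kb
dip masquerade as a >10 kb region and criterion 3 could never reject
short dips; the erosion undoes the smear, making the length criterion a
property of the dip rather than of the kernel. A run shorter than twice
the window width erodes to nothing and is rejected.

Dips are detected genome-wide and then associated with converging
inter-block regions: a boundary is flagged when a dip overlaps its
interval by at least 1 bp (default), or contains its midpoint
(`mode="midpoint"`). Zero-length intervals are reported unflagged with
reason `"no sequence"`.

Step size (100 bp) is chosen so the eroded span is resolved far below
the 5000 bp criterion; halving the step can only extend a
below-background run, so refinement never loses a dip.

## Tree sorting into origin categories

Each gene tree (newick, internal-node bootstrap supports, treated as
unrooted) is scanned for *supported clades*: both sides of any internal
edge with support at or above the active threshold (90/70/50), sides of
2 to n−2 leaves. An ordered rule table assigns the first matching rule's
category:

* stage **a** — targets implicated in plastid endosymbiosis
  (Archaeplastida combinations): categories I (red+green+glaucophyte and
  other combinations), H (red+green), F (Rhodophyta), G (Viridiplantae);
* stage **b** — closely related groups expected under vertical
  inheritance: E (the SAR grouping, including its partial combinations,
  and SAR with haptophytes/cryptophytes), D (Rhizaria), C
  (Stramenopiles), B (other Alveolata), A (dinoflagellates only);
* stage **c** — remote partners indicating horizontal transfer: J
  (Haptophyta), K (Cryptophyta), L (opisthokonts), M (other eukaryotes),
  N (Bacteria), O (Archaea).

A rule matches when some supported clade (i) is exclusive to the rule's
subject and target groups (every leaf belongs to them at some level of
the NCBI-style hierarchy), (ii) contains at least one Dinophyceae leaf
and at least `min_prop_subject` (default 0.7) of the tree's
subject-group leaves, and (iii) fills every *target slot* with at least
one non-subject leaf. Slots make multi-group categories conjunctive: the
red+green rule fires only when both red and green algae sit in the
clade, and a dinoflagellate leaf can never stand in for the "Alveolata"
target of rule B. Without slot conjunction, broad rules early in the
order would swallow every narrower case. Among clades matching a rule,
the highest support wins (ties: larger clade, then lexicographic leaf
order), so outcomes are deterministic and invariant to leaf order and
rerooting (bipartitions are the unit of analysis).

Within stages a and c the subject set walks from the most inclusive
(dinoflagellates plus the rest of SAR, haptophytes and cryptophytes)
down to Dinophyceae alone, dropping the most distant lineage each step;
stage b is expressed directly against subject Dinophyceae, where the
slot semantics already encode the progression. The shipped 74-rule table
is a documented approximation of the published 176-step strategy whose
verbatim steps live in supplementary material; it serializes to editable
YAML (`save_rule_table`/`load_rule_table`) so a transcription can
replace it without code changes. Categories A–E are reported as vertical
inheritance, F–O as endosymbiotic/horizontal transfer.

Because any clade supported at 90 is supported at 70 and 50, the set of
trees classified at a stricter threshold is always a subset of those
classified at a looser one (possibly to a different category) — a
property the acceptance tests check on 500 random trees.

## Orthogroup analyses

Given an OrthoFinder-style orthogroup table and the taxon→group map,
each query-species protein is classified by the narrowest level
containing all taxa of its homologous set: query species only; order
Suessiales; class Dinophyceae; Dinophyceae plus exactly one other phylum
(the *exclusive gene-sharing partner*); or two or more non-dinoflagellate
phyla. Query proteins absent from every set are species-specific
singletons, so the classes partition the query proteome.

Partner counts tabulate, per partner phylum and minimum set size
`x ∈ {2, 20, 40, 60}`, the qualifying sets (taxa within Dinophyceae plus
that phylum, at least one member on each side, size at least `x`). `x`
counts total member sequences by default; `count_mode="taxa"` counts
distinct taxa instead, since the literature is ambiguous on this point.
Strictly single-copy selection returns sets in which every taxon of
interest occurs exactly once (`strict=False` relaxes to at-most-once).

## Synthetic data and what it does (not) show

Every generator is a pure function of its spec and one integer seed;
each derives a named stream from the seed so generators never perturb
one another.

* **Annotation** (`ArchitectureSpec`): strand runs drawn from a
  geometric distribution (default `p = 0.22`, tuned so roughly a third
  of genes sit in blocks of ten or more, matching real Symbiodiniaceae
  assemblies) or an explicit size list; runs alternate strand; default 5
  scaffolds × 200 genes, gene lengths 1–3 kb, gaps 0.2–2 kb. Disruptors
  are planted as a Binomial(n, rate) count (default rate 0.05, the same
  order as the ~8% observed in real assemblies) at positions at least
  two genes from run ends and three genes apart, so every planted flip
  is exactly one callable disruptor and the called fraction is a clean
  binomial estimate of the rate. Natural size-1 runs from the geometric
  draw are *also* legitimate disruptors; truth tables record both the
  planted flips and the post-flip expected blocks. A geometric tail
  cannot simultaneously match the real assemblies' window-conservation
  (~35%) and block-occupancy (~33%) statistics — real block sizes are
  heavier-tailed — so the defaults favour the occupancy statistic, and
  adjacent ≥10-gene block pairs are rare at desk scale (as they are,
  proportionally, in real genomes); fixtures needing guaranteed N=10
  boundaries use explicit block sizes.
* **Sequence** (`SequenceSpec`): i.i.d. per-base draws at background GC
  0.444 (the ~44.4% of the emulated genomes), with 8 kb, 5 pp-deep dip
  segments centred on the midpoints of 68% of qualifying converging
  boundaries (the flagged fraction seen in real data). `noise="exact"`
  replaces sampling with error-diffusion placement whose every window
  matches its target GC to one base — the noise-free fixtures on which
  recovery is asserted at 100%. Under i.i.d. noise a 4 kb window has
  ~0.8 pp GC standard deviation, so region boundaries blur and the
  100% claims are asserted only noise-free.
* **Trees** (`TreeSpec`): one flat, strongly supported planted clade per
  tree holding all dinoflagellate leaves plus the category's partner
  taxa, with remaining taxa attached at the root. No substitution-model
  realism and no internal clade structure: the planted edge is the only
  supported bipartition, which makes recovery a sharp function of the
  support/threshold pair.
* **Orthogroups**: an explicit composition plan realized exactly.

Passing tests on these fixtures demonstrates the *logic* of each stage
(definitions, thresholds, counting, ordering) and calibrated recovery
under simple noise. They do not demonstrate robustness to real-data
phenomena the generators omit: fragmented assemblies, unresolved or
conflicting tree topologies, paralog-rich clades, compositional
heterogeneity along scaffolds, or annotation error.

## Problem sizes

Defaults keep every analysis desk-scale: 1000-gene annotations, ~3 Mb of
sequence, hundreds of trees with ~10–20 leaves. All operations are
linear or near-linear in their input (window scans use prefix sums;
sorting a tree enumerates its internal edges once per rule), so the same
code runs genome-scale inputs (tens of thousands of genes, gigabase
FASTA) without algorithmic changes.
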