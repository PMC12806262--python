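# Methods

This note documents the models and numerical choices behind each stage,
what the simulator does and does not emulate, and the known limitations.

## Clade simulator

The simulator builds an ancestral genome of `n_chromosomes` chromosomes,
each an alternation of intergenic spacers (`intergenic_bp`, default
3,000 bp) and genes (`gene_length_bp`, default 600 bp; random coding
strand), and evolves it root→leaves along a rooted tree. Branch lengths
are in expected substitutions per site. Trees are user-supplied Newick or
random pure-birth (Yule, unit birth rate) scaled to `tree_depth`; random
trees are ultrametric, so node ages are meaningful truth for dating tests.

Per-branch events, in a fixed application order (losses, gains,
duplications, inversions, fissions, fusions, translocations, SVs,
substitutions), with counts drawn Poisson:

* **gene gain/loss** (rates per branch-length unit). A gain creates a new
  single-member family, so genome-specific genes arise exactly as the
  frequency-1 occupancy class; duplication is a separate rate, default 0.
* **rearrangements** (rates per branch). Inversions reverse a run of
  segments (flipping strand and reverse-complementing); fissions and
  translocations are constrained to leave at least one gene on every
  resulting chromosome so that every chromosome stays visible in marker
  space.
* **structural variants** (per-type rates per branch; sizes uniform in
  `sv_size_range`, floor 50 bp to match the caller's default minimum).
  SVs are placed in ancestrally tagged intergenic sequence, ≥100 bp from
  segment edges, and a clade-global exclusion list keeps planted events
  ≥200 bp apart on the ancestor so that events on different branches stay
  separable in every pairwise comparison. Hotspot intervals multiply the
  per-segment placement weight. Tandem expansions are realised as true
  adjacent duplications (the copy keeps its ancestral tag); contractions
  and repeat-class events are realised as sequence indels whose
  repeat-specific alignment signatures are reconstructed by the synthetic
  aligner (below). Upstream regions of promoter-deletion target genes are
  reserved, and the target families are protected from gene loss, so the
  planted promoter indel is the only event in those promoters.
* **substitutions** follow Jukes–Cantor: a site changes with probability
  `3/4·(1 − e^(−4μ/3))` for branch amount μ and moves uniformly to one of
  the other three bases, matching the JC correction used downstream.

Every segment carries its ancestral interval, so the realised homology is
exact. Coordinates in truth tables are 0-based half-open on the ancestor;
GFF3 output is 1-based inclusive. Gene identifiers in FASTA/GFF3 are
opaque (`<genome>_g00001`); family membership lives only in the truth
tables. A fixed seed makes all outputs byte-identical.

What the simulator does **not** emulate: repetitive sequence content and
TE landscapes, assembly and annotation error, alignment noise (anchors are
exact projections of shared ancestry; substitutions never break anchors),
coding indels, incomplete lineage sorting, and gene-order convergence.
Passing tests therefore demonstrate algorithmic correctness against the
generating model, not robustness to real assembly artefacts.

## Synthetic alignments

For simulated genomes, PAF anchors are produced by intersecting the two
segment maps through ancestor coordinates — no external aligner is needed.
Two aligner behaviours around repeats are reproduced explicitly, because a
gap-based SV classifier depends on them: flanking alignments extend a few
bases (8 bp, below the ±10 bp breakpoint tolerance used in evaluation)
into the remaining copy of a contracted tandem, producing the
query-overlap signature; and the flanks of repeat-borne events multi-map
to the repeat's source locus, emitted as one secondary (mapq 0) record per
event.

## Pan-genome

Families are k-mer Jaccard clusters: nucleotide k = 8, similarity ≥ 0.5,
single-linkage connected components (both config-exposed). Two genes with
pairwise identity p share ≈ (1−p)^8 of their 8-mers, so direct links
survive to p ≈ 0.05; beyond that, single linkage must chain through
intermediate genomes. The default simulation settings (substitution rate
0.02–0.05, tree depth ≤ 1) stay within that envelope. Occupancy classes
are strict: core = all n genomes, specific = exactly 1, no softcore.
Accumulation curves use 100 seeded orderings by default, or exhaustive
enumeration when requested (refused above 10,000 orderings). Genome
clustering is average linkage on Jaccard distance between PAV columns,
with genomes pre-sorted lexicographically so distance ties resolve
deterministically. Term enrichment is the one-sided hypergeometric test
with Benjamini–Hochberg FDR; term assignments are user input.

## Synteny and markers

Anchors are families single-copy in both genomes, in gene-rank
coordinates (the simulator controls order exactly, and rearrangement
inference needs order, not bp). Chaining extracts the longest
strictly monotone chain per chromosome pair (O(n²) DP), greedily and
repeatedly, with `max_gap` = 25 ranks and `min_anchors` = 5. Chains are
orientation-consistent: forward chains may only use anchors whose strands
agree in the two genomes, reverse chains only flipped ones — without this
a forward chain can tunnel diagonally through an inverted segment and
absorb it. "Disordered" blocks are those off the dominant chromosome
pairing (the partner receiving the most anchors; ties to the smaller id,
logged). The published 13-block count between two specific cotton species
depends on the real assemblies and is motivation, not a target.

Marker genomes are maximal runs of universally single-copy families whose
adjacency and relative orientation are conserved in *every* genome, taken
in pivot order; each genome is then a signed permutation of the same
marker universe. For truth evaluation the ancestor is included when
building the marker universe (this only refines block boundaries; the
ancestor's order is never shown to the median solver).

## Ancestor inference

Candidate adjacencies are weighted by observation count (an optional mode
would weight by branch length; unweighted counts are the default since the
objective's weighting is a free choice). A maximum-weight matching over
extremities (networkx blossom algorithm; ties broken by a small
lexicographic-rank perturbation, ε < 1/(4·edges)) selects the ancestral
adjacency set; matched paths become CARs and cycles are opened at their
lightest adjacency. The matching solution is then polished by a greedy DCJ
hill-climb on total distance to the inputs, restricted to linear genomes
and multi-started from the matching result and from every input genome —
which also guarantees the median is never worse than any leaf. On random
3-genome instances with ≤5 blocks this reaches the exhaustive optimum in
all tested cases.

The genome median targets the common ancestor of genomes *radiating* from
it; on a nested (ladder-like) tree the root median is genuinely
underdetermined (adjacencies changed on an internal branch are carried by
half the leaves), so ancestral-adjacency recovery is evaluated on star
clades and is expectedly lower in the nested demo.

DCJ distance is the standard `N − (C + I/2)` on the two-genome adjacency
graph. Fission/fusion counts are chromosome-count differences restricted
to shared block content, and the inversion count is the minimum number of
sign disagreements after per-chromosome orientation — both documented
lower-bound estimators, since compound events are not decomposed.

## SV calling and hotspots

Classification follows the six-class gap scheme (insertion, deletion,
tandem expansion/contraction, repeat expansion/contraction) on consecutive
primary anchors of a (query chromosome, reference chromosome, strand)
chain, size `|dq − dr|` filtered to 50–10,000 bp (config-exposed).
Primary-chain selection takes confidently mapped records first (mapq > 0)
and longest first, dropping candidates that overlap a kept anchor by more
than half their own length. Multi-mapping is flagged per anchor *end*: an
overlap exceeding 10% of the shorter record marks the anchor ends it
touches, and a gap routes to the repeat classes when a gap-facing end is
marked. Flagging whole records instead would let one repeat-borne event
mistype its neighbour's gap across a shared flank anchor.

Hotspots: one breakpoint per SV (its reference start, avoiding
double-counting large events), tiling windows (1 Mb by default; tests and
the demo use 20–50 kb to match simulated chromosome sizes), a
per-chromosome uniform permutation null preserving per-chromosome counts,
empirical p = (1 + #{perm ≥ obs})/(1 + n_perm), BH across all windows, and
merging of significant windows that touch. With ~40 windows and n_perm a
few hundred, the smallest attainable q is ≈ n_windows/(n_perm·rank); the
50-kb default in tests keeps a 10× planted hotspot several permutation
floors below α. Pooling calls across many queries re-counts SVs inherited
from internal branches at identical positions; that is genuine signal of
uneven SV distribution but dilutes planted-hotspot contrast in the demo.

## Phylogeny and dating

Per-family p-distances (Hamming for equal-length pairs, global alignment
with match +1 / mismatch −1 / gap −2 otherwise) are combined as the
length-weighted mean — exactly the concatenated-alignment p — then
JC-corrected, `d = −(3/4)·ln(1 − 4p/3)`, with a configured ceiling (5.0)
when p ≥ 0.75. The tree is neighbor joining with negative branch lengths
clamped to zero and Q-criterion ties broken on sorted pair names, rooted
at the midpoint of the outgroup edge; on additive matrices the unrooted
topology and path lengths are exact. ML tree search is deliberately not
implemented: topology and ages are the tested properties, and distance NJ
is consistent for them at this divergence scale.

Calibration scales mean root-to-leaf depths so one node matches a given
age; leaves sit at age 0, making the result exactly ultrametric, and a
child is clamped to its parent's age when mean depths invert. Because the
root is placed at the outgroup-edge midpoint (its true position on that
edge is unidentifiable from distances alone), age evaluation calibrates at
the ingroup crown, whose depth does not depend on the cut point.

## Promoter scan

Affine-gap global alignment (match +2, mismatch −3, open −5, extend −1,
config-exposed) favours one long gap over scattered short ones. Maximal
gap runs ≥ `min_indel` (default 50 bp) are reported with exact length and
reference offset; same-type runs separated by < 10 aligned columns merge,
absorbing alignment ambiguity around repeats. Flanking identity is the
percent identity of the ±100 aligned bp around the gap.

## Pipeline

Stages run in dependency order from one JSON config; the report (pydantic
model, serialised with a bundled JSON Schema) contains no timestamps or
absolute paths, so identical config + seed gives byte-identical reports,
and a cached report with a matching config checksum is reused unless
forced. The demo clade is 8 genomes (two cultivated-like species, a
five-species wild-like clade, an outgroup) of 3 × ~107 kb chromosomes
with all event classes planted, including a 444-bp promoter deletion in
the two wild-like sister species — sized so the full run takes seconds.
Problem sizes throughout the test-suite experiments (genome sizes, seed
counts, permutation depths) were chosen once to give stable statistics at
desk scale.

## Known limitations

* Family clustering has no alignment fallback; at divergence beyond the
  8-mer envelope families fragment rather than merge incorrectly.
* The synthetic aligner models no spurious anchors beyond the repeat
  signatures it plants; SV precision on real alignments will be lower.
* Fission/fusion and inversion counts are lower bounds, not parsimony
  scenarios.
* Hotspot detection assumes a uniform within-chromosome null; real
  covariates (gene density, recombination) are user-level concerns.
* The promoter scanner reports indels relative to one reference sequence
  and does not build a multiple alignment.
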