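# Methods

This note records the models, algorithms, defaults and numerical choices
behind each stage, what the simulator does and does not emulate, and the
known limitations.

## Coordinates and gene ranks

Gene coordinates are stored 1-based inclusive (GFF3 native). All synteny
computation runs in *rank* space: the 0-based index of a gene along its
chromosome after sorting by start coordinate, with ties broken by gene id.
Gene order, not physical distance, is what collinearity dot plots show, and
rank space makes gap parameters independent of gene density. Strand is
stored but ignored by chaining; inversions surface as anti-diagonal
(inverted) blocks. Either `gene` or `mRNA` rows of a GFF3 can define gene
order (configurable, default `gene`).

## NG86 Ka/Ks

For codon-aligned pairs, synonymous (S) and nonsynonymous (N) site counts
follow Nei–Gojobori (1986) under the standard nuclear genetic code: each
codon position contributes (synonymous single-nucleotide changes)/3, so
s + n = 3 per codon exactly; changes to stop codons count as
nonsynonymous. Sites are averaged over the two sequences. Observed
differences are averaged over all k! orderings of the k changed positions;
orderings passing through a stop codon are excluded from the average, and
if every ordering does, all are retained with equal weight (NG86 leaves
this case open; the fallback keeps the count total equal to the Hamming
distance). Pathways are weighted equally — transition/transversion
weighting would be a different model. Proportions ps = Sd/S and pn = Nd/N
are corrected for multiple hits with Jukes–Cantor,
d = −(3/4)·ln(1 − (4/3)p), undefined when p ≥ 3/4. Undefined Ks/Ka are
returned as flagged values with a reason code (`ks_saturated`,
`no_synonymous_sites`, …), never silently dropped; filtering happens only
when a Ks sample is built. Codons containing gaps, ambiguity codes or
stops in either sequence are removed pairwise before counting — standard
practice for this estimator. Maximum-likelihood codon models (GY94, YN00)
and gamma rate variation are out of scope.

## Synteny chaining

Anchors (homolog pairs with both genes placed) are grouped per chromosome
pair and chained by O(n²) dynamic programming: a chain is strictly
increasing in rank on side a and strictly monotone on side b (increasing =
collinear, decreasing = inverted), with consecutive anchors at most
`max_gap` ranks apart on both axes. Non-overlapping chains are extracted
greedily in descending anchor count, with a positional tie-break
((chrom_a, min rank_a, chrom_b, min rank_b), collinear before inverted),
so output is deterministic; each anchor belongs to at most one block.
Defaults `max_gap = 25` and `min_block_size = 5` are the conventional
MCScan-family settings. The DP is exact for the single best chain, which
the test suite verifies against exhaustive subset search on small
instances.

For within-genome (self) synteny, each unordered pair is oriented by
(chrom, rank); trivial self-matches are removed, and same-chromosome
blocks whose anchors all sit within `max(min_block_size, 10)` ranks of the
main diagonal are suppressed: runs of tandem/proximal duplicates are
small-scale duplications by definition and must not pose as WGD
paralogons. Homology search itself (BLAST/DIAMOND) is upstream and out of
scope — pair lists are inputs.

Syntenic depth counts, for every gene, the blocks whose anchor span on
that gene's chromosome covers its rank; the summary statistic is the modal
nonzero depth. One extra WGD in the query shows as modal depth 2 seen from
the comparator and 1 seen from the query (2:1).

## Duplicate-mode classification

Within-genome homolog pairs get exactly one mode with precedence
wgd > tandem > proximal > dispersed: *wgd* if the pair is an anchor of a
self-synteny block; *tandem* if same-chromosome and rank-adjacent, or
separated only by members of the same homolog family (families are
connected components of the pair graph; a strict adjacency-only flag is
available); *proximal* if the rank distance is ≤ 10 (the DupGen_finder
default window); otherwise *dispersed*. Transposed duplicates, which
require an outgroup genome to recognise, are not separated and fall into
dispersed.

## Ks distributions, peaks, correction, dating

Ks is positive and right-skewed, so all density machinery runs on log-Ks.
Samples are filtered to (0.01, 3.0) by default — excluding near-zero
allelic pairs and saturated estimates — with the dropped count logged.
Peaks are located either by Gaussian KDE (Silverman bandwidth, argmax on a
512-point grid spanning the data ±3 SD) or by Gaussian mixtures with
k = 1..4 components fitted by EM (3 seeded initialisations each), the
model chosen by BIC and the peak taken as exp(mean) of the heaviest
component. The mode — not the mean or median — is the peak statistic.
Samples under 50 values fall back from GMM to KDE with a warning. Each
anchor pair contributes one Ks value; no gene-family node weighting is
applied.

Rate correction: two lineages that split from a common reference at the
same time must show the same divergence Ks on a common scale, so
C = (reference split peak) / (other lineage's split peak) and the other
lineage's within-genome Ks values are multiplied by C. Dating uses
Ks = 2rt: a calibration (Ks_cal, T_cal) gives r = Ks_cal/(2 T_cal) and an
event peak dates to t = peak·T_cal/Ks_cal — linear in the peak by
construction. With the 0.781/118-MY calibration the 0.425 event peak dates
to 64.2 MY; published accounts of the same arithmetic round to ~63 MY, a
~2% presentation difference the package does not attempt to reproduce.
Peak-significance testing (SiZer-style) and absolute-rate models are out
of scope.

## Gene-tree topology classification

Species are parsed from tip labels as the prefix before a delimiter
(default `_`, configurable). Trees are rooted on the edge separating all
outgroup tips from all ingroup tips; an outgroup that cannot form a clade
under any rooting makes the call `other`. With exactly two focal tips, let
M be their MRCA: `independent` if M's subtree contains only focal-species
tips; `shared` if exactly two child subtrees of M contain a focal tip and
each of those also contains a partner-species tip (any one partner species
suffices when several are supplied); anything else — polytomies that leave
the duplication node ambiguous, partner tips on one side only, missing
outgroup — is `other`. Branch lengths are ignored: the call is purely
topological. Summaries report shared/independent/other counts, their
percentages of the total, and shared/(shared+independent). Tree inference
itself (alignment, FastTree), bootstrap filtering and full
duplication-loss reconciliation are out of scope; trees are inputs.

## Karyotype reconstruction

Self-synteny blocks with ≥ 5 anchors ("large fragments") contribute their
two rank intervals as segments (intervals on one chromosome overlapping by
more than 50% are merged) joined by edges weighted with anchor counts.
Maximum-weight matching pairs segments into *tiles* — one per surviving
duplicated ancestral fragment. Tiles adjacent on a chromosome are merged
into one ancestral linkage group when the junction looks like the scar of
a post-WGD fission; the ancestral chromosome count is the number of
resulting groups, and the event ledger is validated against
n_extant = 2·n_ancestral + fissions − fusions.

The delicate point is that, from a single genome, a fission junction and a
fusion seam are topologically dual: both present two tiles side by side
whose partners are elsewhere. The package breaks the tie with segment
sizes under an equal-ancestral-size assumption. Each tile's *ancestral
extent* is the gene count of its fuller copy (duplicate deletion thins one
copy, so the longer segment estimates the ancestral span). Two adjacent
tiles merge when (a) their partner segments lie on one and the same
chromosome (then the adjacency is just one duplicated region fragmented
by inversions or retention gaps), or (b) both partners are pure
single-segment chromosomes — as fission products are — *and* the two
extents sum to at most 1.25× the typical tile extent (75th percentile), as
complementary halves of one ancestral chromosome must; fusion seams join
≥ ~1.5 ancestral units and fail the size test. This is a deliberate
heuristic, not an ancestral-genome reconstruction in the
ANGES/DESCHRAMBLER sense: the recovery tests (exact on clean doubled
genomes; within ±1 of the true count on histories with 3 fissions +
6 fusions at retention ≥ 0.5) define its contract. A fusion of two
fission *halves* from different ancestral chromosomes remains genuinely
unresolvable from one genome and would be miscounted.

## The simulator

`SimulationPlan` defaults encode the study conditions the pipeline is
meant to detect: 9 ancestral chromosomes × 200 genes; one WGD; duplicate
retention 0.5 per gene (the regime in which the depth and karyotype
contracts are stated; retention is a free parameter down to sparse
regimes); paralog Ks lognormal around a peak at 0.425 (σ = 0.2 on the log
scale, matching the visual width of empirical WGD peaks); small-scale
(tandem/proximal/dispersed, 30 pairs each) background Ks exponential with
rate 1; 3 fissions, 6 fusions, 2 inversions applied after the WGD
(rearrangement-after-duplication ordering), preferring chromosomes not
already hit so the event ledger stays interpretable; outgroup divergence
Ks 0.781; shared-topology fraction 0.685. Copy "a" of each chromosome is
kept complete and copy "b" is thinned — the common fate of most genes
returning to single copy — so retained-pair counts are Binomial(1800,
retention). Gene lengths are fixed (300 codons) and spacing uniform.
A lognormal WGD component over an exponential small-scale background is
the standard shape assumption for Ks mixtures.

Sequence pairs for estimator tests are generated by JC-inverting target
distances into difference proportions (p = (3/4)(1 − e^(−4d/3))) and
mutating each codon position synonymously with probability ps × (its
synonymous site fraction) and nonsynonymously with pn × (the complement),
never through stop codons, which makes the downstream NG86 counting
unbiased in expectation. Simulated gene trees are the two canonical
4–5-tip shapes with an optional tip-swap noise rate.

Everything is driven by one integer seed; identical plans give
byte-identical outputs, and every emitted file round-trips through the
package's own readers.

What the simulator does **not** emulate: real intergenic sequence and
transposable elements, codon-usage bias, gene-length variation,
lineage-specific gene families, gene conversion between paralogs,
incomplete lineage sorting in gene trees, and assembly/annotation error.
Passing tests therefore demonstrate correctness of the inference machinery
under the model's assumptions, not robustness to every artefact of real
genome data.

## Problem sizes and determinism

Tests and the acceptance script run at desk scale — genomes of ~1800
ancestral genes, Ks samples of ~1000–2000 values, 1000 trees, 200 codon
pairs × 300 codons — sizes at which every statistical contract above is
already sharp. All stochastic components take explicit seeds (numpy
`default_rng`, seeded GMM initialisation), and the end-to-end report is
hash-stable for a fixed config and seed. Genome-scale quantities reported
for real assemblies (thousands of blocks, tens of thousands of anchors)
require the real genomes, which the package deliberately does not
download; its contracts are stated on simulated histories instead.
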