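# Methods

`plastcomp` re-implements, as one tested pipeline, the comparative analysis
typically run on a pair of closely related chloroplast genomes (plastomes):
a cultivated reference and a wild relative, ~120 kb each, identical in gene
content and differing by scattered substitutions, short intergenic indels,
and possibly the orientation of one large collinear block. This note
records the models, parameter choices and numerical conventions, and what
the synthetic benchmark does and does not demonstrate.

## Collinear alignment and variant extraction

The two genomes are assumed collinear after at most one round of block
reorientation — the situation in IRLC legume plastome pairs, where
assembly haplotypes differ only in the orientation of single-copy regions.
No rearrangement graph is built.

* **Anchors.** k-mers (k = 21, odd so no k-mer is its own reverse
  complement) that occur exactly once in each genome, counting both
  strands, seed maximal exact matches. Seeds merge along diagonals and are
  extended until the first mismatch.
* **Orientation.** Contiguous groups of minus-strand anchors define query
  intervals to reverse-complement. Boundaries are taken from the abutting
  plus-strand anchor extents: at a true breakpoint both orientations match
  inside the overlap of the two extents, so any cut inside it is exact.
  Anchors are recomputed on the reoriented query; residual minus-strand
  structure is an error (the pair is not collinear under one round).
* **Chaining.** Maximum-weight (total anchor length) chain, monotone in
  both genomes; ties prefer the leftmost reference position.
* **Gap alignment.** Inter-anchor segments up to 20 kb are aligned
  globally (Biopython `PairwiseAligner`) with match +1, mismatch −1, gap
  open −4, gap extend −1 (a length-L gap costs −4 − L). Larger segments
  are recorded as unaligned. The scores are not prescribed by any upstream
  tool; they are fixed here and exposed in the configuration.
* **Variants.** One SNV per mismatch column; runs of gap columns merge
  into indels, which are left-aligned on the reference (shift while the
  base preceding the event equals its last base). Columns containing N are
  excluded. For indels, `ref_pos` is the base to the left of the event.

## Sliding-window divergence and hotspots

Percent dissimilarity is computed on reference coordinates in 1000-bp
windows stepped by 200 bp; only full windows are emitted, so a reference
of length L yields `floor((L − 1000)/200) + 1` windows (122,855 bp → 610).
The denominator of a window is its comparable columns: aligned columns
minus masked, N and unaligned ones. The numerator counts SNV columns plus
indel columns, each gap column once; insertion columns, which own no
reference coordinate, are attributed to the reference position immediately
left of the event. This convention (indels counted on both sides of the
ratio) keeps the statistic sensitive to the indel-rich noncoding
divergence typical of these genome pairs; `--snv-only` computes the
substitution-only alternative. Masking uses the package's own long-repeat
finder: the union of both copies of every repeat ≥ 30 bp.

Windows with dissimilarity strictly greater than 1.0 % merge into
hotspots; fully masked windows are undefined and never qualify. Each
hotspot is annotated with its containing feature or, as windows overlap
flank-gene edges because of the 200-bp quantization, with the last gene
starting at or before the hotspot and the first ending at or after it.

## Variant effects

Coding SNVs are classified with the bacterial/plastid genetic code
(translation table 11) by translating the reference and mutated codons of
the strand-corrected, spliced CDS; minus-strand alternates are
complemented first. Nonsynonymous changes carry `ref-AA codon-index
alt-AA` notation (e.g. `H447Y`). CDS membership is decided on spliced
coordinates; positions inside a gene span but outside all parts are
intronic; everything else is intergenic with flanks in genome order.
Coding indels are flagged `coding-indel` without frame analysis, and
start/stop-codon variants are classified by the same codon-compare rule
with a context flag. Per-gene summaries order notations by codon index
and satisfy `n_total = n_syn + n_nonsyn` by construction.

## Repeats

* **SSRs** follow MISA semantics: maximal runs of a primitive 1–6 bp unit
  with copy thresholds 10/5/4/3/3/3 by unit length; a run is reported only
  at its true period, and the reported span covers full copies. The class
  label is the lexicographically smallest rotation over the motif and its
  reverse complement, printed `X/revcomp(X)`. Compound-SSR merging is not
  implemented; each run is a separate record.
* **Long repeats** are maximal pairs in four orientation classes
  (forward, reverse, palindromic, complement) with ≥ 30 bp, Hamming
  distance ≤ 3 and identity strictly above 90 % (so 30 bp with 3
  mismatches does not qualify). Maximality means no extension stays within
  the budget; reported windows begin and end on matching positions, and
  a pair contained in a longer same-class pair is suppressed. Detection is
  seed-and-extend: exact k-words with k = ceil((30−3)/4) = 7, which by
  pigeonhole occur in every qualifying window, joined vectorially and
  verified by a windowed mismatch scan, so detection is complete. A
  `--top N` cap per orientation exists for comparison with tools that
  truncate their output. E-value ranking is not reproduced.
* **Tandem repeats** use a deliberately simplified period-autocorrelation
  detector (period ≥ 7 so SSRs are never double-counted, ≥ 2 copies,
  ≥ 24 bp, ~10 % mismatch tolerance with a three-consecutive-mismatch
  stop). It is a labeled stand-in for full Tandem Repeat Finder
  heuristics; its counts are not comparable to that tool's.

## Codon usage and expression

RSCU is the observed codon count scaled by family size over the family
total; family sums therefore equal family sizes, and the single-codon
families (ATG, TGG) are identically 1. MILC follows the published
formulation: `MILC = (Σ_a M_a)/L − C` with
`M_a = 2 Σ_{c∈a} o_c ln(f_c/g_c)`, f the gene's within-family frequencies,
g the reference's, L the gene's codon total, and
`C = (Σ_a (r_a − 1))/L − 0.5` summed over families present in the gene.
Only the distance term is exactly invariant under uniform scaling of
counts; C is the intended length correction. Stop codons are counted in
codon totals (both totals, with and without stops, are reported) but
excluded from MILC families. MELP is
`MILC(gene | genome) / MILC(gene | ribosomal)`, the ribosomal reference
being the pooled usage of all `rps*`/`rpl*` genes. A zero reference
frequency where the gene has observations is floored at 1e-9 rather than
returning an infinite distance; this arises only with degenerate
references. FPKM is `count / (length/10³) / (total_mapped/10⁶)`. The
bias–expression report regresses preferred-codon fraction (share of
codons with genome-level RSCU > 1) on MELP, computes the Spearman
correlation of MELP with log₁₀(FPKM), and tabulates mean FPKM over the
functional categories {ATP synthase, rubisco, photosystem, NADH
dehydrogenase, cytochrome, ribosomal, RNA polymerase, other}, assigned by
gene-name prefix and overridable via a category map.

## Phylogeny

The multiple alignment is consumed, not computed. Distances use the JC69
closed form `d = −(3/4) ln(1 − 4p/3)` with pairwise deletion of gap/N
columns; p ≥ 0.75 is flagged saturated (infinite). Likelihoods use
Felsenstein pruning with JC transition probabilities, uniform base
frequencies, missing-data marginalization for gaps/N, and site-pattern
compression. Branch-length optimization exploits that, under JC, each
site likelihood is linear in `e^(−4t/3)` for one branch with the others
fixed: two full-tree evaluations per branch feed a bounded 1-D search
(branch lengths in [1e-9, 10]; cyclic passes stop when the log-likelihood
improves by less than 1e-6, at most 50 passes). Up to 7 taxa the ML
search enumerates all unrooted topologies (ties broken by enumeration
order); beyond that it refines a neighbor-joining start by
nearest-neighbor-interchange hill climbing. Neighbor joining is the
canonical Q-criterion algorithm with ties broken by taxon name and
negative branch estimates clamped to zero. Bootstrap support resamples
columns with replacement and reports the percentage of replicates
containing each internal bipartition; replicates can be analyzed by ML or
(much faster) NJ. No Bayesian analysis is implemented.

## Synthetic benchmark

The generator emulates the study system: by default an 80 kb genome with
40 protein-coding ORFs (300–1500 bp, valid start/stop, real plastome gene
symbols so ribosomal and functional categories exist), three tRNA and two
rRNA loci, mildly AT-biased intergenic spacers (GC about 0.28 against a
genome-wide 0.36), planted SSR arrays covering unit lengths 1–6, and one
planted long repeat per orientation class. The derived genome carries 200
coding substitutions with a 30 % nonsynonymous fraction (chosen against
the codon table, never creating stops, at most one per codon), 20
intergenic indels of 1–20 bp, and optionally one large block inversion
with breakpoints in clear intergenic sequence. All randomness flows from
one integer seed through per-stage streams.

Planted elements are spaced so each finder should report each plant
exactly once with exact coordinates; in particular, repeat plants get
enough forced flanking mismatches that budget extension stops exactly at
the planted interval. Intergenic background remains random, so incidental
SSRs or repeats can occur — finder correctness is therefore established
against exhaustive oracles (primitive-run scan, per-diagonal quadratic
scan, whole-CDS translate-and-compare, brute-force likelihood sums), not
only against the plant list. Expression levels are log-uniform over three
decades and coupled to a codon-bias mixture weight (ribosomal genes
forced to the biased end); counts are negative-binomial around
level × length with dispersion 0.2 by default.

What passing these tests does **not** show about real data: the generator
has no IR expansion/contraction, no rearrangements beyond one inversion,
no sequencing error or coverage structure, i.i.d. sites without rate
heterogeneity in the alignment simulator, and gene-name-based categories
that real annotations may not match.

## Problem sizes

The test suite runs the planted-recovery condition at 20 seeded 80-kb
pairs, oracle equivalence at 200×2 kb (SSR), 20×5 kb (long repeats) and
50 CDSs × 2700 changes (classifier), and topology recovery at 40
replicates of 10 kb. `scripts/acceptance.py` recomputes the same
quantities at moderately smaller replicate counts (8 pairs, 60/8
sequences, 10 CDSs, 20 ML replicates, 50 bias–expression runs), a size
chosen to keep a full from-scratch rerun around one minute while leaving
every rate estimable; the `n` field of each reported value records the
size actually used.

## Known limitations

Anchor uniqueness breaks down inside genuinely duplicated sequence longer
than the inter-anchor spacing; variant calls inside unaligned (> 20 kb)
gaps are not attempted; the collinearity assumption is one block
reorientation, not general rearrangement; MILC needs every family of the
gene present in the reference to avoid the frequency floor; and the ML
search beyond 7 taxa is a local NNI optimum, not a global one.
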