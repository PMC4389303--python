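# Methods

This note documents the models, algorithms, defaults and design
choices behind `plastomekit`, and what the synthetic-data tests do and
do not demonstrate about real data.

## The genome model

A plastome is modelled as a circular DNA string with a quadripartite
layout: large single-copy region (LSC), inverted repeat B (IRb), small
single-copy region (SSC), inverted repeat A (IRa), where IRa is the
exact reverse complement of IRb. Coordinates are 0-based half-open;
the canonical origin is the first LSC base and the canonical order is
LSC, IRb, SSC, IRa. Circularity is handled by explicit wrap-around
arithmetic; sequence doubling appears only inside search routines.

### Synthetic genomes

`PlastomeSpec` defaults (LSC 81.0 kb, SSC 12.9 kb, IR 21.8 kb, 61 %
AT) sit mid-range of published bamboo plastomes (LSC 79.5–83.3 kb,
SSC 12.4–13.7 kb, IR 19.8–25.0 kb, total 135–144 kb); batteries that
need population-level variation draw each region length uniformly from
those ranges. Bases are i.i.d. with P(A)=P(T)=AT/2, so the realised
AT fraction of a 140 kb genome is within ±0.15 % of the knob
(binomial concentration), satisfying the ±1 % contract with margin.

Annotations come from a packaged, ordered list of 80 canonical grass
plastid genes (54 LSC, 14 IR, 12 SSC, with fixed typical lengths and
strands; IR genes are mirrored into IRa). The order is idealised so
that field-named spacers — *rpl23–ndhB* in the IR, *rps16–trnQ* and
*trnD–psbM* in the LSC — are real adjacencies. Genes are laid out in
order with a 100 bp minimum spacer plus a multinomial split of the
remaining slack; because the multinomial concentrates, every spacer is
comfortably sized in practice. A spec whose genes cannot fit raises
`InfeasibleSpecError`. Gene *footprints* are annotation intervals
over the random background (no codon structure is simulated); this is
sufficient for every consumer in the package, which treats features as
coordinates, not biology.

Two boundary bases are adjusted so the IR pair is *non-extensible*
(the flanking base pairs cannot chance-complement); this makes the
planted IR intervals exactly the maximal inverted-repeat pair of the
circle, so structure detection can be tested for exact equality.

### Planted variants

`plant_variants` applies insertions (random payload at a configurable
AT fraction, default 55 %, or an explicit payload), deletions, and
inversions (optionally bracketed by a degenerate motif planted
literally upstream with its reverse complement downstream; the
recorded inversion interval excludes the flanks). Insertions inside
an IR are mirrored into the other copy, preserving the IR identity
invariant; each copy gets its own truth record. Truth records carry
exact post-edit coordinates plus the pre-edit interval. Indel
placement on a random background is ambiguous when junction bases
repeat; `left_align_indel` normalises any record to its left-most
representation (VCF-style), and recovery comparisons are made on
normalised records.

### Reads and contigs

Reads are drawn uniformly from the circle (wrap-around), strand
random, with i.i.d. substitution errors (capped at 5 %) and constant
high-quality strings — read QC is explicitly out of scope, as are
indel errors and GC-dependent coverage bias beyond the single
AT-fraction knob. Paired-end fragments use a normal insert size
(default 500 ± 50 bp) in FR orientation. Read count is
coverage·G/read_len rounded. `fragment_plastome` breaks the circle
either at the four single-copy/IR junctions (where de Bruijn
assemblers stop) or at k random positions; contigs partition the
circle with an optional declared overlap.

## Finishing

`scaffold_contigs` places each contig by the modal diagonal of k-mers
(default k = 25) unique both in the contig and per strand on the
reference circle; the strand with more anchor support wins, ties
prefer '+'. This degenerates gracefully for IR-derived contigs: a
forward k-mer inside IRb occurs once on the forward strand even though
its reverse complement occurs in IRa, and odd k rules out perfect
palindromic k-mers. Contigs below 3 unique anchors are reported
unplaced; if nothing places, `UnscaffoldableError` is raised.

`close_gaps` walks adjacent placements (including the final wrap) and
joins them by iteratively extending the left flank with evidence
sequences. An extension is admissible only when the overlap is ≥
`min_overlap` (default 20) bases, has zero mismatches, and is anchored
at a terminus of the evidence sequence; a paired read additionally
requires its mate to occur within 3 standard deviations of the insert
size upstream in the proper orientation. Among admissible candidates,
one whose extension immediately joins the next contig is preferred
(tried longest-overlap first, ties by evidence id) — this resolves the
systematic two-way ambiguity at IR-end junctions, where reads from the
other IR copy's junction are also perfect-overlap candidates but do
not close toward the placed neighbour. Failing that, the longest
overlap wins if the top candidates agree; disagreeing candidates fall
back to a strict-majority consensus over the first 30 extension bases,
and a gap with no majority is left open and flagged ambiguous. On
circle closure the duplicated junction overlap is collapsed once.
Unclosable gaps yield a partial result with the junction recorded and
an N-run placed at the estimated gap length.

`assess_assembly` maps each read (both orientations) by seed-and-verify
(20-mer seeds at three offsets, exact match fast path, ≤ 2-mismatch
rescue); unmapped reads are ignored, since in real data they may be
nuclear or organellar-transfer reads. Depth is accumulated per
position with wrap-around; inconsistency calling examines only
positions where mapped reads mismatched, flagging those where the
majority of covering reads disagree with the assembly.

## Quadripartite structure

`detect_inverted_repeats` matches k-mer seeds (k = 25) of the sequence
against its reverse complement; matches belonging to one IR pair share
a constant anti-diagonal (sum of forward start positions), so the
dominant anti-diagonal group locates the pair, which is then extended
outward exact-first: an isolated mismatch is crossed only when ≥ 14 of
the following 15 positions pair and the total stays within 0.1 % of
the pair length. Identical repeats therefore stop exactly at their
true boundaries, while near-identical IRs (the 0.1 % allowance) are
still merged. A sequence whose whole circle is one palindromic
hairpin (X + revcomp(X)) is split at the hairpin apexes derived from
the anti-diagonal. Genomes with no pair ≥ `min_ir_len` (default
1,000 bp) return a no-IR result rather than an error, since some
plastomes genuinely lack IRs.

`canonicalize` re-detects the IRs, labels the copy after the longer
single-copy segment (the LSC) as IRb, rotates the origin to the LSC
start, and chooses the strand that puts the marker gene *psbA* (which
sits at the canonical LSC start, adjacent to the LSC/IRa junction) on
'+'. For unannotated sequences the lexicographically smaller of the
two candidate arrangements is chosen; both rules are idempotent and
invariant under the dihedral group of rotations/reflections. The
pipeline therefore re-canonicalizes once after annotation transfer, so
the marker-based rule replaces the lexicographic fallback.

`transfer_annotations` aligns each reference feature (both strands)
against the doubled target with edlib and computes identity as the
fraction of `=` operations over the extended-CIGAR alignment span.
"70 % similarity" is interpreted as percent identity of the best local
alignment — the unit was otherwise unspecified — with an added span
requirement (aligned span ≥ 90 % of feature length) to reject spurious
short hits. A secondary hit within 0.5 % identity of the best (found
after masking the best hit) is also transferred, which places
IR-duplicated features in both copies without duplicating single-copy
genes.

## Variant detection

`anchor_align` uses k-mers (default 21) unique in both sequences,
chains forward-strand anchors by longest collinear subsequence
(patience LIS), and merges same-diagonal runs with gaps ≤ 3k into
blocks, so isolated substitutions do not split blocks. Reverse-strand
anchors are grouped per diagonal but not globally chained, so multiple
local inversions remain visible. Inter-block gaps ≥ 100 bp on exactly
one sequence (net of the small-side gap, which may be slightly
negative under junction ambiguity) are emitted as insertions or
deletions; a gap large on both sides containing minus-strand blocks is
an inversion (≥ 50 bp). The default thresholds pass all four
marker-sized events (150–4,938 bp) and are exposed as parameters.
Loci are named by the nearest flanking annotated genes, with tRNA
anticodon suffixes stripped ("rps16-trnQ").

`find_inverted_flanks` returns the largest f ≤ 30 such that the f
bases immediately 5' of an inversion and the f bases immediately 3' of
it are reverse complements under IUPAC set-intersection compatibility
(Y matches C or T; degeneracy allowed, mismatches not). The planted
motif pair CCYTTTTY/GAAAAAGG scores exactly 8.

`map_synapomorphies` takes a rooted tree (newick, via dendropy) and
labels each variant record: taxa forming exactly a clade mark its
subtending branch (synapomorphy; autapomorphy if a single taxon);
otherwise the record is homoplastic/conflicting and the minimal
covering clade is reported. The tree is always an input, never
inferred here.

## HGT verification

`classify_insert_origin` aligns the insert (both orientations) against
user-supplied plastid and mitochondrial FASTA panels with edlib
(semi-global, shorter sequence into longer); identity is
1 − dist/span. The call is the panel with the better hit,
"unclassified" below 70 % identity or 100 bp span. The packaged
panels are small *synthetic* stand-ins (61 % vs 55 % AT) for curated
sequence sets; no live database is queried.

`junction_coverage` averages mapped depth over a 100 bp window centred
on each insert boundary and compares it with the genome-wide mean
(mean, not median — the choice was open). A boundary below 0.25 of
the mean is flagged suspect; 0.25 is a policy default chosen so that
reads simulated *without* the insert (depth tapering to 0 at the
boundary, window mean ≈ 0.13 of the genome mean) flag reliably while
reads *with* the insert (ratio ≈ 1) never do. With ~25× coverage the
per-boundary misclassification probability is a few percent, which is
why the discrimination batteries assert ≥ 19/20 rather than 20/20.

`composition_contrast` uses exact base counts (A+T over the full
interval length), so insert and remainder counts always sum to the
genome total.

`insilico_pcr` scans both strands of the doubled circular template
with 4-bit IUPAC masks (vectorised sliding windows), requiring ≤
`max_mismatch` compatible-mismatches overall and none in the 3'
terminal 3 bases (a policy choice; the original experiment reports
only product sizes). Every convergent site pair within `max_product`
yields a product whose length is the distance between the two primer
5' ends, inclusive; products are deduplicated modulo the circle.

## Matrix construction

Matrices are built from pre-aligned sequences; real-data multiple
alignment is delegated to external aligners and is out of scope, so
published full-alignment column counts are not reproduced here. For
synthetic near-identical genomes, `reference_guided_msa` stacks
pairwise anchor chains into a reference-frame alignment
(taxon-specific insertion columns, deletions as gaps). One IR is
excluded before matrix building to avoid over-representing repeat
sequence. Masks (gapped / inversion / coding) travel with the columns;
coding columns carry a per-CDS block id and strand so the coding
partition can be extracted — strand-normalised and concatenated in
genome order — before or after gap stripping with identical results
(the operations commute). Reading-frame harmonisation across taxa
with length-variant CDSs follows the reference row. Writers produce
FASTA, relaxed PHYLIP and a RAxML-style plain-text partition file;
model selection and tree inference are non-goals.

## Pipeline and reproducibility

`run_pipeline` executes simulate → finish → canonicalize → annotate →
variants → hgt → matrix from a `RunConfig` (YAML round-trip), logging
per-stage timings to stderr and writing artifacts plus a
`summary.json` keyed by a config hash and seed. All stage seeds
derive from the single config seed through `numpy.random.SeedSequence`,
so identical config + seed reproduces every artifact byte-for-byte.
The demo run plants the marker-like events (the big insert's payload
is copied at 99 % identity from a synthetic mitochondrial donor) and
its summary contains the planted-variant recovery table.

## Problem sizes used in the test batteries

The recovery and finishing batteries run 50 and 20 full-size genomes
respectively (region lengths drawn from the published ranges); the
HGT discrimination battery runs 20 positive/negative simulation pairs
at 25×; the oracle-equivalence suite compares four routines against
independent brute-force implementations on 1,000 random small
instances each. `scripts/acceptance.py` repeats the same computations
(20 trials per battery by default, `--trials` to change) and finishes
in about a minute.

## What the synthetic tests do not show

The generator's i.i.d. background has no tandem repeats,
microsatellites or gene-sequence conservation, so anchor uniqueness
and zero-mismatch overlap closure are easier than on real plastomes;
real finishing must also contend with quality trimming, indel
sequencing errors and library-preparation composition bias, none of
which are simulated. Passing batteries therefore validate the
algorithms' correctness and their behaviour under the stated noise
model, not performance on arbitrary real libraries. Annotation
transfer assumes the reference and target are close relatives;
divergent references will fall below the 70 % identity gate. The
anchored pairwise aligner is designed for near-identical genomes
differing by structural events and is not a substitute for a general
multiple aligner on divergent taxa.

## Known limitations

- Deletions and inversions inside an IR are not mirrored (only
  insertions are), so planting them there breaks the IR identity
  invariant; the tools still run but structure detection will report
  the reduced maximal pair.
- `close_gaps` assumes gap estimates from scaffolding are roughly
  correct; a badly mis-scaffolded junction can exhaust the extension
  budget and be reported open rather than mis-joined (fail-safe, not
  fail-silent).
- `reference_guided_msa` stacks taxon-specific insertions as separate
  column blocks and does not align insertion content between taxa.
- In-silico PCR models primer annealing combinatorially (mismatch
  counts only), not thermodynamically.
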