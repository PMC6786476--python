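# Methods

This note documents the models, rules and numerical choices behind each
stage, what the synthetic data do and do not emulate, and the known
limitations.

## Coordinates and genome model

All coordinates are 0-based half-open internally; GFF3 is emitted
1-based inclusive.  Genomes are circular: a feature may span the
origin, in which case its stored `end` exceeds the sequence length and
extraction wraps (the same convention is used in emitted GFF3).  The
circular origin is arbitrary and all interval logic is
rotation-invariant; when a quadripartite map exists, the canonical
reporting rotation places the start of the LSC at position 0.  An
LSC/SSC tie in length is broken toward the region with more
protein-coding features.  Gene classes are assigned from a bundled
prefix table (psa/psb → photosystem, pet → cytochrome b6f, atp, ndh,
rbc, chl, rpo, rpl/rps, trn, rrn; anything else "other"), overridable
per gene.

## Synthetic data: what is emulated

`make_reference_plastome` lays down a 82 + 32 + 4 gene complement in a
fixed catalog order with random intergenic spacers (mean 400 bp).
Protein genes are built from a codon alphabet that excludes stop
codons, then capped with ATG…TAA, so every reference ORF is valid by
construction and the classifier's lesion rules have unambiguous ground
truth.  A small set of genes carries realistic lengths (rpoC2, ycf1/2,
psaA/B, rbcL, the rRNAs, …); the rest draw from 126–546 bp (proteins),
71–90 bp (tRNA).

`build_parasite_genome` assembles the degraded genome region by region
with exact lengths — LSC 38,859 bp, SSC 27,947 bp, IRs 9,256 bp each,
85,318 bp total — reusing the reference gene sequences.  Of the 82
protein genes, 49 photosynthesis-related genes are lost: 21 are
retained as pseudogenes (premature stop, 1-bp frameshift deletion or
insertion) and 28 are physically deleted; one tRNA (trnR-CCG) is
deleted.  The IR carries eight genes typically found in the LSC
(trnI-CAU, trnH-GUG, matK, trnK-UUU, trnQ-UUG, rpl23, rpl2, rps19),
duplicated in inverted orientation with `_2` copy suffixes.  Eight
deleted genes (ndhB/D/E/K, petB, psaA/B, psbB) additionally leave
low-depth read fragments (relative depth drawn from 0.2–0.6, half of
the CDS) emulating nuclear/mitochondrial plastid inserts.

**Junction sealing.**  The generator mutates at most one intergenic
base adjacent to each IR junction so that the inverted self-match
cannot extend past the planted boundary.  Without sealing, the flanking
base matches by chance with probability 1/4 per junction, the maximal
self-match would then be longer than the planted repeat, and "0-bp
boundary error" would not be a well-defined target.

Reads are 150-bp paired-end with Gaussian fragment lengths
(mean 650 bp, sd 65, truncated below at the read length), sampled
uniformly on the circle with wrap.  Errors are uniform substitutions
only; no indel errors, no quality model (FASTQ qualities are constant
"I"), no GC- or amplification-bias, and no coverage spikes over rRNA
genes — so a passing suite demonstrates correctness of the inference
rules, not robustness to instrument artifacts.  All generators are
deterministic given their seed.

## IR detection

Candidates are maximal inverted self-matches of the assembly, found by
scanning anti-diagonals of the sequence against its reverse complement
(see the repeat census below) with exact-31-mer seeding — sound here
because an IR-scale match guarantees long exact seeds.  The default
`max_mismatch` is 0: the generator's IR copies are identical, and the
assembly (not the reads) is scanned.  `min_ir_len` = 1,000 bp separates
IR calls from ordinary inverted repeats, which belong to the census.

Read validation uses a minimal internal mapper (exact 31-mer seed +
ungapped extension, ties to the leftmost position; SAM-subset I/O is
provided for external alignments).  Because the mapper collapses two
identical copies onto the leftmost, every fragment crossing a junction
of the *second* copy produces a discordant pair: one mate anchored in
unique sequence, the other displaced into the first copy.  A pair is
discordant when its mates are not in FR orientation with an implied
insert within mean + 4 sd.  Each discordant pair supports one
single-copy-side junction (through its anchor, which must face the
junction within one insert length) and one repeat-side junction
(through the displaced mate pressing against the copy boundary).  A
two-copy candidate is accepted when all four junctions collect at least
`min_pairs` = 5 discordant pairs; a single-interval candidate (IR
collapsed in the assembly) is accepted when its mean depth over the
flanking mean lies in [1.7, 2.3].  These thresholds are package
choices, exposed in configuration, chosen for 50–200× data; boundaries
are reported at the self-match ends, which the junction evidence
validates.  In an IR-free genome every pair is concordant, so the
split-pair count is identically zero and no candidate can be accepted.

Known geometric limitation: if every fragment is shorter than the
distance from the junctions to unique sequence, junction support is
zero even for a real IR.

## Gene-status classification

A reference gene is located in the target by exact 21-mer seeds of its
CDS (both strands), clustered by diagonal; the best cluster's window
(±80 bp plus the unmatched CDS extent) is aligned to the CDS with an
affine-gap global alignment (match +2, mismatch −3, gap open −5,
extend −2) whose end gaps on the genomic window are free.  Sensitivity
is therefore bounded by the presence of one exact 21-mer — ample for
planted lesions, which are point events, but a real-data ortholog
search at high divergence would need a seeded heuristic with smaller or
spaced seeds.

Rules, all thresholds exposed in `ClassifyConfig`:

* homolog present ⇔ identity ≥ 60% over ≥ 30% of the CDS; otherwise
  **absent** (evidence `no_homolog`);
* protein genes: **intact** ⇔ covered fraction ≥ 0.9, no stop codon
  before 90% of the reference protein length, and net indel ≡ 0 mod 3;
  a frame restored within the gene counts as intact-by-frame but still
  pseudogenizes if an internal stop results;
* **pseudogene** ⇔ homolog present and any lesion rule fires
  (`premature_stop`, `frameshift`, `truncated`); a pseudogene call
  always names at least one lesion;
* tRNA/rRNA genes have no frame: covered ≥ 0.9 and identity ≥ 80%.

The premature-stop test translates the reconstruction
`cds[:q_start] + aligned_target + cds[q_end:]`, so a lesion is detected
in the reference frame even when alignment coverage is partial.
"Truncated" is operationalized as < 90% coverage, tolerating terminal
sloppiness while catching real truncations.  Intron-containing genes
are not modeled (the generator produces single-exon genes); with exon
annotations classification would run on the spliced CDS.

Absence verification scans the read pool with exact 21-mer seeds of the
CDS and counts matching read bases (≥ 80% identity over ≥ 50 bp per
read); the covered span's mean depth over the main plastome coverage is
the *relative depth*, and values below 1 flag a likely extra-plastomic
insert — the read-level analogue of finding orthologs on assembly
contigs whose k-mer coverage is below 1.

## Repeat censuses

A maximal repeat pair with ≤ k substitutions is exactly a maximal
≤ k-mismatch run on one diagonal of the sequence against a transform of
itself: identity (forward), complement, reverse, or reverse complement
(inverted); the latter two live on anti-diagonals.  The scanner
enumerates every circular offset with vectorized window sums and
extracts maximal runs between mismatches; for forward/complement,
offsets d and n − d describe the same unordered pairs and only half are
scanned.  This diagonal scan is exact and, on desk-scale genomes
(< 200 kb), faster in practice than pigeonhole seeding with per-pair
extension, whose 5-mer seeds at the default parameters hit nearly every
diagonal anyway; a brute-force oracle pins its correctness in the test
suite.  `N` never matches anything.  Pairs overlapping by more than
half the shorter interval are suppressed (tandem arrays belong to the
tandem scanner), each unordered pair is reported once, and hits are
filtered by an e-value

    E(l, k) = 4 n² · P[Bin(l, 1/4) ≥ l − k],

the expected number of chance pairs of the observed quality.  The
binomial-tail form is a package definition (simple, monotone in l and
k); correctness claims rest on the oracle equivalence, not on matching
any external tool's e-values.  Defaults: min length 20, Hamming
distance ≤ 3, E ≤ 10⁻³.

Tandem arrays are perfect repetitions only: maximal runs of
S[x] = S[x+u] give arrays of total length run + u; a hit requires total
≥ 10 bp, at least two full copies, a unit of 2–50 bp, and a *primitive*
unit (the array's smallest period equals u, so "ACACAC" is reported at
unit AC and never at ACAC; homopolymers fall below the unit floor).
Copy number may be fractional.

Density reports hits per kb and the fraction of genomic bases covered
by the union of hit intervals (each base counted once).

## Rearrangements

Genomes enter the collinearity analysis linearized in their stored
rotation after collapsing IRb (large duplications otherwise confound
1-to-1 anchoring).  Anchors are genes present exactly once in every
genome; a junction between reference-adjacent anchors survives iff the
two anchors are adjacent and equioriented in every genome; maximal
surviving runs are the blocks, optionally re-chained after dropping
blocks below a minimum length.  Block orders become signed
permutations, brought to a canonical frame (block containing the first
anchor first, positive; reflection allowed) so rotation and reflection
of a circular genome do not change distances.

Breakpoint distance counts non-conserved signed adjacencies (linear
framing with end caps by default; circular closure available).
Reversal distance is exact via the breakpoint-graph formula
d = (n + 1) − c + h + f (cycles, hurdles, fortress), with hurdles
identified as unoriented interleaving-components whose elements are
cyclically contiguous among all unoriented-component elements, and
super-hurdle/fortress detection by deletion testing.  The
implementation is validated exhaustively against breadth-first search
over all 46,080 signed permutations of n = 6 and against an independent
IDA* oracle on random n ≤ 8 pairs.  Fortresses cannot occur at these
sizes; the fortress branch is implemented from the standard definition
but is exercised only by the h-odd/all-super test path.

Tree rearrangement counts label internal nodes by Sankoff dynamic
programming over a finite candidate universe: the observed leaf labels
plus their one-reversal neighborhoods, solved exactly within that
universe, then augmented with one-reversal neighbors of the chosen
internal labels and re-solved until the total stops improving.  The
enriched universe matters: restricted to observed labels alone, a star
of three leaves one (disjoint) event each from an unobserved ancestor
costs 4 > 3, exceeding the true event count, and single-label
coordinate descent additionally stalls on equal-cost plateaus where
two adjacent internal nodes must change together — the DP over the
whole tree escapes both.  The total is an upper bound on the
unconstrained minimum and is flagged `heuristic`; it is never below
the largest pairwise leaf distance (triangle inequality).

## Correlated-trait models

Two traits under Brownian motion on a fixed rooted tree have tip
covariance R ⊗ C with C[i,j] the shared root-to-tip path length and
R = [[σx², σxy], [σxy, σy²]].  The free model estimates σxy; the null
fixes it at 0; LR = 2(lnL_free − lnL_null) is referred to χ²(1).
Maximum likelihood is computed in closed form — root states by GLS,
R̂ = D'C⁻¹D/n, null rates the diagonal of R̂ — rather than by numerical
optimization: the optimum is analytic for this model, the closed form
is exact and ~10³× faster, which the 1,000-replicate calibration check
requires.  The likelihood itself is evaluated through the Kronecker
structure (log|R ⊗ C| = n log|R| + 2 log|C|) and agrees with the dense
2n-dimensional normal to 10⁻⁸.  Degenerate inputs: C is floored
(1e-8 × max depth on the diagonal) only when singular, e.g. zero-length
terminal branches; a perfectly correlated pair (Y = X) is kept strictly
inside the parameter space by capping |σ̂xy| at (1 − 10⁻¹²)·σ̂xσ̂y, which
sends the LR to numerical infinity and p to 0 as it should.

Binary traits (IR presence, heterotrophy) are coded 0/1 and analyzed
under the same continuous random-walk model; every result on such a
pair carries an explicit caveat string.  Known small-sample property:
with ML variance estimates the LRT statistic is −n·log(1 − r̂²), which
at n = 16 tips rejects a true null at α = 0.05 about 7% of the time
(the χ²(1) reference is asymptotic); the calibration test in the
acceptance suite measures exactly this.  Power against strong
correlation (r = 0.9) at n = 16 is effectively 1.

## Problem sizes used by the suite

The randomized validation uses compact study conditions chosen to be
statistically meaningful at desk scale: 20 planted-IR scenarios
(~25–40 kb genomes, IRs 2–12 kb, 50–100× reads, ≤ 1% error) plus 20
IR-free controls; 20 lesion scenarios with ≥ 10 lesions each on
~30-gene references; 20 insert-fragment scenarios; 50 sequences up to
2 kb for the dispersed-repeat oracle and 50 up to 1 kb for the tandem
oracle; all signed permutations of n ≤ 6 plus 200 random pairs of
n ≤ 8; 20 planted 6-leaf rearrangement histories; 1,000 null and 500
alternative LRT replicates on a fixed 16-taxon tree.

## Known limitations

* The mapper and ortholog search rely on exact k-mer seeds; both are
  adequate for simulated substitution-only data and would need
  sensitivity work for diverged real data.
* No assembly is performed and IR flip-flop isomers are not resolved;
  the assembly sequence is taken as given.
* The tandem scanner reports perfect arrays only; degenerate
  (mismatch-tolerant) tandem repeats are out of scope.
* Tree rearrangement totals are heuristic upper bounds, not MGR-style
  optima; the reversal median problem is not solved exactly.
* The trait model treats binary characters as continuous liabilities
  observed directly; a threshold or discrete-state model would be the
  next refinement.
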