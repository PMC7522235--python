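# Methods

## The assay being modelled

A coral holobiont sample is characterized by three PCR amplicons sequenced
together on one nanopore flow cell: host 18S rRNA (~1.8 kb), Symbiodiniaceae
ITS2 (~250 bp) and bacterial 16S rRNA (~1.3 kb).  Every primer carries a
constant PCR tail and one of twelve sample barcodes at its 5′ end, so a
forward-strand molecule reads

```
fwd_tail · barcode · fwd_primer · insert · rc(rev_primer) · rc(barcode) · rc(rev_tail)
```

The tails are `TTTCTGTTGGTGCTGATATTGC` (forward) and
`ACTTGCCTGTCGCTCTATCTTC` (reverse).  Marker primers (IUPAC degeneracies
kept): 18S `AACCTGGTTGATCCTGCCAGT` / `TGATCCTTCTGCAGGTTCACCTAC`;
16S 27F `AGAGTTTGATCMTGGCTCAG` / 1492R `TACGGYTACCTTGTTACGACTT`;
ITS2 SYM_VAR_5.8S `GAATTGCAGAACTCCGTGAACC` / SYM_VAR_REV
`CGGGTTCWCTTGTYTGACTTCATGC`.  One published rendering of the ITS2 reverse
tail carries a trailing extra `T`; the scheme here uses the single 22-mer
tail for all three markers, treating that character as part of the primer
context rather than a distinct tail.  The barcode sequences of the original
kit are not public: the scheme generator draws twelve synthetic 24-mers
with pairwise edit distance ≥ 8, deterministically from a seed, and the
package treats them as what they are — synthetic stand-ins whose separation
(not identity) is the property the pipeline depends on.

## Read simulation

`ErrorModel` applies, per input base, deletion with probability `del_rate`,
else substitution with probability `sub_rate` (uniform over the three
alternatives), and after each emitted base an insertion of a uniform random
base with probability `ins_rate`.  The defaults 0.06/0.04/0.05 (≈15% total)
approximate an early-generation nanopore error profile; no published figure
fixes the exact rates for this assay, so the split was chosen once as a
plausible sub/ins/del balance and is fully configurable
(`ErrorModel.with_total` rescales the split to any total).  Expected read
length under the model is `n·(1−del)·(1+ins)`, which the tests verify along
with convergence of the realized rates.

Reads are reverse-complemented with probability ½.  Optional junk reads
(uniform random sequence, 200–1200 bp) model unclassifiable output, and
optional chimeras (two complete amplicons concatenated, so the junction
retains a full tail+barcode block) model the middle-adapter reads that the
demultiplexer must discard.  Emitted qualities are flat Q12 — the pipeline
never uses them, matching a consensus protocol that disables quality
weighting.

What the simulator does *not* emulate: homopolymer-biased and
context-dependent errors, quality-score structure, PCR chimeras with partial
junctions, abundance-dependent amplification bias, and databases at real
scale (hundreds–thousands of entries).  Passing tests therefore demonstrate
the correctness of the decision rules and their behaviour under iid error,
not calibrated accuracy on real flow-cell data.

Fixture databases contain random sequences at the three amplicon lengths,
plus the structures the retention rules act on: Symbiodiniaceae-18S decoys
in the host database (flagged via a companion ID list, mirroring how the
five real decoy entries are identified by accession rather than by
taxonomy), chloroplast entries in the 16S database (flagged when any
taxonomy rank equals "Chloroplast", the Greengenes convention), and ITS2
variant families whose members are 1–2 substitutions apart, the situation
that drives richness inflation.

## Demultiplexing

Both ends of each read are searched, in both orientations, for all 24
tail+barcode blocks (12 barcodes × 2 strands per end) with an exact
semi-global edit-distance search (edlib; IUPAC codes match at zero cost).
A block is accepted at edit distance ≤ ⌈0.25·len(block)⌉; the end window is
150 bp, enough for the ≤ ~70 bp block plus indel slack.  Decision rules:

- a block hit in the read interior (outside both end windows) marks the
  read `DISCARDED_MIDDLE`;
- ends agreeing (or a single hit) assign the read to the barcode's sample;
- ends hitting different barcodes or strands leave it `UNASSIGNED`
  (conservative — no best-end override);
- assigned reads shorter than 100 bp after trimming are `UNASSIGNED`, since
  no marker is informative below that length.

The interior scan uses the full 46-bp tail+barcode blocks rather than the
bare 22-bp tails.  A 22-mer at 25% tolerance matches random sequence inside
a 1–2 kb read far too often (about a third of error-free simulated reads
would be discarded), while a genuine chimera junction always contains a
complete block; the longer motif removes the false positives at the same
relative threshold and the same sensitivity to real junctions.

Trimming removes everything outward of the marker primer boundaries: after
locating the block, each marker's primer is searched just inward of it and
the best hit sets the cut.  On error-free reads this recovers the bare
insert exactly.

## Alignment

The aligner fills the minimap2 role at amplicon scale, natively:

- **Seeding**: canonical-k-mer minimizers, k=15/w=10 for the 1.3–1.8 kb
  markers and k=11/w=5 for the short ITS2 amplicon (denser seeds so enough
  survive 15% error on 250 bp).  K-mers are hashed with a 64-bit mixer so
  minimizer choice is decorrelated from sequence content.
- **Chaining**: longest strictly-colinear subset of seed anchors per
  (reference, strand), via patience LIS; at most 5,000 seeds are considered
  (deterministic subsampling beyond that), and the top 5 chained candidates
  go to DP.
- **Banded DP**: ends-free (overlap) affine-gap alignment — match +2,
  mismatch −4, gap open −4, gap extend −2, a length-L gap costing 4+2L —
  with the band centered on the chain's median diagonal and half-width
  max(50, 0.2·read length, half the chain's diagonal spread + 20).  Free
  end gaps on both sequences tolerate residual adapter bases and partial
  reference coverage.  The banded score equals the unbanded optimum
  whenever the optimal path stays inside the band, which the tests verify
  against an independent full DP.
- **Filters and ties**: an alignment is reported only with identity ≥ 0.70
  and query coverage ≥ 0.50 (chosen to pass ~15%-error reads with margin
  while rejecting cross-marker noise); no positive-scoring alignment means
  unmapped.  Ties break by higher identity, then lexicographically smaller
  reference ID — deterministic and biased toward the alphabetically first
  member of a variant family, which keeps error-free runs exact.

Every alignment carries an explicit `=/X/I/D` edit string; the score is
exactly recomputable from it, and the pileup stage consumes it directly.
A read's marker is whichever database yields the best filtered score.

## Two-round selection

Retention after round 1 is marker-specific (fractions are of *mapped* reads
of that marker in that sample, after the stated removals — the denominators
are recorded in the run metadata):

- **Host 18S**: discard reads whose best hit carries the
  SYMBIODINIACEAE_18S flag, then keep exactly the reference with the most
  reads.  An argmax tie keeps the lexicographically smaller ID and logs a
  warning.
- **ITS2**: keep references at fraction ≥ 0.01.
- **16S**: remove rows mapping to CHLOROPLAST references, recompute the
  total, keep references at fraction ≥ 0.0001.  The order matters: removal
  first shrinks the denominator, so the retained set is a superset of the
  removal-after alternative; the tests pin the implemented order at the
  exact boundary (1 read / 8,000 = 0.000125 is kept).

Round 2 re-maps **all** of the sample's demultiplexed reads — including
round-1 unmapped ones — against only the retained references, with identical
parameters.  The inclusive choice follows the stated purpose of the second
round (aggregating potentially mis-assigned reads); reads excluded as
chloroplast or symbiont-18S hits are counted but never re-enter.

Consensus is gated at **strictly more than 10** supporting reads (≥ 11); a
reference with exactly 10 is not emitted.

## Consensus calling

Pileups accumulate per-reference-position counts over {A,C,G,T,deletion}
directly from the edit strings — no realignment, no quality weighting.
The call is a per-position plurality: deletion wins emit nothing; ties go to
the reference symbol when it is among the leaders, else to the smallest
symbol in A<C<G<T<deletion order.  An insertion after a position is emitted
when its most frequent inserted sequence is carried by more than 50% of the
reads spanning that junction.  Zero-depth positions emit the reference base
(configurable to `N`), so shallow pileups still produce full-length
sequences.

This plurality rule is a fully specified stand-in for a haploid
genotype-likelihood caller: with qualities disabled and deep amplicon
coverage the two coincide, and the equivalence claimed is behavioural, not
bit-exact.  At depth 30 with 5% per-base substitution noise, a site where
the truth differs from the reference is recovered essentially always
(binomial tail < 10⁻⁶; measured ≥ 99% over 500 replicates).

Each consensus is labelled with its closest database reference by global
edit distance (ties to the smaller ID), mirroring closest-match assignment
of novel sequences.

## Profiles and the holobiont network

Relative abundances come from round-2 counts; taxonomy roll-ups use the
Greengenes rank order (domain…species) with missing ranks bucketed as
"unclassified" and totals conserved.  The network is bipartite: one colony
node per sample (attributed with the host family, or "morphology-only" when
no host call was possible) and one taxon node per retained sequence, with an
edge when the taxon's fraction reaches the marker's display filter — 5% for
ITS2 sequences, 1% for bacterial sequences — applied to round-2 fractions
(the final assignments).  Layout is Fruchterman–Reingold, 200 iterations,
seeded; a single node sits at the origin.

## Orchestration, determinism, problem sizes

A single YAML config drives the run; unknown keys are rejected and all
defaults are echoed into `run_metadata.json`.  One global seed fans out to
per-stage seeds through a fixed `SeedSequence` derivation (all derived seeds
< 2³¹), so identical config+seed yields byte-identical output bundles —
timestamps appear only on stderr logging, never in result files.  A stage
failure removes any files already written and aborts with a stage-named
error.

The shipped tests and the acceptance script run the workflow at desk scale,
sized so the full suite completes in a few minutes on one CPU: 12-sample
runs with 15/25/20 reads per marker per sample (720 reads), a 1,000-read
demultiplexing check against an exhaustive full-DP oracle, 200
read/reference pairs for banded-vs-full DP equality, 500 consensus-recovery
replicates at depth 30, and richness sweeps of 600 ITS2 reads × 3 replicates
at total error rates {0, 0.05, 0.10, 0.15}.  These sizes are the package's
own defaults for self-verification; real runs are bounded by read count ×
reference count in the round-1 mapping, which is linear in both.

## Known limitations

- The aligner is exact only within its band and reports nothing when no
  positive-scoring alignment exists; extremely short or extremely noisy
  reads are conservatively unmapped rather than force-aligned.
- Multi-mapped reads are assigned hard to the best reference (ties
  deterministic); there is no probabilistic re-weighting, matching the
  original hard best-hit design.
- The consensus caller assumes one haplotype per retained reference; mixed
  pileups from two true variants collapsing onto one reference yield the
  majority haplotype.
- Richness inflation is reproduced as a mechanism (neighbour capture grows
  with error rate, retained count equal to truth at zero error); absolute
  inflation factors on real data depend on database density and read depth
  and are not claimed.
- Taxonomy handling assumes Greengenes-style rank order for roll-ups; the
  "plain" dialect used for host/ITS2 headers is an assumption, documented
  here, not a published format.
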