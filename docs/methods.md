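# Methods

## The model of the screen

The assay couples random transposition with a translational reporter.
The transposon's resistance gene has no promoter, RBS or start codon, so
a mutant survives selection only when the transposon sits in-frame
within a translated reading frame, 3′ of whatever codon initiates that
frame's translation. Each surviving mutant therefore certifies a triple
(strand, frame, position): translation passes through that position in
that frame. The analysis problem is the inverse map — from a set of
certified triples back to coding sequences.

Three consequences shape the pipeline:

1. **The junction is the datum.** The first nucleotide of the trimmed
   read is the insertion site. On the forward strand this is the
   leftmost aligned base; on the reverse strand the read's first base
   maps to the *rightmost* aligned base. Both conventions for the
   reverse strand exist in the wild, so the alternative (bare leftmost
   POS) is selectable, but the read's-first-base rule is the default
   because it is what the assay measures.
2. **A frame, not a gene, is what a fusion certifies.** Discovery
   therefore works on stop-to-stop frames: the maximal codon run
   containing the junction with no stop codon, bounded by stops (or the
   contig end upstream). All fusions sharing a terminating stop are the
   same translational unit and collapse into one candidate.
3. **The start codon is an estimate.** A fusion cannot reveal the
   initiating codon, only that initiation happens 5′ of the junction.
   The start is chosen from the seven strongest initiation codons
   (ATG, GTG, TTG, CTG, ATA, ATT, ATC in decreasing strength) as the
   furthest-upstream occurrence at or 5′ of the 5′-most supporting
   junction — a deliberately conservative maximal length. The two rules
   "in preferential order" and "furthest upstream" conflict when
   different codons occur at different positions; positional precedence
   is authoritative here, and the ordering of the set documents
   initiation strength only. `--start-anywhere` (library flag
   `require_start_upstream=False`) drops the junction bound for
   exploratory use. The codon set itself is configurable, since far
   more codons can initiate translation at low efficiency.

## Classification rules

A site's host is any phaseable annotated CDS containing its position
(phaseable = length divisible by 3; pseudogene-like models are loaded
but excluded from frame arithmetic). The verdict is IN_FRAME when the
host is on the reporter strand and `(pos − start) mod 3 == 0` (mirrored
from the 3′ end for minus-strand genes), OUT_OF_FRAME when the site is
inside a gene on the wrong strand or in the wrong phase, INTERGENIC
otherwise. With two annotation sources loaded, IN_FRAME in either one
wins and the rescuing source is recorded — a newer annotation can
legitimately claim sites the older one calls OOF/intergenic. For
overlapping same-strand genes, IN_FRAME beats OOF; OOF host selection
prefers same-strand, then 5′-most.

Candidate classes: a candidate overlapping an annotated CDS (largest
overlap wins, ties to the 5′-most gene) on the same strand is a nested
gene with frameshift `(candidate start − parent start) mod 3` (1 → +1,
2 → +2; 0 cannot occur for a genuinely nested frame and demotes the
gene from parenthood with a warning); opposite strand → antisense;
no overlap → intergenic.

## Replicates and noise

Both selections screen the *same* mutant library, so an in-frame fusion
survives both deterministically while a spontaneous-resistance event
(modelled Bernoulli per insertion per screen, rate r) recurs at the
same site only at rate r². Requiring exact (contig, pos, orientation)
identity in both screens — no positional fuzz by default, no minimum
read count — is therefore the noise filter; the expected number of
surviving shared noise insertions is n·r², which the test suite checks
within 3 SD. A `match_window` option exists for noisier data.
Replicate agreement is quantified as Pearson correlation of per-gene
insertion density (unique sites per bp of gene; a read-weighted variant
is available since the density definition is not canonical).

## Coordinate and numerical choices

- 0-based half-open everywhere internally; GFF3/SAM converted at the
  boundary. This removes every ±1 from the frame arithmetic.
- Reporter frame: `(pos + offset) mod 3` forward, `(L − 1 − pos +
  offset) mod 3` reverse. The global `junction_offset` (default 0)
  absorbs alternative junction conventions such as correcting for the
  9-bp target-site duplication of Tn5; it is exposed rather than
  guessed.
- Stop-to-stop bounds exclude both flanking stops; `stop_pos` is the
  stop codon's first base on its strand. At a linear contig end with no
  upstream stop, the run starts at the contig's first in-frame codon;
  with no downstream stop the scan returns nothing (no candidate
  without a stop). Circular contigs are supported behind a flag
  (default off, matching linearized reference genomes) and require
  contig length divisible by 3 for a well-defined wrap.
- Transposon search: segment 1 seeds a scan over every read offset,
  segment 2 must follow immediately; the offset minimising the combined
  Hamming distance wins (leftmost on ties) against one shared budget
  (default 4 substitutions; no indels). Default segment split of a
  supplied query: first 20 nt / remainder.
- Built-in mapper: exact 20-nt seed, full-fragment extension with ≤ 2
  substitutions, unique-best-hit required; ties and multimappers are
  dropped outright so site lists are reproducible. Leading soft-clips
  beyond 3 nt at the read's 5′ (transposon-proximal) end invalidate a
  SAM-imported junction, since residual transposon bases shift sites
  systematically.
- Percentages are printed to 2 decimal places, round-half-up.
- Candidates sharing a stop but hit at different junctions across
  replicates merge on (contig, strand, frame, stop), the stable key of
  the translational unit.

## The simulator: what it emulates, and what it does not

Defaults are the study conditions used throughout the tests and the
acceptance script: 20-kb genome at GC 0.5; 15 non-overlapping annotated
genes of 100–300 codons (ATG start, stop-free body), all expressed;
8 hidden CDSs of 8–60 aa in a 0.40/0.30/0.15/0.15 mix of intergenic /
nested +1 / nested +2 / antisense, 75% expressed; 5000 insertions per
screen drawn uniformly over (position, orientation); spontaneous
resistance 10⁻³ per insertion per screen; reads of barcode (8 nt,
pairwise Hamming ≥ 5) + 39-nt transposon tail + 50 nt genomic flank
with substitution errors at 0.002 (a post-filter short-read error
rate); one read per insertion. Planted start codons follow the observed
initiation-strength ranking (ATG 0.44, GTG 0.25, TTG 0.11, CTG 0.08,
ATA 0.05, ATT 0.04, ATC 0.03). Nested CDSs are embedded by redrawing
codons until the parent's frame stays stop-free, so both layers of the
overlap are simultaneously valid ORFs.

Selection survival requires the insertion in-frame within an expressed
CDS at or 3′ of `start + 3` — the reporter needs initiation upstream of
the junction. The optional `edge_biased` mode thins mid-CDS survivors
with a per-codon geometric decay anchored at both CDS ends; it is a
phenomenological stand-in for the observed 5′/3′ clustering of
surviving fusions, which likely reflects mRNA-stability effects that
are *not* modelled mechanistically. Also not modelled: PCR duplication,
insertion-sequence bias of the transposase, read-depth overdispersion
(the discovery algorithm is count-threshold-free), or growth dynamics.
Passing tests therefore demonstrate correctness of the inference given
the assay's idealised geometry — not robustness to the full noise
structure of a real library.

Problem sizes in the test suite and acceptance script (5 screens of
5000 insertions on 20-kb genomes; 50 genomes of 600 bp for the
exhaustive six-frame oracle comparison; 20 000 insertions for the noise
expectation) are chosen so the whole suite completes in well under a
minute while every statistical check retains power.

## Known limitations

- The exact-seed mapper requires an error-free first 20 nt; at 1%
  substitution error that bounds read-level junction recovery near
  0.99²⁰ ≈ 0.82 (measured 0.823 on the frozen seeded scenario, with no
  incorrect placements). Real data should be mapped with a
  production aligner and imported via SAM; the built-in mapper exists
  to keep desk-scale validation self-contained.
- Reported candidate lengths are upper estimates: the true start may be
  downstream of the furthest-upstream compatible start codon.
- A candidate whose stop-to-stop frame spans a contig boundary on a
  circular genome with length not divisible by 3 is not reconstructable.
- Site-level replicate intersection assumes both screens sequence the
  same library; for independently constructed libraries the exact-match
  filter would be far more aggressive and `match_window` should be
  considered.
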