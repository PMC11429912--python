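# Methods

This note documents the models and procedures implemented in `hapolish`, the
assumptions behind them, the synthetic worlds they are exercised on, and the
numerical choices that a maintainer would want spelled out.

## The problem

Haplotype-resolved draft assemblies built from long reads retain residual
base-level errors: random consensus mistakes (dominated by 1 bp indels in
homopolymers) and a structural failure mode in which genuinely heterozygous
sequence is emitted identically on both haplotypes ("false homozygosity").
When such a collapsed region is longer than a HiFi read (~25 kb ceiling), an
aligner cannot tell the haplotypes apart there, assigns reads arbitrarily,
and any downstream polisher sees a 50/50 mixed pileup at every het site —
so the heterozygous corrections are never made. `hapolish` implements the
two-stage remedy: phase-aware read reassignment in long identical regions
using ultra-long (UL) reads, followed by candidate-window consensus
polishing, class-specific genotype-quality (GQ) filtering, and edit
application, with a k-mer based assessment suite around it.

## Phase-aware reassignment

1. **Region discovery.** The two draft haplotypes are aligned globally
   (edlib, extended `=`/`X` CIGAR) and maximal runs of consecutive `=`
   columns strictly longer than 20,000 bp (roughly the mean HiFi read
   length) are reported as homozygous region pairs on both haplotypes'
   coordinates. CIGARs with `M` are rejected because match/mismatch status
   is ambiguous.
2. **Read pre-filter.** Alignments with gap-compressed mismatch ratio above
   0.02 are excluded from variant calling. The ratio counts each
   insertion/deletion *run* once and each `X` column individually:
   `(nX + gap_events) / (n= + nX + gap_events)`.
3. **Heterozygous candidates.** Per locus the pileup is reduced to ref/alt
   counts (SNVs keyed by base, indels by anchor and allele, indels capped at
   10 bp) and genotyped under a symmetric-error binomial model with error
   rate 0.01. GQ is the phred gap between the best and second-best genotype
   log-likelihood, capped at 99; only heterozygous calls with GQ ≥ 10
   survive. This genotyper is an intentionally simple, *pluggable* stand-in:
   `run_pharaoh` accepts an externally produced phased variant list that
   bypasses both it and the phaser.
4. **Phasing.** UL alignments (reads > 100 kb) vote on the relative phase of
   each adjacent candidate pair (cis when a read carries the same allele
   class at both sites); variants co-covered by at least one UL read join a
   block, and phase propagates left-to-right by majority vote. A read's
   allele at a site is determined by locally re-aligning the read
   subsequence against the ref- and alt-applied reference windows (±12 bp
   flank) — indifferent to where the aligner placed indels in repeats; ties
   abstain.
5. **Block haplotype selection and pseudo-polishing.** Each phase block's
   haplotype with more reference alleles (the one closer to the assembly) is
   selected, ties to A. Its alt alleles are the retained edits for assembly
   haplotype 1; the complementary alleles, carried across the region-pair
   offset, pseudo-polish haplotype 2. Applying one set per haplotype is what
   makes the two pseudo-polished sequences differ inside a collapsed region;
   applying a single set to both (a literal reading of the source pipeline's
   one-sentence description) would leave them identical and the comparison
   uninformative.
6. **Variant blocks and scoring.** A window of width
   `max(100, 2 × reference span)` is centered on each phased variant,
   clipped to the contig, and overlapping windows are merged. Per read, the
   per-haplotype blocks are projected onto read coordinates through each
   alignment, merged on the read, projected back per haplotype, and the edit
   distance (edlib) between the read chunk and the pseudo-polished haplotype
   chunk is summed over merged blocks. Lower sum wins; exact ties keep the
   current assignment. Reads overlapping no block pass through unchanged, as
   does the entire genome outside discovered regions (marker-mode
   reassignment is prior work and intentionally a no-op hook).
7. **Final filter.** Alignments with gap-compressed mismatch ratio above
   0.002 are removed before polishing.

## Candidate-window polishing

A position is a candidate when **three or more distinct reads** disagree
with the assembly there — a mismatch at the position, a deletion covering
it, or an insertion anchored immediately after it; a read counts once per
position however it disagrees. Candidates within 50 bp chain greedily into
windows capped at 100 bp of sequence. Each window becomes a pileup tensor
(rows = reads, deterministically subsampled to 30 by SHA-1 of read name;
columns = reference positions plus one slot per distinct insertion locus;
channels = base / match flag / base quality / mapping quality). The contig
is scanned in 25 kb tiles overlapping by 1 kb so windows at tile boundaries
are never split; candidates are deduplicated across tiles.

The sequence predictor is pluggable behind a
`FeatureTensor -> (sequence, per-position support)` contract. The default
core is a quality-weighted consensus: per column, the allele (base, gap, or
inserted string) with the greatest summed weight wins, with weight
`1 − 10^(−baseq/10)` per supporting read; an insertion is emitted only when
its weight exceeds half the column total; all-pad columns retain the
assembly base. Ties break to the assembly base. A trained model can replace
this core without touching the rest of the pipeline; the GQ scale below is
the core's own convention, not a learned confidence.

Differences between the predicted and assembly sequence become
left-normalized VCF records: substitution runs are emitted as individual
SNVs (never MNPs — this keeps the 1 bp indel classes clean for filtering),
while difference events separated by ≤ 2 matched bases with an indel
involved are merged into a single replacement record. The merge matters:
edit-distance aligners freely fragment one biological 2 bp insertion into
two 1 bp insertions at shifted anchors, and the fragments would be
classified (and filtered) as independent 1 bp indels. Record GQ is the
phred of one minus the smallest support fraction among its predicted
positions, capped at 99.

## Filtering and application

Edits are classified INS1 (anchored +1 bp), DEL1 (anchored −1 bp), or OTHER
and kept when GQ ≥ the class threshold — defaults 20 / 12 / 5, the optimum
of the three-class GQ sweep (below). The comparator is ≥ so edits at the
printed cutoffs survive. Application verifies every REF string against the
assembly (a REF mismatch is a hard error naming the locus), resolves
overlapping REF spans by higher GQ (tie: leftmost), and shifts coordinates
cumulatively.

## K-mer assessment

Canonical 31-mers (lexicographic minimum of the strand pair, 2-bit packed
into uint64) from trusted reads form the database; assembly k-mers with zero
count in it are error k-mers, reported as merged intervals. With B error
k-mers out of T, the per-base error rate is `E = 1 − (1 − B/T)^(1/k)`,
`QV = −10·log10(E)` (capped at 99 and flagged when B = 0), and
`errors/Mb = 10^(−QV/10) × 10^6` — the identity between the last two holds
to 1e−9 relative by construction. Improvement between two rounds is
`ΔQV = −10·log10(errors_after/errors_before)`, capped when the numerator
reaches zero.

Pre-/post-polishing tracks are reconciled by projecting the polished error
intervals onto raw coordinates through the per-contig global alignment:
fixed = raw-only, induced = projected-only, unchanged = intersection, with
base-count conservation (`fixed + unchanged = raw`,
`induced + unchanged = projected`) guaranteed; unprojectable polished
intervals are counted as induced (conservative) and reported separately.
Edits are labelled by intersection with the status classes (precedence
induces > fixes > no_change) and the GQ sweep exhaustively evaluates cutoff
vectors 0–25 under three scenarios (single cutoff; INS1 + rest; INS1 + DEL1
+ rest), scoring `errors_after = unchanged + induced(kept) − fixed(kept)`
and returning the lexicographically lowest argmax.

Residual-error context stratification counts error intervals by GC fraction
above 0.70, overlap with homopolymer runs ≥ 11 bp ("greater than 10 bp"),
and minimum read depth below 5× using the quantized bands [0,5), [5,10),
[10,150). Gene impact runs on supplied CDS pairs: affine-gap global
alignment (Biopython PairwiseAligner; affine scoring keeps one biological
gap as one run, which the multiple-of-three rule requires), frameshift iff
gap length mod 3 ≠ 0 or length > 30; premature stops are TAA/TAG/TGA codons
strictly before the terminal codon; nonsynonymous changes are codon
substitutions that alter the amino acid.

## The synthetic world

The generator is the package's study system, not a fixture. Defaults:

| parameter | default | rationale |
|---|---|---|
| contig length | 1 Mb diploid (2 × 1 Mb) | large enough for several read lengths and two collapsed regions |
| het SNV / indel rate | 1e−3 / 1e−4 per base | typical human-scale heterozygosity |
| collapsed intervals | 2 × 25 kb | longer than the longest HiFi read |
| het rate inside collapsed intervals | 0.25 × genome-wide | assemblers collapse where heterozygosity is locally low; also keeps correctly-assigned reads under the 0.002 ratio filter |
| draft error rate | 1.3e−5 SNV + 7e−6 indel (~1 / 50 kb) | sparse residual errors typical of a good draft |
| HiFi-like reads | mean 18 kb (max < 25 kb), 0.08% substitution + 0.02% indel, 40× | high-accuracy long reads |
| UL-like reads | mean 130 kb (min 100 kb), 0.4% + 0.1%, 15× | phasing evidence only |
| homopolymer indel multiplier | 8× inside runs ≥ 5 bp | the dominant long-read error mode |
| base qualities | constant 35 (HiFi) / 20 (UL), error bases 15 / 7 | deterministic featurization; quality does correlate with error in real data |

Haplotype 1 is the reference strand of the simulation and haplotype 2
carries every het alt — a pure labelling choice invisible to the pipeline.
Corruption reverts each het inside a designated interval on haplotype 2 and
mirrors haplotype 1's random errors there, so the two draft copies of a
collapsed region are byte-identical, exactly as an assembler emitting one
consensus twice would produce. Every corruption is recorded as the
VCF-style repair that undoes it; applying all repairs to the draft
reproduces the truth byte-exactly, which is the conservation oracle used
throughout the tests.

Reads are placed by a small truth-seeded aligner: each read is globally
aligned (edlib) to its expected locus on *both* draft haplotypes, the lower
edit distance wins, and ties within a 3-edit slop — the norm inside
collapsed regions — are broken by a seeded coin flip. This reproduces real
aligner ambiguity without leaking the truth assignment. Read starts are
uniform across (and truncated at) contig ends, keeping coverage flat edge
to edge; all randomness flows through one `numpy` generator per call, so a
seed reproduces byte-identical FASTA/FASTQ/SAM.

What the generator does *not* emulate: chimeric reads and adapter
artifacts, GC-dependent coverage bias, quality-score miscalibration,
segmental duplications and long tandem repeat arrays, and a separate
short-read library — the evaluation k-mer database is built from the
simulated HiFi reads (subsampled to ~15×), so the sequencing-bias
pathologies of short-read k-mer databases discussed in the literature are
out of scope here. Passing the end-to-end recovery tests therefore
demonstrates the machinery is correct and self-consistent, not that the
default consensus core matches a trained model's accuracy on real data.

## Problem sizes and reference results

The end-to-end study conditions (acceptance script and the recovery tests)
are a 2 × 1 Mb diploid with ~1 injected error / 50 kb per haplotype, two
25 kb collapsed intervals, 40× HiFi-like and 15× UL-like reads; a run takes
roughly 2–3 minutes on one CPU. Under those conditions the pipeline
restores the truth genome byte-exactly across the seeds exercised: 100% of
injected errors corrected (the acceptance bar is ≥ 90% in unique sequence),
zero unsupported edits (bar: < 1 per 500 kb), and ≥ 99% of reads
originating in collapsed regions assigned to their haplotype of origin
(bar: ≥ 95%). Raw-draft QV is ~47 and all error k-mers are removed, so the
reported ΔQV hits its 99 cap. Unit and oracle tests run on kilobase-scale
constructions in seconds.

## Numerical choices and edge cases

- All internal coordinates are 0-based half-open; 1-based conversion
  happens only at VCF write time. Reverse-strand projection normalizes to
  forward-read coordinates unless the caller asks for stored orientation
  (the scorer does, because it slices the stored, target-forward sequence).
- Soft clips consume query but project nowhere; hard clips consume nothing.
- Homozygosity length threshold is strict (`> 20,000`); a 20,000 run is
  excluded, 20,001 included. Candidate support is strict ≥ 3 ("more than
  two reads"). GQ thresholds are inclusive (≥) so edits at the printed
  optima are kept.
- Phase-block haplotype ties select A; edit-distance ties keep the current
  assignment; consensus ties keep the assembly base — all deterministic and
  logged at debug level.
- `delta_qv` with zero errors after polishing is capped at 99 (matching the
  QV cap); zero errors before is an error.
- Degenerate inputs: empty pileups call nothing; zero-coverage windows are
  skipped with a log entry; contigs shorter than the read-length minimum
  yield no reads with a warning; sweep with no edits returns cutoff 0.

## Known limitations

- The default consensus core is a stand-in for a trained sequence
  predictor; its GQ is a support-fraction convention and the shipped
  20/12/5 policy was derived for model-produced GQs, so with the default
  core the policy is exercised for its mechanics, not recalibrated.
- Multi-part (split) read alignments are treated independently; structural
  variation between haplotypes beyond small indels is out of scope.
- The mismatch-ratio filters are applied per alignment record, not per
  read.
- The phaser is greedy majority-vote, not weighted minimum error
  correction; with deep consistent UL coverage the two coincide, which the
  exhaustive-enumeration oracle test checks on small instances.
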