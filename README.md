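# hapolish

Phase-aware polishing of diploid genome assemblies, with a k-mer based
quality-assessment suite.

Even high-quality haplotype-resolved assemblies retain base-level errors —
mostly 1 bp indels in homopolymers — plus a subtler failure mode: regions
where genuinely heterozygous sequence was assembled identically on both
haplotypes (*false homozygosity*). When such a region is longer than a HiFi
read, the aligner assigns its reads to a haplotype at random, the pileup at
every het site is a useless 50/50 mixture, and the heterozygous corrections
are never made. `hapolish` is a toolkit for this problem, aimed at people
building or evaluating assembly-polishing pipelines:

- **`synthdata`** — seeded synthetic diploid genomes with designated
  collapsed regions, corrupted drafts with a recorded truth edit set, and
  HiFi-like / ultra-long (UL) ONT-like reads with truth alignments.
- **`alignio`** — alignment records with extended CIGARs, the
  gap-compressed mismatch ratio, interval projection (liftover) through
  alignments, and SAM/PAF/BED/FASTA/VCF I/O.
- **`pharaoh`** — read reassignment in identical stretches > 20 kb:
  heterozygous candidates from the mixed pileup (GQ ≥ 10), UL-read phasing
  into blocks, per-block haplotype selection, pseudo-polishing inside
  variant blocks, and per-read assignment by summed block edit distance.
- **`polisher`** — candidate positions (≥ 3 disagreeing reads), windows
  (≤ 100 bp, 50 bp grouping), pileup featurization, a pluggable sequence
  predictor (default: quality-weighted consensus), and left-normalized VCF
  edit emission.
- **`finalize`** — class-specific GQ filtering (1 bp insertions ≥ 20, 1 bp
  deletions ≥ 12, everything else ≥ 5) and verified edit application.
- **`evalkit`** — error k-mers and QV, fixed/induced/unchanged error
  tracks, edit annotation, exhaustive GQ-cutoff sweeps, error-context
  stratification, and frameshift / premature-stop / nonsynonymous screens.
- **`pipeline` / `cli`** — one configured end-to-end run and thin
  `hapolish` subcommands.

The core quantities follow the standard k-mer conventions: with B error
k-mers out of T assembly k-mers, the per-base error rate is
`E = 1 − (1 − B/T)^(1/k)` and `QV = −10·log10 E`; errors per megabase is
`10^(−QV/10)·10⁶`, and the improvement from polishing is
`ΔQV = −10·log10(errors_after / errors_before)`.

## A worked example

`examples/02_phase_reads.py` builds a 200 kb diploid with one 25 kb
collapsed region, simulates 40× HiFi-like and 15× UL-like reads, aligns
them to the draft, and runs the reassignment stage:

```
identical regions > 20 kb: 1
heterozygous candidates (GQ >= 10): 10
phase blocks: 1
reads re-scored: 220, moved: 42
assignment accuracy vs truth: 220/220
```

The haplotype-vs-haplotype alignment exposes one identical stretch (the
collapsed region plus its het-free shoulders); the mixed pileup yields ten
heterozygous candidates that the UL reads phase into a single block; 220
reads overlap the variant blocks and every one ends up on its haplotype of
origin — including the 42 the aligner had placed on the wrong haplotype.
`examples/03_polish_and_apply.py` continues to the polishing stage and
prints `polished == truth haplotype: True`: with ~30 reads supporting each
correction, the consensus restores the truth sequence byte-exactly. The
other examples cover world simulation, the k-mer QV machinery with the
GQ-cutoff sweep, and the gene-impact screens.

An equivalent shell session:

```
hapolish simulate --seed 3 --length 200000 --loh-count 1 --outdir world/
hapolish pharaoh --hap1 world/draft_hap1.fasta --hap2 world/draft_hap2.fasta \
    --hifi-sam world/hifi_draft.sam --ul-sam world/ul_draft.sam --outdir ph/
hapolish polish --hap1 world/draft_hap1.fasta --hap2 world/draft_hap2.fasta \
    --sam ph/pharaoh.sam --out-vcf edits.vcf
hapolish finalize --fasta world/draft_hap1.fasta --vcf edits.vcf --out polished.fasta
```

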