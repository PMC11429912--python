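"""Build a synthetic diploid world: truth genome, corrupted draft, reads.

The generator plants heterozygous variants on a 150 kb diploid contig, keeps
one 25 kb interval nearly het-free, and the corruption step collapses that
interval (the draft shows haplotype 1's sequence for both haplotypes) while
injecting random substitution/1 bp-indel errors — recording every repair.
"""

import dataclasses

from hapolish.synthdata import (
    HIFI_PROFILE,
    corrupt_assembly,
    generate_diploid,
    simulate_reads,
)

genome, truth = generate_diploid(
    seed=11, contig_length=150_000, loh_count=1, loh_length=25_000
)
draft, repairs = corrupt_assembly(genome, seed=12, truth=truth)
reads, origins = simulate_reads(
    genome, dataclasses.replace(HIFI_PROFILE, depth=10, seed=13)
)

iv = truth.loh_intervals["hap1"][0]
print(f"heterozygous variants: {len(truth.het_variants)}")
print(f"collapsed interval (hap1 coords): {iv.start}-{iv.end}")
print(f"truth repairs: hap1={len(repairs['hap1'])}, hap2={len(repairs['hap2'])}")
print(f"simulated reads: {len(reads)} (~10x per haplotype)")
# hap2 needs many more repairs: every het inside the collapsed interval was
# overwritten with hap1's allele and must be restored by polishing.
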