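"""Reassign reads inside a falsely homozygous region.

Inside the collapsed 25 kb interval both draft haplotypes are identical, so
the aligner assigns reads arbitrarily.  The phasing stage finds the identical
stretch from the haplotype-vs-haplotype alignment, calls heterozygous
candidates from the mixed pileup, phases them with ultra-long reads, and
re-scores every read against both pseudo-polished haplotypes.
"""

import dataclasses

from hapolish.pharaoh import run_pharaoh
from hapolish.synthdata import (
    HIFI_PROFILE,
    UL_PROFILE,
    align_reads_to_draft,
    corrupt_assembly,
    generate_diploid,
    simulate_reads,
)

genome, truth = generate_diploid(
    seed=3, contig_length=200_000, loh_count=1, loh_length=25_000
)
draft, _ = corrupt_assembly(genome, seed=4, truth=truth)
hifi, hifi_origins = simulate_reads(
    genome, dataclasses.replace(HIFI_PROFILE, depth=40, seed=5), "hifi"
)
ul, ul_origins = simulate_reads(
    genome, dataclasses.replace(UL_PROFILE, depth=15, seed=6), "ul"
)
hifi_alns = align_reads_to_draft(hifi, draft, truth, hifi_origins, seed=7)
ul_alns = align_reads_to_draft(ul, draft, truth, ul_origins, seed=8)

result = run_pharaoh(draft, hifi_alns, ul_alns)

correct = sum(
    1 for name, hap in result.assignments.items() if hap == hifi_origins[name][0]
)
print(f"identical regions > 20 kb: {len(result.regions)}")
print(f"heterozygous candidates (GQ >= 10): {len(result.candidates)}")
print(f"phase blocks: {len(result.phase_blocks)}")
print(f"reads re-scored: {len(result.assignments)}, moved: {result.n_moved}")
print(f"assignment accuracy vs truth: {correct}/{len(result.assignments)}")
# expect ~100%: each read covers several phased het sites, and the summed
# block edit distance picks its haplotype of origin.
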