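"""Polish a draft haplotype: candidates -> windows -> consensus -> edits.

A 100 kb haplotype is corrupted with random errors; reads simulated from the
truth are aligned back and the polisher proposes VCF-style edits wherever
three or more reads disagree with the draft.  Edits pass the class-specific
GQ policy (insertions 20, deletions 12, other 5) and are applied.
"""

import dataclasses

from hapolish.finalize import FilterPolicy, apply_edits, apply_gq_filters
from hapolish.polisher import polish_haplotype
from hapolish.synthdata import (
    HIFI_PROFILE,
    align_reads_to_draft,
    corrupt_assembly,
    generate_diploid,
    simulate_reads,
)

genome, truth = generate_diploid(seed=21, contig_length=100_000, loh_count=0)
draft, repairs = corrupt_assembly(
    genome, error_snv_rate=5e-5, error_indel_rate=3e-5, seed=22, truth=truth
)
reads, origins = simulate_reads(
    genome, dataclasses.replace(HIFI_PROFILE, depth=30, seed=23)
)
alns = align_reads_to_draft(reads, draft, truth, origins, seed=24)
primary = [a for a in alns if not a.is_secondary and a.target_name == "contig0#hap1"]

edits, windows = polish_haplotype("contig0#hap1", draft.haplotypes["hap1"]["contig0"], primary)
kept = apply_gq_filters(edits, FilterPolicy())
polished = apply_edits(draft.haplotypes["hap1"]["contig0"], kept)

print(f"injected errors on hap1: {len(repairs['hap1'])}")
print(f"candidate windows: {len(windows)}; proposed edits: {len(edits)}; kept: {len(kept)}")
print(f"polished == truth haplotype: {polished == genome.haplotypes['hap1']['contig0']}")
# every injected error is supported by ~30 disagreeing reads, so the
# consensus recovers the truth sequence exactly.
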