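"""Gene-impact screening of assembly errors in coding sequence.

Alignment gaps in a CDS are frameshifts when their length is not a multiple
of three or exceeds 30 bp; substitutions are screened for premature stop
codons and amino-acid changes.
"""

from hapolish.evalkit import (
    align_cds,
    detect_frameshifts,
    detect_nonsynonymous,
    detect_premature_stops,
)

ref_cds = "ATG" + "GAAGCTTGGCGTCTTACCGAT" * 3 + "TAA"

# a 4 bp deletion: frameshift
broken = ref_cds[:15] + ref_cds[19:]
aln = align_cds("tx1", ref_cds, broken)
print("4 bp gap frameshifts:", detect_frameshifts(aln))

# an in-frame 3 bp deletion: no frameshift
inframe = ref_cds[:15] + ref_cds[18:]
print("3 bp gap frameshifts:", detect_frameshifts(align_cds("tx2", ref_cds, inframe)))

# substitution creating an early stop (TGG -> TGA at codon 3)
stop = ref_cds[:11] + "A" + ref_cds[12:]
print("premature stop codons:", detect_premature_stops(stop))

# a nonsynonymous substitution (GAA -> CAA, Glu -> Gln)
missense = ref_cds[:3] + "C" + ref_cds[4:]
print("nonsynonymous changes:", detect_nonsynonymous(ref_cds, missense))
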