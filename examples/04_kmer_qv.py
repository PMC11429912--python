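"""K-mer quality assessment: QV, error tracks, and the GQ-cutoff sweep.

An assembly k-mer absent from the trusted read k-mer set marks a probable
error.  QV follows the survival form E = 1 - (1 - B/T)^(1/k); errors per Mb
is (10^(-QV/10)) * 1e6, and a polishing round's improvement is
delta_QV = -10*log10(errors_after / errors_before).
"""

import numpy as np

from hapolish.evalkit import (
    KmerDB,
    LabeledEdit,
    delta_qv,
    error_kmers,
    error_reduction,
    sweep_gq,
)
from hapolish.polisher import PolishEdit

rng = np.random.default_rng(31)
truth = "".join(rng.choice(list("ACGT"), 50_000))
db = KmerDB.from_sequences([truth], k=31)

# an "assembly" with three substitution errors
assembly = list(truth)
for p in (10_000, 25_000, 40_000):
    assembly[p] = "ACGT"[("ACGT".index(assembly[p]) + 1) % 4]
assembly = "".join(assembly)

intervals, report = error_kmers(assembly, db)
print(f"error k-mers: {report.error_kmers} in {len(intervals)} intervals")
print(f"QV = {report.qv:.2f}, errors/Mb = {report.errors_per_mb:.2f}")

d = delta_qv(report.error_kmers, 31)  # suppose polishing fixes two errors
print(f"fixing two of three errors: delta_QV = {d:.2f} "
      f"({100 * error_reduction(d):.0f}% error reduction)")

# GQ sweep on a toy annotated edit set: low-GQ 1 bp insertions induce
# errors, everything else fixes them -> optimum cuts only INS1
edits = [
    LabeledEdit(PolishEdit("c", 0, "A", "AT", gq), "induces", n_induced=1)
    for gq in (4, 7, 11)
] + [
    LabeledEdit(PolishEdit("c", 0, "A", "G", gq), "fixes", n_fixed=1)
    for gq in (6, 14, 23)
]
res = sweep_gq(edits, "ins1+rest", unchanged_errors=10)
print(f"optimal cutoffs: {res.cutoffs}, estimated delta_QV = {res.delta_qv:.2f}")
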