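"""Class-specific GQ filtering of proposed edits and their application.

The polishing model's raw edit set over-corrects in a class-specific way:
most error-inducing edits are 1 bp insertions or deletions.  Filtering
therefore uses three thresholds — by default GQ 20 for 1 bp insertions, GQ 12
for 1 bp deletions, GQ 5 for everything else — keeping an edit when its GQ is
greater than or equal to its class threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from ._seq import apply_variant_list
from .polisher import PolishEdit

log = logging.getLogger(__name__)

__all__ = ["FilterPolicy", "classify_edit", "apply_gq_filters", "apply_edits"]

INS1, DEL1, OTHER = "INS1", "DEL1", "OTHER"


@dataclass(frozen=True)
class FilterPolicy:
    min_gq_ins1: float = 20.0
    min_gq_del1: float = 12.0
    min_gq_other: float = 5.0

    def __post_init__(self):
        if min(self.min_gq_ins1, self.min_gq_del1, self.min_gq_other) < 0:
            raise ValueError("GQ thresholds must be non-negative")

    def threshold(self, edit_class: str) -> float:
        return {
            INS1: self.min_gq_ins1,
            DEL1: self.min_gq_del1,
            OTHER: self.min_gq_other,
        }[edit_class]


def classify_edit(edit: PolishEdit) -> str:
    """INS1 / DEL1 / OTHER for a normalized edit (anchored 1 bp indels)."""
    dlen = len(edit.alt) - len(edit.ref)
    if dlen == 1 and len(edit.ref) == 1:
        return INS1
    if dlen == -1 and len(edit.alt) == 1:
        return DEL1
    return OTHER


def apply_gq_filters(
    edits: Sequence[PolishEdit], policy: FilterPolicy = FilterPolicy()
) -> list[PolishEdit]:
    """Keep edits whose GQ meets their class threshold (idempotent)."""
    kept: list[PolishEdit] = []
    counts = {INS1: [0, 0], DEL1: [0, 0], OTHER: [0, 0]}
    for e in edits:
        cls = e.edit_class or classify_edit(e)
        e.edit_class = cls
        ok = e.gq >= policy.threshold(cls)
        counts[cls][0 if ok else 1] += 1
        if ok:
            kept.append(e)
    for cls, (n_kept, n_drop) in counts.items():
        log.debug("GQ filter %s: kept %d, removed %d", cls, n_kept, n_drop)
    return kept


def _resolve_overlaps(edits: list[PolishEdit]) -> list[PolishEdit]:
    """Among edits whose REF spans overlap, keep the higher GQ (tie: leftmost)."""
    chosen: list[PolishEdit] = []
    for e in sorted(edits, key=lambda e: (e.pos, e.pos + len(e.ref))):
        if chosen and e.pos < chosen[-1].pos + len(chosen[-1].ref):
            if e.gq > chosen[-1].gq:
                log.debug("overlap at %s:%d resolved to higher-GQ edit", e.contig, e.pos)
                chosen[-1] = e
            continue
        chosen.append(e)
    return chosen


def apply_edits(
    seq: str, edits: Sequence[PolishEdit], resolve_overlaps: bool = True
) -> str:
    """Apply VCF-style edits to a sequence with cumulative coordinate shifts.

    Edits must carry 0-based positions on ``seq``; REF strings are verified
    against the assembly and any disagreement is a hard error naming the
    locus.  Output length is input plus the summed length differences.
    """
    ordered = sorted(edits, key=lambda e: e.pos)
    if resolve_overlaps:
        ordered = _resolve_overlaps(ordered)
    return apply_variant_list(seq, [(e.pos, e.ref, e.alt) for e in ordered])
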