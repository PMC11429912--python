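"""Phase-aware read reassignment in long falsely homozygous regions.

Diploid assemblers sometimes emit a single sequence for both haplotypes of a
genuinely heterozygous region ("false homozygosity").  When such a region is
longer than a HiFi read, the aligner cannot tell the haplotypes apart and
assigns reads arbitrarily, which blocks any heterozygous polishing edit from
being recovered there.  This module re-assigns those reads using heterozygous
variants phased with ultra-long (UL) reads:

1. find identical stretches > 20 kb from the haplotype-vs-haplotype alignment;
2. call heterozygous candidates from the mixed HiFi pileup (reads with
   gap-compressed mismatch ratio > 0.02 removed first);
3. phase the candidates into blocks using UL reads > 100 kb;
4. per block, pick the block haplotype with more reference alleles (the one
   closer to the assembly); its alt alleles pseudo-polish assembly haplotype
   1 and the complementary alleles pseudo-polish haplotype 2, but only inside
   variant blocks built around the phased variants;
5. score each read against both pseudo-polished haplotypes by summed edit
   distance over the merged variant blocks and move it to the winner;
6. finally drop alignments with gap-compressed mismatch ratio > 0.002.

The genotyper (step 2) and phaser (step 3) are deliberately simple, pluggable
stand-ins for external tools: an externally produced phased variant list can
be passed to :func:`run_pharaoh` to bypass both.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import edlib
import numpy as np

from ._seq import apply_variant_list
from .alignio import (
    AlignmentRecord,
    GenomicInterval,
    gap_compressed_mismatch_ratio,
    merge_intervals,
    parse_cigar,
    project_intervals,
)
from .synthdata import HAPS, DiploidAssembly

log = logging.getLogger(__name__)

__all__ = [
    "HomozygousRegionPair",
    "PhasedVariant",
    "PhaseBlock",
    "VariantBlock",
    "align_hap_vs_hap",
    "find_homozygous_regions",
    "call_het_candidates",
    "phase_hets",
    "select_block_haplotype",
    "build_variant_blocks",
    "score_and_assign",
    "final_alignment_filter",
    "run_pharaoh",
    "PharaohResult",
]


@dataclass
class HomozygousRegionPair:
    """A maximal run of 100% identical sequence on both haplotypes."""

    hap1_interval: GenomicInterval
    hap2_interval: GenomicInterval
    length: int


@dataclass
class PhasedVariant:
    """A heterozygous candidate, optionally phased into a block.

    ``allele_on_hapA``/``allele_on_hapB`` take values ``"ref"``/``"alt"`` once
    the variant belongs to a phase block; the two block haplotypes carry
    different alleles by construction.
    """

    contig: str
    pos: int  # 0-based anchor on the calling haplotype
    ref: str
    alt: str
    gq: float
    block_id: int | None = None
    allele_on_hapA: str | None = None
    allele_on_hapB: str | None = None

    @property
    def span(self) -> int:
        return len(self.ref)


@dataclass
class PhaseBlock:
    block_id: int
    variants: list[PhasedVariant]
    selected_haplotype: str | None = None  # "A" or "B"


@dataclass
class VariantBlock:
    interval: GenomicInterval
    variants: list[PhasedVariant] = field(default_factory=list)


def align_hap_vs_hap(draft: DiploidAssembly, contig: str) -> AlignmentRecord:
    """Globally align draft hap2 (query) to draft hap1 (target) with edlib."""
    seq1 = draft.haplotypes["hap1"][contig]
    seq2 = draft.haplotypes["hap2"][contig]
    res = edlib.align(seq2, seq1, mode="NW", task="path")
    return AlignmentRecord(
        query_name=DiploidAssembly.full_name(contig, "hap2"),
        query_seq="",
        target_name=DiploidAssembly.full_name(contig, "hap1"),
        target_start=0,
        cigar=parse_cigar(res["cigar"]),
        tags={"NM": res["editDistance"]},
    )


def find_homozygous_regions(
    hap_vs_hap: Sequence[AlignmentRecord], min_len: int = 20_000
) -> list[HomozygousRegionPair]:
    """Maximal runs of consecutive ``=`` columns strictly longer than min_len.

    Intervals are reported on both haplotypes' coordinates.  CIGARs containing
    ``M`` are rejected: match/mismatch status would be ambiguous.
    """
    out = []
    for aln in hap_vs_hap:
        t = aln.target_start
        q = aln.query_aln_start
        run_t = run_q = run_len = 0
        in_run = False

        def flush():
            nonlocal in_run
            if in_run and run_len > min_len:
                out.append(
                    HomozygousRegionPair(
                        hap1_interval=GenomicInterval(aln.target_name, run_t, run_t + run_len),
                        hap2_interval=GenomicInterval(aln.query_name, run_q, run_q + run_len),
                        length=run_len,
                    )
                )
            in_run = False

        for op, n in aln.cigar:
            if op == "M":
                raise ValueError("find_homozygous_regions needs =/X CIGARs, got M")
            if op == "=":
                if not in_run:
                    run_t, run_q, run_len, in_run = t, q, 0, True
                run_len += n
                t += n
                q += n
            else:
                flush()
                if op == "X":
                    t += n
                    q += n
                elif op == "D":
                    t += n
                elif op in "IS":
                    q += n
        flush()
    return out


# ---------------------------------------------------------------------------
# Heterozygous candidate calling (pluggable stand-in genotyper)
# ---------------------------------------------------------------------------


def _genotype_loglik(n_ref: int, n_alt: int, error_rate: float) -> dict[str, float]:
    e = min(max(error_rate, 1e-6), 0.5)
    return {
        "RR": n_alt * math.log10(e) + n_ref * math.log10(1 - e),
        "RA": (n_ref + n_alt) * math.log10(0.5),
        "AA": n_ref * math.log10(e) + n_alt * math.log10(1 - e),
    }


def genotype_site(n_ref: int, n_alt: int, error_rate: float = 0.01) -> tuple[str, float]:
    """Maximum-likelihood diploid genotype under a symmetric-error binomial.

    Returns (genotype, GQ) where GQ is the phred-scaled gap between the best
    and second-best genotype log-likelihood, capped at 99.
    """
    ll = _genotype_loglik(n_ref, n_alt, error_rate)
    ranked = sorted(ll.items(), key=lambda kv: kv[1], reverse=True)
    gq = min(99.0, 10.0 * (ranked[0][1] - ranked[1][1]))
    return ranked[0][0], gq


def call_het_candidates(
    reads: Sequence[AlignmentRecord],
    region: GenomicInterval,
    ref_seq: str,
    error_rate: float = 0.01,
    min_gq: float = 10.0,
    max_indel_len: int = 10,
) -> list[PhasedVariant]:
    """Call heterozygous variants from a pileup over one homozygous region.

    ``reads`` are alignments to the region's haplotype-1 coordinates, already
    filtered by mismatch ratio.  Per locus, read evidence is reduced to
    ref/alt counts and genotyped with :func:`genotype_site`; only heterozygous
    calls with GQ >= ``min_gq`` are returned, sorted by position.
    """
    cov = np.zeros(len(region) + 1, dtype=np.int32)
    # allele evidence: key -> count.  SNV key: ("snv", pos, base);
    # insertion: ("ins", anchor, seq); deletion: ("del", anchor, length)
    counts: dict[tuple, int] = {}
    for aln in reads:
        t = aln.target_start
        q = aln.query_aln_start
        seq = aln.query_seq
        ov0 = max(t, region.start)
        ov1 = min(aln.target_end, region.end)
        if ov0 < ov1:
            cov[ov0 - region.start] += 1
            cov[ov1 - region.start] -= 1
        for op, n in aln.cigar:
            if op == "=":
                t += n
                q += n
            elif op == "X":
                for i in range(n):
                    p = t + i
                    if region.start <= p < region.end:
                        key = ("snv", p, seq[q + i])
                        counts[key] = counts.get(key, 0) + 1
                t += n
                q += n
            elif op == "D":
                anchor = t - 1
                if region.start <= anchor < region.end and n <= max_indel_len:
                    key = ("del", anchor, n)
                    counts[key] = counts.get(key, 0) + 1
                t += n
            elif op == "I":
                anchor = t - 1
                if region.start <= anchor < region.end and n <= max_indel_len:
                    key = ("ins", anchor, seq[q : q + n])
                    counts[key] = counts.get(key, 0) + 1
                q += n
            elif op in "SH":
                if op == "S":
                    q += n
    coverage = np.cumsum(cov[:-1])

    out: list[PhasedVariant] = []
    for key in sorted(counts, key=lambda k: (k[1], k[0])):
        kind, pos, payload = key
        n_alt = counts[key]
        depth = int(coverage[pos - region.start])
        if depth == 0:
            continue
        n_ref = max(0, depth - n_alt)
        genotype, gq = genotype_site(n_ref, n_alt, error_rate)
        if genotype != "RA" or gq < min_gq:
            continue
        contig = region.contig
        if kind == "snv":
            ref, alt = ref_seq[pos], payload
            if ref == alt:
                continue
        elif kind == "ins":
            ref = ref_seq[pos]
            alt = ref + payload
        else:  # del
            ref = ref_seq[pos : pos + 1 + payload]
            alt = ref_seq[pos]
            if len(ref) < 1 + payload:
                continue
        out.append(PhasedVariant(contig, pos, ref, alt, gq))
    out.sort(key=lambda v: v.pos)
    return out


# ---------------------------------------------------------------------------
# Phasing (pluggable stand-in phaser)
# ---------------------------------------------------------------------------


def read_allele_at(
    aln: AlignmentRecord, variant: PhasedVariant, ref_seq: str, flank: int = 12
) -> str | None:
    """Which allele ("ref"/"alt") does this alignment's read carry, if clear?

    The read subsequence covering the variant locus (plus a small flank) is
    compared by edit distance against the reference window and the window
    with the alt allele applied; the strictly closer one wins.  Ties and
    partial coverage return None.  Re-aligning locally makes the call
    indifferent to how the aligner placed indels inside repeat tracts.
    """
    w0 = variant.pos - flank
    w1 = variant.pos + variant.span + flank
    if not (aln.target_start <= w0 and w1 <= aln.target_end):
        return None
    proj = project_intervals(
        [GenomicInterval(aln.target_name, w0, w1)],
        aln,
        "target_to_query",
        normalize_strand=False,
    )
    if not proj:
        return None
    read_sub = aln.query_seq[proj[0].start : proj[0].end]
    if not read_sub:
        return None
    ref_win = ref_seq[w0:w1]
    alt_win = (
        ref_seq[w0 : variant.pos] + variant.alt + ref_seq[variant.pos + variant.span : w1]
    )
    d_ref = edlib.align(read_sub, ref_win, mode="NW")["editDistance"]
    d_alt = edlib.align(read_sub, alt_win, mode="NW")["editDistance"]
    if d_ref < d_alt:
        return "ref"
    if d_alt < d_ref:
        return "alt"
    return None


def phase_hets(
    candidates: list[PhasedVariant],
    ul_reads: Sequence[AlignmentRecord],
    ref_seq: str = "",
    min_ul_length: int = 100_000,
) -> list[PhaseBlock]:
    """Greedy majority-vote phasing of candidates using long reads.

    Variants co-covered by at least one UL read (length > ``min_ul_length``)
    join the same block; the relative phase of each adjacent pair is set by
    majority vote of the co-covering reads (cis when a read carries the same
    allele class at both sites).  Variants never co-covered become singleton
    blocks.  Block haplotype A is anchored to the reference allele of each
    block's first variant.
    """
    variants = sorted(candidates, key=lambda v: (v.contig, v.pos))
    n = len(variants)
    votes: dict[tuple[int, int], list[int]] = {}  # (i, j) -> [cis, trans]
    linked = np.zeros(max(0, n - 1), dtype=bool)
    for aln in ul_reads:
        if len(aln.query_seq) <= min_ul_length:
            continue
        covered: list[tuple[int, str]] = []
        for i, v in enumerate(variants):
            if v.contig != aln.target_name:
                continue
            if aln.target_start <= v.pos and v.pos + v.span <= aln.target_end:
                allele = read_allele_at(aln, v, ref_seq)
                if allele is not None:
                    covered.append((i, allele))
        for (i, ai), (j, aj) in zip(covered, covered[1:]):
            if j == i + 1:
                pass
            for kk in range(i, j):
                linked[kk] = True
            key = (i, j)
            votes.setdefault(key, [0, 0])[0 if ai == aj else 1] += 1

    blocks: list[PhaseBlock] = []
    block_id = 0
    i = 0
    while i < n:
        j = i
        while j + 1 < n and j < len(linked) and linked[j]:
            j += 1
        members = variants[i : j + 1]
        # propagate phase left to right; allele_on_hapA of first member = ref
        phase = "ref"
        for k, v in enumerate(members):
            if k > 0:
                key = (i + k - 1, i + k)
                cis, trans = votes.get(key, [1, 0])  # unvoted adjacency: cis
                same = cis >= trans
                prev = members[k - 1].allele_on_hapA
                phase = prev if same else ("alt" if prev == "ref" else "ref")
            v.allele_on_hapA = phase
            v.allele_on_hapB = "alt" if phase == "ref" else "ref"
            v.block_id = block_id
        blocks.append(PhaseBlock(block_id, members))
        block_id += 1
        i = j + 1
    return blocks


def select_block_haplotype(block: PhaseBlock) -> tuple[str, list[PhasedVariant]]:
    """Pick the block haplotype with more reference alleles (tie -> A).

    Returns the choice and the retained variants: those whose alt allele sits
    on the selected haplotype (the edits that make the assembly match it).
    """
    if not block.variants:
        raise ValueError("empty phase block")
    refs_a = sum(1 for v in block.variants if v.allele_on_hapA == "ref")
    refs_b = sum(1 for v in block.variants if v.allele_on_hapB == "ref")
    choice = "A" if refs_a >= refs_b else "B"
    if refs_a == refs_b:
        log.debug("block %d haplotype tie, choosing A", block.block_id)
    block.selected_haplotype = choice
    attr = "allele_on_hapA" if choice == "A" else "allele_on_hapB"
    retained = [v for v in block.variants if getattr(v, attr) == "alt"]
    return choice, retained


def build_variant_blocks(
    variants: list[PhasedVariant],
    min_block_size: int = 100,
    contig_length: int | None = None,
) -> list[VariantBlock]:
    """Windows around variants: width max(min_block_size, 2 x variant span).

    Windows are centered on the variant's reference span, clipped to contig
    bounds, and merged when they overlap, so one block may hold several
    variants.
    """
    raw: list[tuple[int, int, PhasedVariant]] = []
    for v in sorted(variants, key=lambda x: x.pos):
        width = max(min_block_size, 2 * v.span)
        start = v.pos - width // 2 + v.span // 2
        end = start + width
        if start < 0:
            start, end = 0, width
        if contig_length is not None and end > contig_length:
            end = contig_length
            start = max(0, end - width)
        raw.append((start, end, v))
    blocks: list[VariantBlock] = []
    for start, end, v in raw:
        if blocks and start <= blocks[-1].interval.end:
            last = blocks[-1]
            last.interval = GenomicInterval(
                v.contig, last.interval.start, max(last.interval.end, end)
            )
            last.variants.append(v)
        else:
            blocks.append(VariantBlock(GenomicInterval(v.contig, start, end), [v]))
    return blocks


# ---------------------------------------------------------------------------
# Read scoring
# ---------------------------------------------------------------------------


def _pseudo_polish(seq: str, variants: list[tuple[int, str, str]], start: int, end: int) -> str:
    """Apply variants falling fully inside [start, end) to seq[start:end)."""
    local = [
        (pos - start, ref, alt)
        for pos, ref, alt in sorted(variants)
        if start <= pos and pos + len(ref) <= end
    ]
    return apply_variant_list(seq[start:end], local)


def score_and_assign(
    alns_by_hap: dict[str, AlignmentRecord],
    current_hap: str,
    draft: DiploidAssembly,
    blocks_by_hap: dict[str, list[GenomicInterval]],
    retained_by_hap: dict[str, list[tuple[int, str, str]]],
) -> tuple[str, dict[str, int]]:
    """Assign a read to the haplotype it matches best inside variant blocks.

    The per-haplotype variant blocks are projected onto the read, merged on
    read coordinates, and each merged chunk is compared (edit distance)
    against both pseudo-polished haplotypes.  Sums are compared; a tie keeps
    the current assignment.  A read overlapping no block is returned
    unchanged.
    """
    read_ivs: list[GenomicInterval] = []
    for hap, aln in alns_by_hap.items():
        ivs = [iv for iv in blocks_by_hap.get(hap, []) if iv.overlaps(aln.target_interval)]
        read_ivs.extend(
            project_intervals(ivs, aln, "target_to_query", normalize_strand=False)
        )
    if not read_ivs:
        return current_hap, {}
    merged = merge_intervals(
        GenomicInterval("read", iv.start, iv.end) for iv in read_ivs
    )

    dist: dict[str, int] = {}
    for hap, aln in alns_by_hap.items():
        contig, _ = DiploidAssembly.split_name(aln.target_name)
        hap_seq = draft.haplotypes[hap][contig]
        total = 0
        for miv in merged:
            back = project_intervals(
                [GenomicInterval(aln.query_name, miv.start, miv.end)],
                aln,
                "query_to_target",
                normalize_strand=False,
            )
            if not back:
                total += len(miv)  # block absent on this haplotype
                continue
            tiv = back[0]
            polished = _pseudo_polish(
                hap_seq, retained_by_hap.get(hap, []), tiv.start, tiv.end
            )
            read_sub = aln.query_seq[miv.start : miv.end]
            if polished and read_sub:
                total += edlib.align(read_sub, polished, mode="NW")["editDistance"]
            else:
                total += max(len(polished), len(read_sub))
        dist[hap] = total

    best = min(dist.values())
    winners = [h for h, d in dist.items() if d == best]
    assigned = current_hap if current_hap in winners else winners[0]
    return assigned, dist


def final_alignment_filter(
    alns: Sequence[AlignmentRecord], max_ratio: float = 0.002
) -> list[AlignmentRecord]:
    """Keep alignments with gap-compressed mismatch ratio <= max_ratio."""
    return [a for a in alns if gap_compressed_mismatch_ratio(a) <= max_ratio]


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


@dataclass
class PharaohResult:
    final_alignments: list[AlignmentRecord]
    regions: list[HomozygousRegionPair]
    phase_blocks: list[PhaseBlock]
    candidates: list[PhasedVariant]
    assignments: dict[str, str]  # read name -> assigned hap, for scored reads
    n_moved: int = 0


def run_pharaoh(
    draft: DiploidAssembly,
    hifi_alns: Sequence[AlignmentRecord],
    ul_alns: Sequence[AlignmentRecord],
    min_homo_len: int = 20_000,
    min_block: int = 100,
    het_gq: float = 10.0,
    pre_ratio: float = 0.02,
    final_ratio: float = 0.002,
    ul_min_len: int = 100_000,
    error_rate: float = 0.01,
    external_variants: list[PhasedVariant] | None = None,
) -> PharaohResult:
    """Run the full reassignment pipeline on in-memory alignments.

    ``hifi_alns`` must contain, for every read, one primary record and one
    secondary record on the other haplotype (the usual diploid aligner
    output).  Outside the detected homozygous regions assignments pass
    through untouched (marker-mode reassignment is prior work and is a no-op
    hook here).
    """
    # index HiFi alignments per read
    per_read: dict[str, dict[str, AlignmentRecord]] = {}
    primary_hap: dict[str, str] = {}
    for aln in hifi_alns:
        contig, hap = DiploidAssembly.split_name(aln.target_name)
        per_read.setdefault(aln.query_name, {})[hap] = aln
        if not aln.is_secondary:
            primary_hap[aln.query_name] = hap

    regions: list[HomozygousRegionPair] = []
    all_blocks: list[PhaseBlock] = []
    all_candidates: list[PhasedVariant] = []
    assignments: dict[str, str] = {}
    n_moved = 0

    for contig in draft.haplotypes["hap1"]:
        hvh = align_hap_vs_hap(draft, contig)
        regions_c = find_homozygous_regions([hvh], min_homo_len)
        regions.extend(regions_c)
        h1_name = DiploidAssembly.full_name(contig, "hap1")
        seq1 = draft.haplotypes["hap1"][contig]

        for region in regions_c:
            r1, r2 = region.hap1_interval, region.hap2_interval
            # reads whose alignment to either haplotype overlaps the region
            names = set()
            for name, by_hap in per_read.items():
                a1 = by_hap.get("hap1")
                a2 = by_hap.get("hap2")
                if a1 is not None and a1.target_name == h1_name and a1.target_interval.overlaps(r1):
                    names.add(name)
                elif a2 is not None and a2.target_interval.overlaps(r2):
                    names.add(name)
            pile = []
            for name in names:
                a1 = per_read[name].get("hap1")
                if a1 is None or a1.target_name != h1_name:
                    continue
                if gap_compressed_mismatch_ratio(a1) <= pre_ratio:
                    pile.append(a1)

            if external_variants is not None:
                candidates = [
                    v
                    for v in external_variants
                    if v.contig == h1_name and r1.start <= v.pos < r1.end
                ]
            else:
                candidates = call_het_candidates(
                    pile, r1, seq1, error_rate=error_rate, min_gq=het_gq
                )
            all_candidates.extend(candidates)
            if not candidates:
                continue

            # all UL alignments to hap1 coordinates: inside an identical
            # region the primary/secondary choice is arbitrary
            ul_here = [
                a
                for a in ul_alns
                if a.target_name == h1_name and a.target_interval.overlaps(r1)
            ]
            if external_variants is not None and all(
                v.allele_on_hapA is not None for v in candidates
            ):
                blocks = _blocks_from_phased(candidates)
            else:
                blocks = phase_hets(candidates, ul_here, seq1, ul_min_len)
            all_blocks.extend(blocks)

            offset = r2.start - r1.start
            retained_h1: list[tuple[int, str, str]] = []
            retained_h2: list[tuple[int, str, str]] = []
            phased: list[PhasedVariant] = []
            for block in blocks:
                _, retained = select_block_haplotype(block)
                retained_h1.extend((v.pos, v.ref, v.alt) for v in retained)
                other = set(id(v) for v in retained)
                retained_h2.extend(
                    (v.pos + offset, v.ref, v.alt)
                    for v in block.variants
                    if id(v) not in other
                )
                phased.extend(block.variants)

            vblocks1 = build_variant_blocks(phased, min_block, len(seq1))
            blocks_by_hap = {
                "hap1": [b.interval for b in vblocks1],
                "hap2": [
                    GenomicInterval(
                        DiploidAssembly.full_name(contig, "hap2"),
                        b.interval.start + offset,
                        b.interval.end + offset,
                    )
                    for b in vblocks1
                ],
            }

            for name in sorted(names):
                by_hap = per_read[name]
                if "hap1" not in by_hap or "hap2" not in by_hap:
                    continue
                cur = primary_hap.get(name, "hap1")
                new, _dist = score_and_assign(
                    by_hap, cur, draft, blocks_by_hap,
                    {"hap1": retained_h1, "hap2": retained_h2},
                )
                assignments[name] = new
                if new != cur:
                    n_moved += 1
                    primary_hap[name] = new
                    for hap, aln in by_hap.items():
                        aln.is_secondary = hap != new

    finals = [a for a in hifi_alns if not a.is_secondary]
    finals = final_alignment_filter(finals, final_ratio)
    return PharaohResult(
        final_alignments=finals,
        regions=regions,
        phase_blocks=all_blocks,
        candidates=all_candidates,
        assignments=assignments,
        n_moved=n_moved,
    )


def _blocks_from_phased(variants: list[PhasedVariant]) -> list[PhaseBlock]:
    by_block: dict[int, list[PhasedVariant]] = {}
    for v in variants:
        by_block.setdefault(v.block_id or 0, []).append(v)
    return [
        PhaseBlock(bid, sorted(vs, key=lambda v: v.pos))
        for bid, vs in sorted(by_block.items())
    ]
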