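"""Candidate-window polishing: featurization, consensus prediction, VCF edits.

The polishing front end scans read alignments for positions where three or
more reads disagree with the assembly, groups nearby candidates into windows
of at most 100 bp, and builds a tensor-like pileup representation of each
window (base, match/mismatch flag, base quality, mapping quality — one row
per read, one column per reference position plus one slot per distinct
insertion locus).

The sequence predictor behind the window interface is pluggable.  The default
core is a deterministic quality-weighted pileup consensus: per column the
allele with the greatest summed weight wins, with weight ``1 - 10^(-q/10)``
per supporting read, and an insertion is only emitted when its summed weight
exceeds half the column total.  A trained model can replace it behind the
same ``FeatureTensor -> (sequence, support)`` contract; the genotype-quality
scale of the default core (phred of one minus the winning support fraction)
is its own convention, not a learned confidence.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Callable, Sequence

import edlib
import numpy as np

from .alignio import AlignmentRecord, GenomicInterval, parse_cigar

__all__ = [
    "CandidateWindow",
    "FeatureTensor",
    "PolishEdit",
    "find_candidate_positions",
    "group_windows",
    "featurize_window",
    "predict_sequence",
    "edits_from_diff",
    "polish_haplotype",
]

GAP_CODE = 4
PAD_CODE = 5
_BASE_CODES = {b: i for i, b in enumerate("ACGT")}

MATCH, MISMATCH, NA = 0, 1, 2


@dataclass
class CandidateWindow:
    contig: str
    interval: GenomicInterval  # span <= max_span
    candidate_positions: list[int]


@dataclass
class FeatureTensor:
    """Pileup representation of one candidate window.

    Columns follow reference order; an insertion locus observed in any read
    adds one column directly after its anchor.  ``columns`` holds
    ``(ref_pos, 0)`` for reference columns and ``(anchor_pos, 1)`` for
    insertion slots.  ``ins_strings[row][col]`` carries the full inserted
    sequence for insertion slots (the base channel stores its first base).
    """

    bases: np.ndarray  # uint8 (rows, cols): 0-3 ACGT, 4 gap, 5 pad
    match: np.ndarray  # uint8: 0 match, 1 mismatch, 2 n/a
    baseq: np.ndarray  # uint8
    mapq: np.ndarray  # uint8
    columns: list[tuple[int, int]]
    ref_start: int
    ref_seq: str
    read_names: list[str] = field(default_factory=list)
    ins_strings: dict[tuple[int, int], str] = field(default_factory=dict)

    @property
    def n_rows(self) -> int:
        return self.bases.shape[0]


def find_candidate_positions(
    window: GenomicInterval,
    reads: Sequence[AlignmentRecord],
    min_support: int = 3,
    ref_seq: str | None = None,
) -> list[int]:
    """Positions where >= min_support distinct reads disagree with the assembly.

    A read disagrees at a position if it carries a mismatch there, a deletion
    covering it, or an insertion anchored immediately after it.  Each read
    counts once per position regardless of how it disagrees.
    """
    counts: dict[int, int] = {}
    for aln in reads:
        t = aln.target_start
        q = aln.query_aln_start
        hit: set[int] = set()
        for op, n in aln.cigar:
            if op == "=":
                t += n
                q += n
            elif op == "X":
                for p in range(t, t + n):
                    if window.start <= p < window.end:
                        hit.add(p)
                t += n
                q += n
            elif op == "D":
                for p in range(t, t + n):
                    if window.start <= p < window.end:
                        hit.add(p)
                t += n
            elif op == "I":
                anchor = t - 1
                if window.start <= anchor < window.end:
                    hit.add(anchor)
                q += n
            elif op == "S":
                q += n
        for p in hit:
            counts[p] = counts.get(p, 0) + 1
    return sorted(p for p, c in counts.items() if c >= min_support)


def group_windows(
    positions: Sequence[int],
    contig: str = "",
    max_gap: int = 50,
    max_span: int = 100,
) -> list[CandidateWindow]:
    """Greedy left-to-right chaining of candidate positions into windows.

    The current window extends while the next position is within ``max_gap``
    of the previous one and the total span stays within ``max_span``; every
    position lands in exactly one window.
    """
    out: list[CandidateWindow] = []
    cur: list[int] = []
    for p in positions:
        if cur and (p - cur[-1] > max_gap or p - cur[0] + 1 > max_span):
            out.append(
                CandidateWindow(contig, GenomicInterval(contig, cur[0], cur[-1] + 1), cur)
            )
            cur = []
        cur = cur + [p] if cur else [p]
    if cur:
        out.append(
            CandidateWindow(contig, GenomicInterval(contig, cur[0], cur[-1] + 1), cur)
        )
    return out


def _stable_order(names: list[str]) -> list[int]:
    keyed = sorted(
        range(len(names)),
        key=lambda i: hashlib.sha1(names[i].encode()).hexdigest(),
    )
    return keyed


def featurize_window(
    window: CandidateWindow,
    reads: Sequence[AlignmentRecord],
    ref_seq: str,
    depth_cap: int = 30,
    flank: int = 5,
) -> FeatureTensor | None:
    """Build the pileup tensor for one window (None when coverage is zero).

    Rows beyond ``depth_cap`` are dropped by a deterministic subsample (reads
    ordered by the SHA-1 of their names), so the tensor is identical across
    runs and platforms.
    """
    start = max(0, window.interval.start - flank)
    end = min(len(ref_seq), window.interval.end + flank)
    overlapping = [
        a for a in reads if a.target_start < end and a.target_end > start
    ]
    if not overlapping:
        return None
    order = _stable_order([a.query_name for a in overlapping])
    rows = [overlapping[i] for i in order[:depth_cap]]

    # first pass: per-read cell extraction + insertion loci
    per_read_cells: list[dict[int, tuple[int, int, int]]] = []  # pos -> (code, flag, q)
    per_read_ins: list[dict[int, tuple[str, int]]] = []  # anchor -> (seq, q)
    ins_loci: set[int] = set()
    for aln in rows:
        t = aln.target_start
        q = aln.query_aln_start
        quals = aln.query_quals or [30] * len(aln.query_seq)
        cells: dict[int, tuple[int, int, int]] = {}
        ins: dict[int, tuple[str, int]] = {}
        prev_q = 30
        for op, n in aln.cigar:
            if op in "=X":
                flag = MATCH if op == "=" else MISMATCH
                for i in range(n):
                    p = t + i
                    if start <= p < end:
                        base = aln.query_seq[q + i]
                        cells[p] = (_BASE_CODES.get(base, PAD_CODE), flag, quals[q + i])
                prev_q = quals[q + n - 1]
                t += n
                q += n
            elif op == "D":
                for i in range(n):
                    p = t + i
                    if start <= p < end:
                        cells[p] = (GAP_CODE, NA, prev_q)
                t += n
            elif op == "I":
                anchor = t - 1
                if start <= anchor < end:
                    ins[anchor] = (aln.query_seq[q : q + n], min(quals[q : q + n]))
                    ins_loci.add(anchor)
                q += n
            elif op == "S":
                q += n
        per_read_cells.append(cells)
        per_read_ins.append(ins)

    columns: list[tuple[int, int]] = []
    for p in range(start, end):
        columns.append((p, 0))
        if p in ins_loci:
            columns.append((p, 1))

    n_rows, n_cols = len(rows), len(columns)
    bases = np.full((n_rows, n_cols), PAD_CODE, dtype=np.uint8)
    match = np.full((n_rows, n_cols), NA, dtype=np.uint8)
    baseq = np.zeros((n_rows, n_cols), dtype=np.uint8)
    mapq = np.zeros((n_rows, n_cols), dtype=np.uint8)
    ins_strings: dict[tuple[int, int], str] = {}

    for r, aln in enumerate(rows):
        for c, (pos, is_ins) in enumerate(columns):
            if is_ins:
                got = per_read_ins[r].get(pos)
                if got is not None:
                    s, qmin = got
                    bases[r, c] = _BASE_CODES.get(s[0], PAD_CODE)
                    match[r, c] = MISMATCH
                    baseq[r, c] = qmin
                    mapq[r, c] = aln.mapq
                    ins_strings[(r, c)] = s
                elif pos in per_read_cells[r]:
                    # read covers the junction but has no insertion
                    bases[r, c] = GAP_CODE
                    match[r, c] = NA
                    baseq[r, c] = per_read_cells[r][pos][2]
                    mapq[r, c] = aln.mapq
            else:
                got = per_read_cells[r].get(pos)
                if got is not None:
                    bases[r, c], match[r, c], baseq[r, c] = got
                    mapq[r, c] = aln.mapq
    return FeatureTensor(
        bases=bases,
        match=match,
        baseq=baseq,
        mapq=mapq,
        columns=columns,
        ref_start=start,
        ref_seq=ref_seq[start:end],
        read_names=[a.query_name for a in rows],
        ins_strings=ins_strings,
    )


def _weight(q: np.ndarray | int) -> np.ndarray | float:
    return 1.0 - 10.0 ** (-np.asarray(q, dtype=float) / 10.0)


def predict_sequence(tensor: FeatureTensor) -> tuple[str, list[float]]:
    """Quality-weighted pileup consensus over the window.

    Returns the predicted sequence and one support fraction (winning weight /
    column total weight) per emitted base.  Columns with no read evidence
    retain the assembly base with support 0.
    """
    if tensor.n_rows == 0:
        raise ValueError("empty tensor")
    out: list[str] = []
    support: list[float] = []
    for c, (pos, is_ins) in enumerate(tensor.columns):
        col_bases = tensor.bases[:, c]
        col_q = tensor.baseq[:, c]
        covered = col_bases != PAD_CODE
        if is_ins:
            total = float(np.sum(_weight(col_q[covered])))
            if total <= 0:
                continue
            alleles: dict[str, float] = {}
            for r in np.flatnonzero(covered):
                s = tensor.ins_strings.get((int(r), c))
                if s is not None:
                    alleles[s] = alleles.get(s, 0.0) + float(_weight(int(col_q[r])))
            if not alleles:
                continue
            best_seq, best_w = max(alleles.items(), key=lambda kv: (kv[1], kv[0]))
            if best_w > total / 2.0:
                frac = best_w / total
                out.append(best_seq)
                support.extend([frac] * len(best_seq))
            continue
        ref_base = tensor.ref_seq[pos - tensor.ref_start]
        if not covered.any():
            out.append(ref_base)
            support.append(0.0)
            continue
        weights = np.zeros(5)  # A C G T gap
        for r in np.flatnonzero(covered):
            code = int(col_bases[r])
            if code <= GAP_CODE:
                weights[code] += float(_weight(int(col_q[r])))
        total = float(weights.sum())
        ref_code = _BASE_CODES.get(ref_base, 0)
        best = int(np.argmax(weights))
        # deterministic tie-break in favour of the assembly base
        if weights[best] == weights[ref_code]:
            best = ref_code
        frac = float(weights[best]) / total if total > 0 else 0.0
        if best == GAP_CODE:
            continue  # deletion: emit nothing
        out.append("ACGT"[best])
        support.append(frac)
    return "".join(out), support


@dataclass
class PolishEdit:
    """A VCF-style proposed correction (internal coordinates are 0-based)."""

    contig: str
    pos: int
    ref: str
    alt: str
    gq: float
    edit_class: str | None = None

    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref, self.alt)


def _left_normalize(
    seq: str, pos: int, ref: str, alt: str, lower_bound: int = 0
) -> tuple[int, str, str]:
    """Trim shared affixes, then roll an indel leftwards through repeats."""
    # trim common suffix down to one base
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # trim common prefix, keeping anchors for indels
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    # roll left
    while pos > lower_bound and len(ref) != len(alt) and ref[-1] == alt[-1]:
        prev = seq[pos - 1]
        ref = prev + ref[:-1]
        alt = prev + alt[:-1]
        pos -= 1
    return pos, ref, alt


def edits_from_diff(
    assembly_seq: str,
    predicted_seq: str,
    support: Sequence[float],
    contig: str = "",
    offset: int = 0,
) -> list[PolishEdit]:
    """Express predicted-vs-assembly differences as left-normalized VCF edits.

    SNVs come out as single-base records (adjacent substitutions are never
    merged into MNPs); indels carry a preceding anchor base.  The GQ of a
    record is the phred of one minus the smallest support fraction among the
    predicted positions it covers, capped at 99.
    """
    if assembly_seq == predicted_seq:
        return []
    res = edlib.align(predicted_seq, assembly_seq, mode="NW", task="path")
    cigar = parse_cigar(res["cigar"])

    # collect difference events as (op, t0, t1, q0, q1)
    events: list[tuple[str, int, int, int, int]] = []
    t = q = 0
    for op, n in cigar:
        if op == "=":
            t += n
            q += n
        elif op == "X":
            events.append(("X", t, t + n, q, q + n))
            t += n
            q += n
        elif op == "D":
            events.append(("D", t, t + n, q, q))
            t += n
        elif op == "I":
            events.append(("I", t, t, q, q + n))
            q += n

    # cluster events separated by <= 2 matched bases when an indel is
    # involved: a split representation of one complex local change (e.g. a
    # 2 bp insertion emitted as two 1 bp insertions by the aligner) becomes a
    # single replacement record.  Pure substitution runs stay per-column.
    clusters: list[list[tuple[str, int, int, int, int]]] = []
    for ev in events:
        if (
            clusters
            and ev[1] - clusters[-1][-1][2] <= 2
            and (ev[0] in "ID" or any(e[0] in "ID" for e in clusters[-1]))
        ):
            clusters[-1].append(ev)
        else:
            clusters.append([ev])

    def gq_from(fracs: list[float]) -> float:
        s = min(fracs) if fracs else 0.0
        return min(99.0, -10.0 * float(np.log10(max(1.0 - s, 1e-10))))

    def supports(q0: int, q1: int) -> list[float]:
        got = [support[i] for i in range(q0, min(q1, len(support)))]
        if not got and 0 < q0 <= len(support):
            got = [support[q0 - 1]]  # pure deletion: anchor support
        return got

    edits: list[PolishEdit] = []
    last_end = 0
    for cluster in clusters:
        only_x = all(e[0] == "X" for e in cluster)
        if only_x:
            for _, t0, t1, q0, _ in cluster:
                for i in range(t1 - t0):
                    edits.append(
                        PolishEdit(
                            contig,
                            t0 + i,
                            assembly_seq[t0 + i],
                            predicted_seq[q0 + i],
                            gq_from(supports(q0 + i, q0 + i + 1)),
                        )
                    )
            last_end = cluster[-1][2]
            continue
        t0, q0 = cluster[0][1], cluster[0][3]
        t1, q1 = cluster[-1][2], cluster[-1][4]
        if t0 > 0:
            pos = t0 - 1
            ref = assembly_seq[pos:t1]
            alt = assembly_seq[pos] + predicted_seq[q0:q1]
        else:  # anchor on the right instead
            pos = 0
            ref = assembly_seq[: t1 + 1]
            alt = predicted_seq[q0:q1] + assembly_seq[t1]
        gq = gq_from(supports(q0, q1))
        pos, ref, alt = _left_normalize(assembly_seq, pos, ref, alt, last_end)
        if ref != alt:
            edits.append(PolishEdit(contig, pos, ref, alt, gq))
            last_end = pos + len(ref)
    for e in edits:
        e.pos += offset
    return edits


def polish_haplotype(
    contig_name: str,
    ref_seq: str,
    reads: Sequence[AlignmentRecord],
    min_support: int = 3,
    max_gap: int = 50,
    max_span: int = 100,
    depth_cap: int = 30,
    scan_window: int = 25_000,
    scan_overlap: int = 1_000,
    predictor: Callable[[FeatureTensor], tuple[str, list[float]]] = predict_sequence,
) -> tuple[list[PolishEdit], list[CandidateWindow]]:
    """Scan one haplotype contig and emit proposed edits.

    The contig is scanned in 25 kb windows overlapping by 1 kb so candidate
    groups at scan boundaries are never split; candidate positions are
    deduplicated across tiles.
    """
    reads = [a for a in reads if a.target_name == contig_name]
    reads.sort(key=lambda a: a.target_start)
    starts = np.array([a.target_start for a in reads], dtype=np.int64)
    ends = np.array([a.target_end for a in reads], dtype=np.int64)

    def overlapping(s: int, e: int) -> list[AlignmentRecord]:
        idx = np.flatnonzero((starts < e) & (ends > s))
        return [reads[i] for i in idx]

    candidates: set[int] = set()
    L = len(ref_seq)
    step = scan_window - scan_overlap
    for w0 in range(0, max(1, L), step):
        w1 = min(L, w0 + scan_window)
        tile = GenomicInterval(contig_name, w0, w1)
        cand = find_candidate_positions(tile, overlapping(w0, w1), min_support, ref_seq)
        candidates.update(cand)
        if w1 >= L:
            break

    windows = group_windows(sorted(candidates), contig_name, max_gap, max_span)
    edits: list[PolishEdit] = []
    for window in windows:
        tensor = featurize_window(
            window, overlapping(window.interval.start - 10, window.interval.end + 10),
            ref_seq, depth_cap=depth_cap,
        )
        if tensor is None or tensor.n_rows == 0:
            continue
        predicted, support = predictor(tensor)
        window_assembly = tensor.ref_seq
        edits.extend(
            edits_from_diff(
                window_assembly, predicted, support, contig_name, tensor.ref_start
            )
        )
    # windows overlap their flanks; dedupe identical records
    seen = set()
    unique: list[PolishEdit] = []
    for e in sorted(edits, key=lambda e: (e.pos, e.ref, e.alt)):
        if e.key() not in seen:
            seen.add(e.key())
            unique.append(e)
    return unique, windows
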