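"""K-mer based quality assessment, edit annotation, and gene-impact analysis.

The assessment machinery mirrors the standard k-mer QV workflow: assembly
k-mers absent from a trusted read k-mer set are "error k-mers"; the per-base
error rate is estimated as ``E = 1 - (1 - B/T)^(1/k)`` from B error k-mers
out of T, and ``QV = -10 log10 E``.  Errors per megabase follow
``(10^(-QV/10)) * 1e6``.  Pre-/post-polishing error tracks are reconciled by
projecting the polished track onto raw-assembly coordinates through the
raw-vs-polished alignment and classifying every interval as fixed, induced or
unchanged; polishing edits are then labelled by intersection with those
classes, which feeds the GQ-cutoff sweep.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import edlib
import numpy as np
from Bio.Seq import Seq

from ._seq import homopolymer_runs, seq_to_codes
from .alignio import (
    AlignmentRecord,
    GenomicInterval,
    merge_intervals,
    parse_cigar,
    project_intervals,
)
from .polisher import PolishEdit

log = logging.getLogger(__name__)

__all__ = [
    "KmerDB",
    "QVReport",
    "ErrorKmerTrack",
    "error_kmers",
    "delta_qv",
    "error_reduction",
    "annotate_error_kmers",
    "annotate_edits",
    "LabeledEdit",
    "sweep_gq",
    "SweepResult",
    "stratify_error_context",
    "CdsAlignment",
    "align_cds",
    "detect_frameshifts",
    "detect_premature_stops",
    "detect_nonsynonymous",
]

QV_CAP = 99.0
STOP_CODONS = {"TAA", "TAG", "TGA"}


def _kmer_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical k-mer integers for every window, plus a validity mask."""
    codes = seq_to_codes(seq)
    n = len(codes) - k + 1
    if n <= 0:
        return np.zeros(0, dtype=np.uint64), np.zeros(0, dtype=bool)
    bad = (codes == 4).astype(np.int32)
    bad_run = np.convolve(bad, np.ones(k, dtype=np.int32), mode="valid")
    valid = bad_run == 0
    safe = np.where(codes == 4, 0, codes).astype(np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    rc = (np.uint64(3) - safe).astype(np.uint64)
    for j in range(k):
        fwd |= safe[j : j + n] << np.uint64(2 * (k - 1 - j))
        rev |= rc[j : j + n] << np.uint64(2 * j)
    return np.minimum(fwd, rev), valid


class KmerDB:
    """Sorted canonical k-mer set built from trusted reads (or any sequences)."""

    def __init__(self, kmers: np.ndarray, k: int):
        self.kmers = np.unique(kmers)
        self.k = k

    @classmethod
    def from_sequences(cls, seqs: Iterable[str], k: int = 31) -> "KmerDB":
        chunks = []
        for seq in seqs:
            km, valid = _kmer_codes(seq, k)
            if km.size:
                chunks.append(np.unique(km[valid]))
        allk = np.concatenate(chunks) if chunks else np.zeros(0, dtype=np.uint64)
        return cls(allk, k)

    def __len__(self) -> int:
        return int(self.kmers.size)

    def contains(self, kmers: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.kmers, kmers)
        idx = np.minimum(idx, max(0, self.kmers.size - 1))
        if self.kmers.size == 0:
            return np.zeros(kmers.shape, dtype=bool)
        return self.kmers[idx] == kmers


@dataclass
class QVReport:
    """K-mer survey of one assembly (or region thereof)."""

    total_kmers: int
    error_kmers: int
    k: int
    qv: float
    errors_per_mb: float
    region_label: str = ""
    capped: bool = False


def _qv_from_counts(total: int, errors: int, k: int, label: str = "") -> QVReport:
    if total <= 0:
        raise ValueError("no k-mers to assess")
    capped = errors == 0
    if capped:
        qv = QV_CAP
    else:
        err_rate = 1.0 - (1.0 - errors / total) ** (1.0 / k)
        qv = -10.0 * math.log10(err_rate)
        if qv > QV_CAP:
            qv, capped = QV_CAP, True
    errors_per_mb = 10.0 ** (-qv / 10.0) * 1e6
    return QVReport(total, errors, k, qv, errors_per_mb, label, capped)


def error_kmers(
    assembly_seq: str,
    read_db: KmerDB,
    k: int | None = None,
    contig: str = "contig",
    region_label: str = "",
) -> tuple[list[GenomicInterval], QVReport]:
    """Error k-mer intervals and QV for one contig against a read k-mer set.

    An error k-mer is an assembly k-mer with zero count in the read database;
    adjacent error k-mers are merged into intervals covering all their bases.
    """
    k = k or read_db.k
    if len(assembly_seq) < k:
        raise ValueError(f"sequence shorter than k={k}")
    kmers, valid = _kmer_codes(assembly_seq, k)
    present = read_db.contains(kmers)
    err_pos = np.flatnonzero(valid & ~present)
    intervals = merge_intervals(
        GenomicInterval(contig, int(p), int(p) + k) for p in err_pos
    )
    report = _qv_from_counts(int(valid.sum()), int(err_pos.size), k, region_label)
    return intervals, report


def assembly_qv(
    seqs: dict[str, str], read_db: KmerDB, k: int | None = None, region_label: str = ""
) -> tuple[list[GenomicInterval], QVReport]:
    """Aggregate error k-mers and QV over several contigs."""
    k = k or read_db.k
    total = errors = 0
    intervals: list[GenomicInterval] = []
    for name, seq in seqs.items():
        ivs, rep = error_kmers(seq, read_db, k, contig=name)
        intervals.extend(ivs)
        total += rep.total_kmers
        errors += rep.error_kmers
    return intervals, _qv_from_counts(total, errors, k, region_label)


def delta_qv(errors_before: float, errors_after: float, max_delta: float = QV_CAP) -> float:
    """QV improvement from error-k-mer counts: -10*log10(after/before)."""
    if errors_before <= 0:
        raise ValueError("errors_before must be positive")
    if errors_after <= 0:
        return max_delta
    return min(max_delta, -10.0 * math.log10(errors_after / errors_before))


def error_reduction(delta: float) -> float:
    """Fractional error reduction implied by a QV improvement."""
    return 1.0 - 10.0 ** (-delta / 10.0)


# ---------------------------------------------------------------------------
# Fixed / induced / unchanged bookkeeping
# ---------------------------------------------------------------------------

FIXED, INDUCED, UNCHANGED = "fixed", "induced", "unchanged"


@dataclass
class ErrorKmerTrack:
    """Status-annotated error intervals in raw-assembly coordinates."""

    intervals: list[GenomicInterval] = field(default_factory=list)
    status: list[str] = field(default_factory=list)
    base_counts: dict[str, int] = field(default_factory=dict)
    interval_counts: dict[str, int] = field(default_factory=dict)
    unprojected_induced_bases: int = 0

    def by_status(self, status: str) -> list[GenomicInterval]:
        return [iv for iv, s in zip(self.intervals, self.status) if s == status]


def align_assemblies(raw: dict[str, str], polished: dict[str, str]) -> list[AlignmentRecord]:
    """Globally align each polished contig (query) to its raw twin (target)."""
    out = []
    for name, raw_seq in raw.items():
        res = edlib.align(polished[name], raw_seq, mode="NW", task="path")
        out.append(
            AlignmentRecord(
                query_name=name,
                query_seq="",
                target_name=name,
                target_start=0,
                cigar=parse_cigar(res["cigar"]),
            )
        )
    return out


def annotate_error_kmers(
    raw_track: Sequence[GenomicInterval],
    polished_track: Sequence[GenomicInterval],
    raw_vs_polished: Sequence[AlignmentRecord],
    contig_lengths: dict[str, int],
) -> ErrorKmerTrack:
    """Classify error intervals as fixed, induced or unchanged by polishing.

    The polished-assembly error track is projected onto raw coordinates
    through the per-contig alignment; fixed = raw-only, induced =
    projected-only, unchanged = intersection.  Polished intervals with no
    image on the raw assembly are counted as induced (conservative) but
    cannot be placed; their total length is reported separately.
    """
    aln_by_contig = {a.query_name: a for a in raw_vs_polished}
    track = ErrorKmerTrack(base_counts={FIXED: 0, INDUCED: 0, UNCHANGED: 0},
                           interval_counts={FIXED: 0, INDUCED: 0, UNCHANGED: 0})
    for contig, L in contig_lengths.items():
        raw_mask = np.zeros(L, dtype=bool)
        for iv in raw_track:
            if iv.contig == contig:
                raw_mask[iv.start : iv.end] = True
        proj_mask = np.zeros(L, dtype=bool)
        aln = aln_by_contig.get(contig)
        for iv in polished_track:
            if iv.contig != contig:
                continue
            if aln is None:
                track.unprojected_induced_bases += len(iv)
                continue
            img = project_intervals([iv], aln, "query_to_target")
            if not img:
                log.debug("unprojectable polished interval %s:%d-%d counted induced",
                          iv.contig, iv.start, iv.end)
                track.unprojected_induced_bases += len(iv)
                continue
            proj_mask[img[0].start : img[0].end] = True
        for status, mask in (
            (FIXED, raw_mask & ~proj_mask),
            (INDUCED, proj_mask & ~raw_mask),
            (UNCHANGED, raw_mask & proj_mask),
        ):
            pos = np.flatnonzero(mask)
            track.base_counts[status] += int(pos.size)
            if pos.size:
                breaks = np.flatnonzero(np.diff(pos) > 1)
                starts = np.concatenate(([0], breaks + 1))
                ends = np.concatenate((breaks, [pos.size - 1]))
                for s, e in zip(starts, ends):
                    track.intervals.append(
                        GenomicInterval(contig, int(pos[s]), int(pos[e]) + 1)
                    )
                    track.status.append(status)
                track.interval_counts[status] += int(starts.size)
    return track


@dataclass
class LabeledEdit:
    edit: PolishEdit
    label: str  # "induces", "fixes", "no_change", "none"
    n_fixed: int = 0
    n_induced: int = 0
    n_unchanged: int = 0


def annotate_edits(
    edits: Sequence[PolishEdit], track: ErrorKmerTrack
) -> list[LabeledEdit]:
    """Label edits by intersection of their REF span with the status classes.

    Precedence on multi-overlap: induces > fixes > no_change.  Counts of
    overlapped intervals per class are kept for the GQ sweep.
    """
    by_status = {s: track.by_status(s) for s in (FIXED, INDUCED, UNCHANGED)}
    out = []
    for e in edits:
        span = GenomicInterval(e.contig, e.pos, e.pos + max(1, len(e.ref)))
        hits = {
            s: sum(1 for iv in ivs if iv.overlaps(span)) for s, ivs in by_status.items()
        }
        if hits[INDUCED]:
            label = "induces"
        elif hits[FIXED]:
            label = "fixes"
        elif hits[UNCHANGED]:
            label = "no_change"
        else:
            label = "none"
        if sum(1 for v in hits.values() if v) > 1:
            log.debug("edit %s:%d overlaps multiple classes; labelled %s",
                      e.contig, e.pos, label)
        out.append(LabeledEdit(e, label, hits[FIXED], hits[INDUCED], hits[UNCHANGED]))
    return out


@dataclass
class SweepResult:
    scenario: str
    cutoffs: dict[str, int]  # class -> GQ cutoff
    delta_qv: float
    curve: dict[tuple[int, ...], float]


def sweep_gq(
    annotated_edits: Sequence[LabeledEdit],
    scenario: str = "ins1+del1+rest",
    gq_range: Sequence[int] = range(0, 26),
    unchanged_errors: int = 0,
) -> SweepResult:
    """Exhaustive GQ-cutoff sweep maximizing the estimated QV improvement.

    Scenarios: ``single`` (one cutoff for everything), ``ins1+rest`` (one for
    1 bp insertions, one for the rest), ``ins1+del1+rest`` (one per class).
    An edit is kept when its GQ >= its class cutoff; estimated errors after
    filtering = unchanged + induced(kept) - fixed(kept), and the improvement
    follows :func:`delta_qv`.  Ties go to the lowest cutoff vector
    (lexicographic).
    """
    from .finalize import classify_edit

    if not annotated_edits:
        zero = {"INS1": 0, "DEL1": 0, "OTHER": 0}
        return SweepResult(scenario, zero, 0.0, {})

    per_class: dict[str, list[tuple[float, int, int]]] = {"INS1": [], "DEL1": [], "OTHER": []}
    for le in annotated_edits:
        cls = le.edit.edit_class or classify_edit(le.edit)
        per_class[cls].append((le.edit.gq, le.n_fixed, le.n_induced))

    errors_before = unchanged_errors + sum(le.n_fixed for le in annotated_edits)
    if errors_before <= 0:
        errors_before = 1  # degenerate but keeps the ratio defined

    cuts = list(gq_range)

    def kept_counts(cls: str, cutoff: int) -> tuple[int, int]:
        f = sum(nf for gq, nf, _ in per_class[cls] if gq >= cutoff)
        i = sum(ni for gq, _, ni in per_class[cls] if gq >= cutoff)
        return f, i

    table = {
        cls: {c: kept_counts(cls, c) for c in cuts} for cls in per_class
    }

    if scenario == "single":
        combos = [((c,), {"INS1": c, "DEL1": c, "OTHER": c}) for c in cuts]
    elif scenario == "ins1+rest":
        combos = [
            ((ci, cr), {"INS1": ci, "DEL1": cr, "OTHER": cr})
            for ci in cuts
            for cr in cuts
        ]
    elif scenario == "ins1+del1+rest":
        combos = [
            ((ci, cd, co), {"INS1": ci, "DEL1": cd, "OTHER": co})
            for ci in cuts
            for cd in cuts
            for co in cuts
        ]
    else:
        raise ValueError(f"unknown scenario {scenario!r}")

    best_key: tuple[int, ...] | None = None
    best_delta = -math.inf
    best_cutoffs: dict[str, int] = {}
    curve: dict[tuple[int, ...], float] = {}
    for key, cutoffs in combos:
        fixed = induced = 0
        for cls, c in cutoffs.items():
            f, i = table[cls][c]
            fixed += f
            induced += i
        after = unchanged_errors + induced + (errors_before - unchanged_errors - fixed)
        after = max(after, 0)
        d = delta_qv(errors_before, after)
        curve[key] = d
        if d > best_delta:
            best_delta, best_key, best_cutoffs = d, key, cutoffs
    return SweepResult(scenario, best_cutoffs, best_delta, curve)


# ---------------------------------------------------------------------------
# Context stratification of residual errors
# ---------------------------------------------------------------------------


def stratify_error_context(
    intervals: Sequence[GenomicInterval],
    seqs: dict[str, str],
    depth: dict[str, np.ndarray] | None = None,
    gc_threshold: float = 0.70,
    homopolymer_min: int = 11,
    low_cov: int = 5,
    cov_bands: Sequence[int] = (0, 5, 10, 150),
) -> dict[str, int]:
    """Count error intervals by sequence/coverage context.

    Categories: GC fraction above ``gc_threshold``; overlap with homopolymer
    runs of at least ``homopolymer_min`` bases; overlap with positions whose
    read depth falls below ``low_cov`` (depth is quantized into the
    half-open bands given by ``cov_bands``).
    """
    hp_by_contig = {
        name: homopolymer_runs(seq, homopolymer_min) for name, seq in seqs.items()
    }
    counts = {
        "total": 0,
        "high_gc": 0,
        "homopolymer": 0,
        "low_coverage": 0,
    }
    band_labels = [
        f"cov_{cov_bands[i]}_{cov_bands[i+1]}" for i in range(len(cov_bands) - 1)
    ]
    for lbl in band_labels:
        counts[lbl] = 0
    for iv in intervals:
        seq = seqs[iv.contig][iv.start : iv.end]
        counts["total"] += 1
        gc = (seq.count("G") + seq.count("C")) / max(1, len(seq))
        if gc > gc_threshold:
            counts["high_gc"] += 1
        if any(s < iv.end and iv.start < e for s, e in hp_by_contig[iv.contig]):
            counts["homopolymer"] += 1
        if depth is not None and iv.contig in depth:
            d = depth[iv.contig][iv.start : iv.end]
            if d.size and d.min() < low_cov:
                counts["low_coverage"] += 1
            if d.size:
                dmin = int(d.min())
                for i, lbl in enumerate(band_labels):
                    if cov_bands[i] <= dmin < cov_bands[i + 1]:
                        counts[lbl] += 1
                        break
    return counts


# ---------------------------------------------------------------------------
# Gene impact
# ---------------------------------------------------------------------------


@dataclass
class CdsAlignment:
    """Pairwise alignment of an annotated CDS against the reference CDS."""

    transcript_id: str
    ref_cds: str
    asm_cds: str
    cigar: list[tuple[str, int]]

    def __post_init__(self):
        if len(self.ref_cds) % 3 != 0:
            raise ValueError(
                f"{self.transcript_id}: reference CDS length not divisible by 3"
            )


def align_cds(transcript_id: str, ref_cds: str, asm_cds: str) -> CdsAlignment:
    """Globally align an annotated CDS to its reference with affine gaps.

    Affine gap scoring keeps indels contiguous, so a single biological gap is
    reported as one run rather than fragments — which matters for the
    multiple-of-three frameshift rule.
    """
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -0.1
    aln = aligner.align(ref_cds, asm_cds)[0]
    cigar: list[tuple[str, int]] = []
    t = q = 0
    ref_blocks, asm_blocks = aln.aligned
    for (t0, t1), (q0, q1) in zip(ref_blocks.tolist(), asm_blocks.tolist()):
        if t0 > t:
            cigar.append(("D", t0 - t))
        if q0 > q:
            cigar.append(("I", q0 - q))
        for i in range(t1 - t0):
            op = "=" if ref_cds[t0 + i] == asm_cds[q0 + i] else "X"
            if cigar and cigar[-1][0] == op:
                cigar[-1] = (op, cigar[-1][1] + 1)
            else:
                cigar.append((op, 1))
        t, q = t1, q1
    if t < len(ref_cds):
        cigar.append(("D", len(ref_cds) - t))
    if q < len(asm_cds):
        cigar.append(("I", len(asm_cds) - q))
    return CdsAlignment(transcript_id, ref_cds, asm_cds, cigar)


def detect_frameshifts(
    cds_aln: CdsAlignment, max_inframe_gap: int = 30
) -> list[tuple[str, int, int]]:
    """Gaps that are not a multiple of 3, or longer than 30 bp.

    Returns (transcript_id, gap position on the reference CDS, gap length)
    for every alignment gap satisfying the disjunction.
    """
    out = []
    t = 0
    for op, n in cds_aln.cigar:
        if op in "=XM":
            t += n
        elif op in "ID":
            if n % 3 != 0 or n > max_inframe_gap:
                out.append((cds_aln.transcript_id, t, n))
            if op == "D":
                t += n
    return out


def detect_premature_stops(cds_seq: str) -> list[int]:
    """Codon indices of stop codons strictly before the terminal codon."""
    if len(cds_seq) % 3 != 0:
        warnings.warn("CDS length not divisible by 3; trailing bases ignored")
    n_codons = len(cds_seq) // 3
    out = []
    for i in range(n_codons - 1):
        if cds_seq[3 * i : 3 * i + 3].upper() in STOP_CODONS:
            out.append(i)
    return out


def detect_nonsynonymous(cds_ref: str, cds_alt: str) -> list[tuple[int, str, str]]:
    """Codons whose nucleotide change alters the encoded amino acid.

    Sequences must be the same length and a multiple of 3 (indels belong to
    the frameshift analysis).  Synonymous changes are excluded.
    """
    if len(cds_ref) != len(cds_alt):
        raise ValueError("CDS length mismatch; indels belong to frameshift analysis")
    if len(cds_ref) % 3 != 0:
        raise ValueError("CDS length not divisible by 3")
    out = []
    for i in range(len(cds_ref) // 3):
        c_ref = cds_ref[3 * i : 3 * i + 3].upper()
        c_alt = cds_alt[3 * i : 3 * i + 3].upper()
        if c_ref != c_alt:
            aa_ref = str(Seq(c_ref).translate())
            aa_alt = str(Seq(c_alt).translate())
            if aa_ref != aa_alt:
                out.append((i, aa_ref, aa_alt))
    return out
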