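"""Alignment records, CIGAR arithmetic, coordinate projection, and format I/O.

Everything downstream of the aligner works on :class:`AlignmentRecord`, a thin
in-memory alignment with an *extended* CIGAR (``=``/``X`` instead of ``M``),
mirroring what ``--eqx`` aligner output provides.  Coordinates are 0-based
half-open throughout; conversion to 1-based happens only when VCF records are
written.

Two primitives defined here are shared by the phasing and evaluation stages:

* :func:`gap_compressed_mismatch_ratio` — per-alignment divergence where each
  insertion or deletion run counts once, used for the 0.02 / 0.002 read
  filters.
* :func:`project_intervals` — lift intervals through an alignment in either
  direction (the "liftover through CIGAR" used for variant blocks, confidence
  regions and error-k-mer tracks).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Literal

import pysam

__all__ = [
    "GenomicInterval",
    "AlignmentRecord",
    "parse_cigar",
    "format_cigar",
    "gap_compressed_mismatch_ratio",
    "project_intervals",
    "merge_intervals",
    "read_sam",
    "write_sam",
    "read_paf",
    "read_bed",
    "write_bed",
    "read_fasta",
    "write_fasta",
    "write_vcf",
    "read_vcf",
]

_CIGAR_RE = re.compile(r"(\d+)([=XIDSHM])")

QUERY_OPS = frozenset("=XIS")
TARGET_OPS = frozenset("=XD")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval on a named sequence."""

    contig: str
    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start <= self.end):
            raise ValueError(f"invalid interval {self.contig}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class AlignmentRecord:
    """A single pairwise alignment with extended CIGAR."""

    query_name: str
    query_seq: str
    target_name: str
    target_start: int
    cigar: list[tuple[str, int]]
    strand: str = "+"
    mapq: int = 60
    query_quals: list[int] | None = None
    tags: dict = field(default_factory=dict)
    is_secondary: bool = False

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def query_length(self) -> int:
        return sum(n for op, n in self.cigar if op in QUERY_OPS)

    @property
    def query_aln_start(self) -> int:
        """Start of the aligned part on the stored query (skips clips)."""
        off = 0
        for op, n in self.cigar:
            if op in "SH":
                off += n if op == "S" else 0
            else:
                break
        return off

    @property
    def target_end(self) -> int:
        return self.target_start + sum(n for op, n in self.cigar if op in TARGET_OPS)

    @property
    def target_interval(self) -> GenomicInterval:
        return GenomicInterval(self.target_name, self.target_start, self.target_end)

    def check_consistency(self):
        if self.query_seq and self.query_length != len(self.query_seq):
            raise ValueError(
                f"CIGAR consumes {self.query_length} query bases but "
                f"sequence has {len(self.query_seq)} ({self.query_name})"
            )


def parse_cigar(text: str) -> list[tuple[str, int]]:
    ops = [(m.group(2), int(m.group(1))) for m in _CIGAR_RE.finditer(text)]
    if "".join(f"{n}{op}" for op, n in ops) != text:
        raise ValueError(f"unparseable CIGAR {text!r}")
    return ops


def format_cigar(cigar: Iterable[tuple[str, int]]) -> str:
    return "".join(f"{n}{op}" for op, n in cigar)


def compact_cigar(cigar: Iterable[tuple[str, int]]) -> list[tuple[str, int]]:
    """Merge adjacent runs of the same op and drop zero-length runs."""
    out: list[tuple[str, int]] = []
    for op, n in cigar:
        if n == 0:
            continue
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + n)
        else:
            out.append((op, n))
    return out


def gap_compressed_mismatch_ratio(aln: AlignmentRecord) -> float:
    """Divergence with each indel run counted once.

    numerator = #X columns + #insertion runs + #deletion runs;
    denominator adds the matched (=) columns.  Requires an ``=``/``X`` CIGAR;
    ``M`` is ambiguous and rejected.
    """
    n_match = n_mismatch = n_gap_events = 0
    for op, n in aln.cigar:
        if op == "=":
            n_match += n
        elif op == "X":
            n_mismatch += n
        elif op in "ID":
            n_gap_events += 1
        elif op == "M":
            raise ValueError("gap-compressed ratio needs =/X CIGARs, got M")
    denom = n_match + n_mismatch + n_gap_events
    if denom == 0:
        raise ValueError(f"empty alignment for {aln.query_name}")
    return (n_mismatch + n_gap_events) / denom


def aligned_segments(aln: AlignmentRecord) -> list[tuple[int, int, int, int]]:
    """Co-linear blocks (t0, t1, q0, q1) consuming both sides (=/X runs).

    Query coordinates are in the stored (target-forward) orientation and
    include soft clips, matching SAM conventions.
    """
    t = aln.target_start
    q = 0
    segs = []
    for op, n in aln.cigar:
        if op in "=XM":
            segs.append((t, t + n, q, q + n))
            t += n
            q += n
        elif op == "D":
            t += n
        elif op in "IS":
            q += n
        # hard clips consume nothing
    return segs


def _project_onto(
    segs: list[tuple[int, int, int, int]],
    start: int,
    end: int,
    src: int,
    dst: int,
) -> tuple[int, int] | None:
    """Image of [start, end) from coordinate column ``src`` to ``dst``.

    ``segs`` columns: 0/1 = target start/end, 2/3 = query start/end.
    Returns None when no aligned base of the interval exists on the far side.
    """
    lo = hi = None
    for seg in segs:
        s0, s1 = seg[src], seg[src + 1]
        d0 = seg[dst]
        o0 = max(start, s0)
        o1 = min(end, s1)
        if o0 < o1:
            m0 = d0 + (o0 - s0)
            m1 = d0 + (o1 - s0)
            lo = m0 if lo is None else min(lo, m0)
            hi = m1 if hi is None else max(hi, m1)
    if lo is None or lo >= hi:
        return None
    return lo, hi


def project_intervals(
    intervals: Iterable[GenomicInterval],
    aln: AlignmentRecord,
    direction: Literal["target_to_query", "query_to_target"] = "target_to_query",
    normalize_strand: bool = True,
) -> list[GenomicInterval]:
    """Lift intervals through the alignment's CIGAR walk.

    Portions falling opposite an indel are clipped; intervals whose image is
    empty (entirely deleted / inserted on the other side) are dropped.  When
    the record is reverse strand, query-side coordinates are normalized to
    forward-strand (original read) coordinates unless ``normalize_strand``
    is off, in which case they stay in the stored (target-forward)
    orientation; input query intervals are interpreted the same way.
    """
    segs = aligned_segments(aln)
    out = []
    if direction == "target_to_query":
        src, dst, out_name = 0, 2, aln.query_name
    else:
        src, dst, out_name = 2, 0, aln.target_name
    qlen = aln.query_length
    flip = aln.strand == "-" and normalize_strand
    for iv in intervals:
        start, end = iv.start, iv.end
        if flip and src == 2:
            start, end = qlen - end, qlen - start
        img = _project_onto(segs, start, end, src, dst)
        if img is None:
            continue
        lo, hi = img
        if flip and dst == 2:
            lo, hi = qlen - hi, qlen - lo
        out.append(GenomicInterval(out_name, lo, hi))
    return out


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals; overlapping or bookended runs are merged."""
    by_contig: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_contig.setdefault(iv.contig, []).append(iv)
    out = []
    for contig in sorted(by_contig):
        ivs = sorted(by_contig[contig], key=lambda i: (i.start, i.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(GenomicInterval(contig, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        out.append(GenomicInterval(contig, cur_s, cur_e))
    return out


# ---------------------------------------------------------------------------
# Format I/O
# ---------------------------------------------------------------------------


def write_sam(path: str, records: Iterable[AlignmentRecord], contig_lengths: dict[str, int]):
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": ln} for name, ln in contig_lengths.items()],
    }
    with pysam.AlignmentFile(path, "w", header=header) as fh:
        for rec in records:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = rec.query_name
            a.query_sequence = rec.query_seq or None
            if rec.query_quals is not None:
                a.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(q + 33) for q in rec.query_quals)
                )
            a.reference_name = rec.target_name
            a.reference_start = rec.target_start
            a.mapping_quality = rec.mapq
            a.cigarstring = format_cigar(rec.cigar)
            flag = 0
            if rec.strand == "-":
                flag |= 16
            if rec.is_secondary:
                flag |= 256
            a.flag = flag
            for key, val in rec.tags.items():
                a.set_tag(key, val)
            fh.write(a)


def read_sam(path: str) -> list[AlignmentRecord]:
    out = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped:
                continue
            quals = list(a.query_qualities) if a.query_qualities is not None else None
            out.append(
                AlignmentRecord(
                    query_name=a.query_name,
                    query_seq=a.query_sequence or "",
                    target_name=a.reference_name,
                    target_start=a.reference_start,
                    cigar=parse_cigar(a.cigarstring),
                    strand="-" if a.is_reverse else "+",
                    mapq=a.mapping_quality,
                    query_quals=quals,
                    tags=dict(a.get_tags()),
                    is_secondary=a.is_secondary,
                )
            )
    return out


def read_paf(path: str) -> list[AlignmentRecord]:
    """Minimal PAF reader; requires the ``cg:Z:`` CIGAR tag."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            qname, _, _, _, strand, tname, _, tstart = fields[:8]
            tags = {}
            for tag in fields[12:]:
                key, typ, val = tag.split(":", 2)
                tags[key] = int(val) if typ == "i" else val
            if "cg" not in tags:
                raise ValueError(f"PAF line for {qname} lacks cg: CIGAR tag")
            out.append(
                AlignmentRecord(
                    query_name=qname,
                    query_seq="",
                    target_name=tname,
                    target_start=int(tstart),
                    cigar=parse_cigar(tags.pop("cg")),
                    strand=strand,
                    mapq=int(fields[11]),
                    tags=tags,
                )
            )
    return out


def read_bed(path: str) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            contig, start, end = line.split("\t")[:3]
            out.append(GenomicInterval(contig, int(start), int(end)))
    return out


def write_bed(path: str, intervals: Iterable[GenomicInterval], names: Iterable[str] | None = None):
    with open(path, "w") as fh:
        if names is None:
            for iv in intervals:
                fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\n")
        else:
            for iv, name in zip(intervals, names):
                fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{name}\n")


def read_fasta(path: str) -> dict[str, str]:
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            elif name is not None:
                seqs[name].append(line)
    return {k: "".join(v) for k, v in seqs.items()}


def write_fasta(path: str, seqs: dict[str, str], width: int = 80):
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_vcf(path: str, records, contig_lengths: dict[str, int], sample: str = "polish"):
    """Write VCF v4.2 with GT:GQ sample fields.

    ``records`` are (contig, pos0, ref, alt, gq) tuples or objects with those
    attributes; positions are 0-based here and converted on write.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, ln in contig_lengths.items():
            fh.write(f"##contig=<ID={name},length={ln}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample + "\n")
        for rec in records:
            if isinstance(rec, tuple):
                contig, pos, ref, alt, gq = rec
            else:
                contig, pos, ref, alt, gq = rec.contig, rec.pos, rec.ref, rec.alt, rec.gq
            fh.write(
                f"{contig}\t{pos + 1}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT:GQ\t1/1:{int(round(gq))}\n"
            )


def read_vcf(path: str) -> list[tuple[str, int, str, str, int]]:
    """Read (contig, pos0, ref, alt, gq) tuples from a VCF."""
    out = []
    with pysam.VariantFile(path) as fh:
        for rec in fh:
            gq = 0
            for sample in rec.samples.values():
                if sample.get("GQ") is not None:
                    gq = int(sample["GQ"])
                break
            out.append((rec.chrom, rec.pos - 1, rec.ref, rec.alts[0], gq))
    return out
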