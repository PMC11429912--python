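"""Seeded synthetic diploid genomes, corrupted drafts, and simulated reads.

This module builds the worlds the polishing pipeline is tested on:

* a diploid truth genome (two haplotypes differing at recorded heterozygous
  variants, with long designated low-heterozygosity intervals and planted
  homopolymer runs);
* a corrupted draft assembly whose deviations from the truth are recorded as
  the VCF-style edits that would repair them — inside the designated long
  intervals the draft collapses both haplotypes onto haplotype 1's sequence,
  reproducing the "false homozygosity" failure mode of diploid assemblers;
* HiFi-like and ultra-long (UL) ONT-like reads with truth-derived extended
  CIGAR alignments, plus a small seed-and-extend aligner (edlib-based) that
  places reads on the draft the way a real aligner would: scoring both
  haplotypes and breaking exact ties at random, so reads inside collapsed
  regions end up on an arbitrary haplotype.

All randomness flows through one ``numpy.random.Generator`` per call; the
same seed reproduces byte-identical FASTA/FASTQ/SAM output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import edlib
import numpy as np

from ._seq import homopolymer_mask, revcomp
from .alignio import AlignmentRecord, GenomicInterval, compact_cigar, parse_cigar

__all__ = [
    "SimProfile",
    "HIFI_PROFILE",
    "UL_PROFILE",
    "DiploidAssembly",
    "TruthSet",
    "OffsetMap",
    "generate_diploid",
    "corrupt_assembly",
    "simulate_reads",
    "align_reads_to_draft",
    "write_fastq",
]

HAPS = ("hap1", "hap2")


@dataclass(frozen=True)
class SimProfile:
    """Read-simulation parameters for one technology.

    Rates are per-base probabilities; ``homopolymer_indel_multiplier`` scales
    the indel rate inside homopolymer runs of five or more bases, emulating
    the dominant long-read error mode.
    """

    read_length_mean: int
    read_length_sd: int
    min_length: int
    substitution_rate: float
    indel_rate: float
    homopolymer_indel_multiplier: float
    depth: float
    seed: int = 0
    max_length: int | None = None
    base_quality: int = 35
    error_base_quality: int = 15

    def __post_init__(self):
        for rate in (self.substitution_rate, self.indel_rate):
            if not 0 <= rate <= 0.2:
                raise ValueError(f"rate {rate} outside [0, 0.2]")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.homopolymer_indel_multiplier < 1:
            raise ValueError("homopolymer multiplier must be >= 1")


#: HiFi-like: ~18 kb reads capped below 25 kb, ~0.1% error.
HIFI_PROFILE = SimProfile(
    read_length_mean=18_000,
    read_length_sd=3_000,
    min_length=5_000,
    substitution_rate=8e-4,
    indel_rate=2e-4,
    homopolymer_indel_multiplier=8.0,
    depth=40,
    max_length=24_999,
)

#: ONT-UL-like: >100 kb reads used only as phasing evidence.
UL_PROFILE = SimProfile(
    read_length_mean=130_000,
    read_length_sd=20_000,
    min_length=100_000,
    substitution_rate=4e-3,
    indel_rate=1e-3,
    homopolymer_indel_multiplier=8.0,
    depth=15,
    base_quality=20,
    error_base_quality=7,
)


class OffsetMap:
    """Piecewise-constant coordinate shift induced by a sorted indel list.

    Built from (src_anchor_end, delta) events; positions at or after an
    event's anchor end shift by the cumulative delta.  Only positions outside
    variant spans are meaningful, which is all the callers need (read starts,
    interval boundaries).
    """

    def __init__(self, events: list[tuple[int, int]]):
        events = sorted(events)
        self._pos = np.array([p for p, _ in events], dtype=np.int64)
        self._cum = np.cumsum([d for _, d in events]).astype(np.int64) if events else np.zeros(0, np.int64)

    def __call__(self, pos: int) -> int:
        i = int(np.searchsorted(self._pos, pos, side="right"))
        return pos + (int(self._cum[i - 1]) if i > 0 else 0)

    @staticmethod
    def from_variants(variants) -> "OffsetMap":
        """Map src->dst coordinates for (pos, ref, alt) applied to src."""
        return OffsetMap(
            [(pos + len(ref), len(alt) - len(ref)) for pos, ref, alt in variants]
        )


@dataclass
class DiploidAssembly:
    """Two named haplotypes, each a dict of contig-name -> sequence.

    Contigs are addressed either by (contig, hap) or by the combined
    ``contig#hap`` name used in FASTA/SAM output.
    """

    haplotypes: dict[str, dict[str, str]]
    truth_to_draft: dict[str, dict[str, OffsetMap]] | None = None

    @staticmethod
    def full_name(contig: str, hap: str) -> str:
        return f"{contig}#{hap}"

    @staticmethod
    def split_name(full: str) -> tuple[str, str]:
        contig, hap = full.rsplit("#", 1)
        return contig, hap

    def seq(self, full: str) -> str:
        contig, hap = self.split_name(full)
        return self.haplotypes[hap][contig]

    def contig_lengths(self) -> dict[str, int]:
        return {
            self.full_name(contig, hap): len(seq)
            for hap in HAPS
            for contig, seq in self.haplotypes[hap].items()
        }

    def as_named_seqs(self, hap: str) -> dict[str, str]:
        return {
            self.full_name(contig, hap): seq
            for contig, seq in self.haplotypes[hap].items()
        }


@dataclass
class TruthSet:
    """Ground truth produced alongside a synthetic genome/draft pair.

    het_variants: (contig, pos_on_hap1, ref, alt, carrier_hap) records; the
    alt allele always sits on hap2 (polarity is a labelling choice, invisible
    to the pipeline).  injected_errors: per haplotype, the sorted VCF-style
    repairs (contig_full_name, pos_on_draft, ref, alt) that restore the truth.
    loh_intervals: designated long collapsed intervals per haplotype, in that
    haplotype's truth coordinates.
    """

    het_variants: list[tuple[str, int, str, str, str]] = field(default_factory=list)
    injected_errors: dict[str, list[tuple[str, int, str, str]]] = field(default_factory=dict)
    loh_intervals: dict[str, list[GenomicInterval]] = field(default_factory=dict)
    read_origins: dict[str, tuple[str, str, int, str]] = field(default_factory=dict)
    hap1_to_hap2: dict[str, OffsetMap] = field(default_factory=dict)
    hap2_to_hap1: dict[str, OffsetMap] = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


_LUT = np.frombuffer(b"ACGT", dtype=np.uint8)


def _codes_to_str(codes: np.ndarray) -> str:
    return _LUT[codes].tobytes().decode("ascii")


def _sample_positions(rng, length, rate_vec) -> np.ndarray:
    u = rng.random(length)
    return np.flatnonzero(u < rate_vec)


def _enforce_spacing(positions: np.ndarray, min_gap: int) -> list[int]:
    kept: list[int] = []
    last = -(10**9)
    for p in positions.tolist():
        if p - last >= min_gap:
            kept.append(p)
            last = p
    return kept


def generate_diploid(
    seed: int,
    n_contigs: int = 1,
    contig_length: int = 1_000_000,
    het_snv_rate: float = 1e-3,
    het_indel_rate: float = 1e-4,
    loh_count: int = 2,
    loh_length: int = 25_000,
    loh_het_rate: float | None = None,
    homopolymer_density: float = 2e-4,
    loh_margin: int = 30_000,
) -> tuple[DiploidAssembly, TruthSet]:
    """Build a diploid truth genome with designated low-heterozygosity intervals.

    Haplotype 1 is the reference strand of the simulation; haplotype 2 carries
    the alt allele of every heterozygous variant.  Inside each designated
    interval the het rate drops to ``loh_het_rate`` (assemblers collapse
    haplotypes precisely where heterozygosity is locally low); the draft
    produced by :func:`corrupt_assembly` will represent both haplotypes with
    hap1's sequence there.

    Raises ValueError when ``loh_count`` intervals of ``loh_length`` cannot be
    placed on a contig of ``contig_length``.
    """
    if loh_het_rate is None:
        # collapsed regions arise where heterozygosity is locally low
        loh_het_rate = 0.25 * (het_snv_rate + het_indel_rate)
    for rate in (het_snv_rate, het_indel_rate, loh_het_rate):
        if rate < 0:
            raise ValueError("rates must be non-negative")
    rng = np.random.default_rng(seed)
    hap1: dict[str, str] = {}
    hap2: dict[str, str] = {}
    truth = TruthSet()

    for ci in range(n_contigs):
        contig = f"contig{ci}"
        codes = _random_seq(rng, contig_length)
        # plant homopolymer runs so indel-bias and context stratification have
        # something to chew on
        n_runs = rng.poisson(homopolymer_density * contig_length)
        for _ in range(n_runs):
            run_len = int(rng.integers(6, 25))
            start = int(rng.integers(0, max(1, contig_length - run_len)))
            codes[start : start + run_len] = rng.integers(0, 4)
        seq1 = _codes_to_str(codes)

        # place designated collapsed intervals
        loh: list[GenomicInterval] = []
        span_needed = loh_count * (loh_length + loh_margin) + loh_margin
        if loh_count and span_needed > contig_length:
            raise ValueError(
                f"cannot place {loh_count} x {loh_length} bp intervals on a "
                f"{contig_length} bp contig"
            )
        attempts = 0
        while len(loh) < loh_count:
            attempts += 1
            if attempts > 1000:
                raise ValueError("failed to place non-overlapping intervals")
            s = int(rng.integers(loh_margin, contig_length - loh_length - loh_margin + 1))
            iv = GenomicInterval(contig, s, s + loh_length)
            if all(
                iv.end + loh_margin <= o.start or o.end + loh_margin <= iv.start
                for o in loh
            ):
                loh.append(iv)
        loh.sort()

        in_loh = np.zeros(contig_length, dtype=bool)
        for iv in loh:
            in_loh[iv.start : iv.end] = True

        total_rate = het_snv_rate + het_indel_rate
        snv_frac = het_snv_rate / total_rate if total_rate > 0 else 0.0
        rate_vec = np.where(in_loh, loh_het_rate, total_rate)
        positions = _enforce_spacing(_sample_positions(rng, contig_length - 4, rate_vec[:-4] if contig_length > 4 else rate_vec), 10)

        variants: list[tuple[int, str, str]] = []
        for pos in positions:
            ref_base = seq1[pos]
            if rng.random() < snv_frac or total_rate == 0:
                alt = "ACGT".replace(ref_base, "")[int(rng.integers(0, 3))]
                variants.append((pos, ref_base, alt))
            else:
                ilen = int(rng.integers(1, 3))
                if rng.random() < 0.5:  # insertion on hap2
                    ins = _codes_to_str(rng.integers(0, 4, ilen, dtype=np.uint8))
                    variants.append((pos, ref_base, ref_base + ins))
                else:  # deletion on hap2
                    variants.append((pos, seq1[pos : pos + 1 + ilen], ref_base))

        from ._seq import apply_variant_list

        seq2 = apply_variant_list(seq1, variants)
        hap1[contig] = seq1
        hap2[contig] = seq2

        truth.het_variants.extend(
            (contig, pos, ref, alt, "hap2") for pos, ref, alt in variants
        )
        fwd = OffsetMap.from_variants(variants)
        truth.hap1_to_hap2[contig] = fwd
        truth.hap2_to_hap1[contig] = OffsetMap(
            [
                (pos + len(alt) + (fwd(pos) - pos), len(ref) - len(alt))
                for pos, ref, alt in variants
            ]
        )
        truth.loh_intervals.setdefault("hap1", []).extend(loh)
        truth.loh_intervals.setdefault("hap2", []).extend(
            GenomicInterval(contig, fwd(iv.start), fwd(iv.end)) for iv in loh
        )

    genome = DiploidAssembly({"hap1": hap1, "hap2": hap2})
    return genome, truth


def corrupt_assembly(
    genome: DiploidAssembly,
    error_snv_rate: float = 1.3e-5,
    error_indel_rate: float = 7e-6,
    seed: int = 0,
    truth: TruthSet | None = None,
    collapse_loh: bool = True,
) -> tuple[DiploidAssembly, dict[str, list[tuple[str, int, str, str]]]]:
    """Corrupt a truth genome into a draft, recording the repairs.

    Random substitution and 1 bp indel errors are injected per haplotype.
    When a :class:`TruthSet` with designated intervals is supplied and
    ``collapse_loh`` is on, hap2's draft sequence inside each interval is an
    exact copy of hap1's draft there (false homozygosity: the assembler
    emits one consensus twice, errors included).  Operationally every het
    variant inside the interval is reverted on hap2 and hap1's random errors
    there are mirrored onto hap2; all the restorations join the truth edit
    set.

    Returns the draft and per-haplotype repair lists; applying the repairs to
    the draft reproduces the truth genome exactly.  The draft object carries
    ``truth_to_draft`` coordinate maps for downstream read placement.
    """
    if error_snv_rate < 0 or error_indel_rate < 0:
        raise ValueError("rates must be non-negative")
    rng = np.random.default_rng(seed)
    draft_haps: dict[str, dict[str, str]] = {h: {} for h in HAPS}
    repairs: dict[str, list[tuple[str, int, str, str]]] = {h: [] for h in HAPS}
    maps: dict[str, dict[str, OffsetMap]] = {h: {} for h in HAPS}
    hap1_errors: dict[str, list[tuple[int, str, str]]] = {}

    collapse = truth is not None and collapse_loh

    for hap in HAPS:
        for contig, seq in genome.haplotypes[hap].items():
            L = len(seq)
            corruptions: list[tuple[int, str, str]] = []  # on truth-hap coords
            blocked: list[int] = []
            exclude: list[GenomicInterval] = []

            if truth is not None:
                fwd = truth.hap1_to_hap2.get(contig)
                for c, pos1, ref, alt, _carrier in truth.het_variants:
                    if c == contig:
                        blocked.append(pos1 if hap == "hap1" else fwd(pos1))

            if collapse and hap == "hap2":
                fwd = truth.hap1_to_hap2[contig]
                loh1 = [
                    iv for iv in truth.loh_intervals.get("hap1", []) if iv.contig == contig
                ]
                exclude = [
                    iv for iv in truth.loh_intervals.get("hap2", []) if iv.contig == contig
                ]
                for c, pos1, ref, alt, _carrier in truth.het_variants:
                    if c != contig:
                        continue
                    if any(iv.start <= pos1 < iv.end for iv in loh1):
                        # hap2 carries alt; the collapsed draft shows ref
                        corruptions.append((fwd(pos1), alt, ref))
                # mirror hap1's random errors so the collapsed copies are
                # byte-identical
                for p1, ref, alt in hap1_errors.get(contig, []):
                    if any(iv.start <= p1 < iv.end for iv in loh1):
                        corruptions.append((fwd(p1), ref, alt))
                blocked.extend(p for p, _, _ in corruptions)

            total = error_snv_rate + error_indel_rate
            new_errors: list[tuple[int, str, str]] = []
            if total > 0:
                u = rng.random(max(0, L - 2))
                cand = np.flatnonzero(u < total)
                blocked_arr = np.array(sorted(blocked), dtype=np.int64)
                kept: list[int] = []
                last = -(10**9)
                for p in cand.tolist():
                    if p - last < 20:
                        continue
                    if any(iv.start - 20 <= p < iv.end + 20 for iv in exclude):
                        continue
                    if blocked_arr.size:
                        j = int(np.searchsorted(blocked_arr, p))
                        near = []
                        if j > 0:
                            near.append(int(blocked_arr[j - 1]))
                        if j < blocked_arr.size:
                            near.append(int(blocked_arr[j]))
                        if any(abs(p - b) < 20 for b in near):
                            continue
                    kept.append(p)
                    last = p
                snv_frac = error_snv_rate / total
                for p in kept:
                    base = seq[p]
                    if rng.random() < snv_frac:
                        wrong = "ACGT".replace(base, "")[int(rng.integers(0, 3))]
                        new_errors.append((p, base, wrong))
                    elif rng.random() < 0.5:  # draft gains a base
                        extra = "ACGT"[int(rng.integers(0, 4))]
                        new_errors.append((p, base, base + extra))
                    else:  # draft loses a base
                        new_errors.append((p, seq[p : p + 2], base))
            corruptions.extend(new_errors)
            if hap == "hap1":
                hap1_errors[contig] = new_errors

            corruptions.sort()
            from ._seq import apply_variant_list

            draft_seq = apply_variant_list(seq, corruptions)
            draft_haps[hap][contig] = draft_seq

            full = DiploidAssembly.full_name(contig, hap)
            shift = 0
            events = []
            for pos, ref, alt in corruptions:
                dpos = pos + shift
                repairs[hap].append((full, dpos, alt, ref))
                delta = len(alt) - len(ref)
                events.append((pos + len(ref), delta))
                shift += delta
            maps[hap][contig] = OffsetMap(events)

    draft = DiploidAssembly(draft_haps, truth_to_draft=maps)
    if truth is not None:
        truth.injected_errors = repairs
    return draft, repairs


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


def _simulate_one_read(
    rng: np.random.Generator,
    seq: str,
    hp_mask: np.ndarray,
    start: int,
    length: int,
    profile: SimProfile,
) -> tuple[str, list[int], list[tuple[str, int]]]:
    """Returns (read_seq target-forward, quals, cigar)."""
    segment = seq[start : start + length]
    m = len(segment)
    sub_hits = np.flatnonzero(rng.random(m) < profile.substitution_rate)
    p_ind = profile.indel_rate * np.where(
        hp_mask[start : start + m], profile.homopolymer_indel_multiplier, 1.0
    )
    ind_hits = np.flatnonzero(rng.random(m) < np.minimum(p_ind, 0.2))

    events: dict[int, str] = {}
    for p in ind_hits.tolist():
        events[p] = "ins" if rng.random() < 0.5 else "del"
    for p in sub_hits.tolist():
        events.setdefault(p, "sub")

    out: list[str] = []
    quals: list[int] = []
    cigar: list[tuple[str, int]] = []
    cursor = 0
    q_ok = profile.base_quality
    q_err = profile.error_base_quality
    for p in sorted(events):
        if p > cursor:
            run = segment[cursor:p]
            out.append(run)
            quals.extend([q_ok] * len(run))
            cigar.append(("=", len(run)))
        kind = events[p]
        base = segment[p]
        if kind == "sub":
            wrong = "ACGT".replace(base, "")[int(rng.integers(0, 3))]
            out.append(wrong)
            quals.append(q_err)
            cigar.append(("X", 1))
            cursor = p + 1
        elif kind == "ins":
            ins = base if hp_mask[start + p] else "ACGT"[int(rng.integers(0, 4))]
            out.append(ins)
            quals.append(q_err)
            cigar.append(("I", 1))
            out.append(base)
            quals.append(q_ok)
            cigar.append(("=", 1))
            cursor = p + 1
        else:  # del
            cigar.append(("D", 1))
            cursor = p + 1
    if cursor < m:
        run = segment[cursor:]
        out.append(run)
        quals.extend([q_ok] * len(run))
        cigar.append(("=", len(run)))
    return "".join(out), quals, compact_cigar(cigar)


def simulate_reads(
    genome: DiploidAssembly,
    profile: SimProfile,
    name_prefix: str = "read",
) -> tuple[list[AlignmentRecord], dict[str, tuple[str, str, int, str]]]:
    """Simulate reads from both haplotypes with truth alignments.

    Returns (records, origins).  Each record's CIGAR uses ``=``/``X``/``I``/
    ``D`` consistent with the simulated errors, target names are
    ``contig#hap``, MAPQ is 60, and ``query_seq`` is stored target-forward
    (SAM convention); ``origins`` maps read name to
    (hap, contig, start_on_truth_hap, strand).
    """
    rng = np.random.default_rng(profile.seed)
    records: list[AlignmentRecord] = []
    origins: dict[str, tuple[str, str, int, str]] = {}
    idx = 0
    for hap in HAPS:
        for contig, seq in genome.haplotypes[hap].items():
            L = len(seq)
            if L < profile.min_length:
                warnings.warn(
                    f"{contig}#{hap} shorter than min_length; no reads simulated"
                )
                continue
            hp_mask = homopolymer_mask(seq, 5)
            mean = profile.read_length_mean
            # read starts uniform over [-mean, L): reads are truncated at both
            # contig ends, keeping coverage flat right up to the edges
            n_reads = int(round((L + mean) * profile.depth / mean))
            starts = rng.integers(-mean, L, size=n_reads)
            lengths = rng.normal(mean, profile.read_length_sd, n_reads)
            lengths = np.clip(
                lengths,
                profile.min_length,
                profile.max_length if profile.max_length else None,
            ).astype(np.int64)
            strands = rng.random(n_reads) < 0.5
            for ri in range(n_reads):
                start = int(starts[ri])
                end = min(start + int(lengths[ri]), L)
                start = max(0, start)
                length = end - start
                if length < 200:
                    continue
                read_seq, quals, cigar = _simulate_one_read(
                    rng, seq, hp_mask, start, length, profile
                )
                strand = "-" if strands[ri] else "+"
                name = f"{name_prefix}_{hap}_{contig}_{idx:06d}"
                idx += 1
                records.append(
                    AlignmentRecord(
                        query_name=name,
                        query_seq=read_seq,
                        target_name=DiploidAssembly.full_name(contig, hap),
                        target_start=start,
                        cigar=cigar,
                        strand=strand,
                        mapq=60,
                        query_quals=quals,
                        tags={"HP": 1 if hap == "hap1" else 2},
                    )
                )
                origins[name] = (hap, contig, start, strand)
    return records, origins


def write_fastq(path: str, records: list[AlignmentRecord]):
    """Write reads in their sequencing (strand-of-origin) orientation."""
    with open(path, "w") as fh:
        for rec in records:
            seq, quals = rec.query_seq, rec.query_quals or [30] * len(rec.query_seq)
            if rec.strand == "-":
                seq = revcomp(seq)
                quals = quals[::-1]
            fh.write(f"@{rec.query_name}\n{seq}\n+\n")
            fh.write("".join(chr(q + 33) for q in quals) + "\n")


# ---------------------------------------------------------------------------
# Placement of simulated reads on the draft
# ---------------------------------------------------------------------------


def align_reads_to_draft(
    reads: list[AlignmentRecord],
    draft: DiploidAssembly,
    truth: TruthSet,
    origins: dict[str, tuple[str, str, int, str]],
    seed: int = 0,
    tie_slop: int = 3,
) -> list[AlignmentRecord]:
    """Place each simulated read on the draft, scoring both haplotypes.

    For every read, its locus on each draft haplotype is derived from the
    truth origin through the recorded coordinate maps, and the read is
    globally aligned to each with edlib.  The lower edit distance wins the
    primary assignment; ties within ``tie_slop`` — the norm inside collapsed
    regions, where both windows hold the same sequence up to boundary
    rounding — are broken by a seeded coin flip, reproducing real aligner
    behaviour in false homozygosity.  The losing alignment is kept as a
    secondary record so the phasing stage can re-score reads against both
    haplotypes.
    """
    if draft.truth_to_draft is None:
        raise ValueError("draft lacks truth_to_draft maps; use corrupt_assembly")
    rng = np.random.default_rng(seed)
    out: list[AlignmentRecord] = []
    for read in reads:
        hap, contig, start, strand = origins[read.query_name]
        other = "hap2" if hap == "hap1" else "hap1"
        rl = len(read.query_seq)
        end = read.target_end  # truth-hap coords

        if hap == "hap1":
            span_other = (
                truth.hap1_to_hap2[contig](start),
                truth.hap1_to_hap2[contig](end),
            )
        else:
            span_other = (
                truth.hap2_to_hap1[contig](start),
                truth.hap2_to_hap1[contig](end),
            )
        spans = {hap: (start, end), other: span_other}

        # generous distance bound: read errors + het divergence + slack
        bound = int(rl * 0.02 + 150)
        alns: dict[str, tuple[int, int, list[tuple[str, int]]]] = {}
        for h in (hap, other):
            dseq = draft.haplotypes[h][contig]
            m = draft.truth_to_draft[h][contig]
            s, e = spans[h]
            w0 = max(0, m(s))
            w1 = min(len(dseq), max(w0 + 1, m(e)))
            window = dseq[w0:w1]
            res = edlib.align(read.query_seq, window, mode="NW", task="path", k=bound)
            if res["editDistance"] < 0:  # bound exceeded; rare, retry unbounded
                res = edlib.align(read.query_seq, window, mode="NW", task="path")
            alns[h] = (res["editDistance"], w0, parse_cigar(res["cigar"]))

        d_own, d_oth = alns[hap][0], alns[other][0]
        if abs(d_own - d_oth) <= tie_slop:
            primary = hap if rng.random() < 0.5 else other
        elif d_own < d_oth:
            primary = hap
        else:
            primary = other

        for h in (hap, other):
            dist, t0, cigar = alns[h]
            out.append(
                AlignmentRecord(
                    query_name=read.query_name,
                    query_seq=read.query_seq,
                    target_name=DiploidAssembly.full_name(contig, h),
                    target_start=t0,
                    cigar=cigar,
                    strand=strand,
                    mapq=60,
                    query_quals=read.query_quals,
                    tags={"NM": dist, "HP": 1 if h == "hap1" else 2},
                    is_secondary=(h != primary),
                )
            )
    return out
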