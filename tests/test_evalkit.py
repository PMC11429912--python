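"""K-mer QV machinery, error-track annotation, GQ sweep, and gene impact."""

import math

import numpy as np
import pytest

from hapolish.alignio import AlignmentRecord, GenomicInterval, parse_cigar
from hapolish.evalkit import (
    FIXED,
    INDUCED,
    UNCHANGED,
    KmerDB,
    LabeledEdit,
    align_cds,
    annotate_edits,
    annotate_error_kmers,
    delta_qv,
    detect_frameshifts,
    detect_nonsynonymous,
    detect_premature_stops,
    error_kmers,
    error_reduction,
    stratify_error_context,
    sweep_gq,
)
from hapolish.polisher import PolishEdit


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestKmerQV:
    def test_assembly_contained_in_reads_caps_qv(self):
        rng = np.random.default_rng(0)
        seq = random_seq(rng, 500)
        db = KmerDB.from_sequences([seq], k=21)
        intervals, report = error_kmers(seq, db, 21)
        assert intervals == []
        assert report.error_kmers == 0
        assert report.capped and report.qv == 99.0

    def test_single_substitution_yields_k_error_kmers_one_interval(self):
        rng = np.random.default_rng(1)
        k = 31
        seq = random_seq(rng, 400)
        db = KmerDB.from_sequences([seq], k=k)
        mid = 200
        mutated = seq[:mid] + ("A" if seq[mid] != "A" else "C") + seq[mid + 1 :]
        intervals, report = error_kmers(mutated, db, k)
        assert report.error_kmers == k
        assert len(intervals) == 1
        assert len(intervals[0]) == 2 * k - 1

    def test_printed_error_rate_and_qv_pair(self):
        # an error rate of 8.14 per Mb corresponds to QV 50.9
        k, T = 31, 10**6
        E = 8.14e-6
        B = round(T * (1 - (1 - E) ** k))
        from hapolish.evalkit import _qv_from_counts

        report = _qv_from_counts(T, B, k)
        assert report.qv == pytest.approx(50.9, abs=0.05)
        assert report.errors_per_mb == pytest.approx(8.14, abs=0.05)

    def test_qv_errors_per_mb_identity_always_holds(self):
        from hapolish.evalkit import _qv_from_counts

        rng = np.random.default_rng(2)
        for _ in range(50):
            T = int(rng.integers(1000, 10**7))
            B = int(rng.integers(0, T // 10))
            r = _qv_from_counts(T, B, 31)
            assert r.errors_per_mb == pytest.approx(
                10 ** (-r.qv / 10) * 1e6, rel=1e-9
            )

    def test_sequence_shorter_than_k_is_an_error(self):
        db = KmerDB.from_sequences(["ACGTACGTACGT"], k=9)
        with pytest.raises(ValueError):
            error_kmers("ACGT", db, 9)

    def test_canonical_kmers_are_strand_neutral(self):
        rng = np.random.default_rng(3)
        seq = random_seq(rng, 300)
        rc = seq[::-1].translate(str.maketrans("ACGT", "TGCA"))
        db = KmerDB.from_sequences([rc], k=21)
        _, report = error_kmers(seq, db, 21)
        assert report.error_kmers == 0


class TestDeltaQV:
    def test_no_change_is_zero(self):
        assert delta_qv(100, 100) == 0.0

    def test_halving_errors_gains_3_01(self):
        assert delta_qv(200, 100) == pytest.approx(3.0103, abs=1e-4)

    def test_zero_after_is_capped(self):
        assert delta_qv(100, 0) == 99.0

    def test_zero_before_is_an_error(self):
        with pytest.raises(ValueError):
            delta_qv(0, 10)

    def test_additivity(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            b, a1, a2 = sorted(rng.integers(1, 10**6, 3))[::-1]
            assert delta_qv(b, a1) + delta_qv(a1, a2) == pytest.approx(
                delta_qv(b, a2), abs=1e-9
            )


def _identity_aln(name, length):
    return AlignmentRecord(
        query_name=name, query_seq="", target_name=name,
        target_start=0, cigar=parse_cigar(f"{length}="),
    )


class TestAnnotateErrorKmers:
    def test_identical_tracks_all_unchanged(self):
        raw = [GenomicInterval("c", 10, 40), GenomicInterval("c", 100, 130)]
        track = annotate_error_kmers(raw, raw, [_identity_aln("c", 200)], {"c": 200})
        assert track.base_counts[FIXED] == 0
        assert track.base_counts[INDUCED] == 0
        assert track.base_counts[UNCHANGED] == 60

    def test_raw_only_interval_is_fixed(self):
        raw = [GenomicInterval("c", 10, 40)]
        track = annotate_error_kmers(raw, [], [_identity_aln("c", 200)], {"c": 200})
        assert track.base_counts[FIXED] == 30
        assert track.by_status(FIXED) == raw

    def test_polished_only_interval_is_induced(self):
        pol = [GenomicInterval("c", 50, 70)]
        track = annotate_error_kmers([], pol, [_identity_aln("c", 200)], {"c": 200})
        assert track.base_counts[INDUCED] == 20

    def test_insertion_shift_matches_per_base_mask_oracle(self):
        # polished has a 5 bp insertion at 100: polished coords >= 100 map
        # back shifted by -5
        aln = AlignmentRecord(
            query_name="c", query_seq="", target_name="c",
            target_start=0, cigar=parse_cigar("100=5I100="),
        )
        raw = [GenomicInterval("c", 50, 60), GenomicInterval("c", 150, 160)]
        pol = [GenomicInterval("c", 50, 60), GenomicInterval("c", 160, 170)]
        track = annotate_error_kmers(raw, pol, [aln], {"c": 200})
        # oracle: polished 160-170 -> raw 155-165 via explicit map
        raw_mask = np.zeros(200, bool)
        for iv in raw:
            raw_mask[iv.start : iv.end] = True
        proj_mask = np.zeros(200, bool)
        proj_mask[50:60] = True
        proj_mask[155:165] = True
        assert track.base_counts[UNCHANGED] == int((raw_mask & proj_mask).sum())
        assert track.base_counts[FIXED] == int((raw_mask & ~proj_mask).sum())
        assert track.base_counts[INDUCED] == int((~raw_mask & proj_mask).sum())

    def test_interval_length_accounting_balances_exactly(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            L = 1000
            raw = _random_track(rng, L)
            pol = _random_track(rng, L)
            track = annotate_error_kmers(raw, pol, [_identity_aln("c", L)], {"c": L})
            raw_bases = _mask(raw, L).sum()
            pol_bases = _mask(pol, L).sum()
            assert track.base_counts[FIXED] + track.base_counts[UNCHANGED] == raw_bases
            assert track.base_counts[INDUCED] + track.base_counts[UNCHANGED] == pol_bases


def _random_track(rng, L):
    out = []
    pos = 0
    while pos < L - 50:
        pos += int(rng.integers(10, 100))
        end = min(L, pos + int(rng.integers(5, 40)))
        if pos < end:
            out.append(GenomicInterval("c", pos, end))
        pos = end
    return out


def _mask(ivs, L):
    m = np.zeros(L, bool)
    for iv in ivs:
        m[iv.start : iv.end] = True
    return m


class TestAnnotateEdits:
    def _track(self):
        from hapolish.evalkit import ErrorKmerTrack

        return ErrorKmerTrack(
            intervals=[
                GenomicInterval("c", 10, 40),
                GenomicInterval("c", 60, 90),
                GenomicInterval("c", 120, 150),
            ],
            status=[FIXED, INDUCED, UNCHANGED],
            base_counts={FIXED: 30, INDUCED: 30, UNCHANGED: 30},
            interval_counts={FIXED: 1, INDUCED: 1, UNCHANGED: 1},
        )

    def test_labels_by_overlap(self):
        track = self._track()
        edits = [
            PolishEdit("c", 20, "A", "G", 30),
            PolishEdit("c", 70, "A", "G", 30),
            PolishEdit("c", 130, "A", "G", 30),
            PolishEdit("c", 200, "A", "G", 30),
        ]
        labels = [le.label for le in annotate_edits(edits, track)]
        assert labels == ["fixes", "induces", "no_change", "none"]

    def test_multi_overlap_precedence_induces_wins(self):
        track = self._track()
        # an edit spanning both a fixed and an induced interval
        e = PolishEdit("c", 35, "A" * 30, "A", 30)
        (le,) = annotate_edits([e], track)
        assert le.label == "induces"
        assert le.n_fixed == 1 and le.n_induced == 1


def _le(gq, cls_ref_alt, n_fixed=0, n_induced=0):
    ref, alt = cls_ref_alt
    return LabeledEdit(
        PolishEdit("c", 0, ref, alt, gq),
        "induces" if n_induced else ("fixes" if n_fixed else "none"),
        n_fixed=n_fixed,
        n_induced=n_induced,
    )


class TestSweepGQ:
    def test_no_induced_edits_optimum_at_zero(self):
        edits = [_le(g, ("A", "G"), n_fixed=1) for g in (5, 10, 15, 20)]
        for scenario in ("single", "ins1+rest", "ins1+del1+rest"):
            res = sweep_gq(edits, scenario, unchanged_errors=10)
            assert all(c == 0 for c in res.cutoffs.values())

    def test_inducing_ins1_class_gets_cut_above_its_gqs(self):
        edits = [_le(g, ("A", "AT"), n_induced=1) for g in (3, 6, 9)]
        edits += [_le(g, ("A", "G"), n_fixed=1) for g in (4, 8, 12)]
        res = sweep_gq(edits, "ins1+rest", unchanged_errors=5)
        assert res.cutoffs["INS1"] > 9
        assert res.cutoffs["OTHER"] == 0

    def test_three_class_scenario_never_worse_than_single(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            edits = []
            for _ in range(30):
                kind = rng.integers(0, 3)
                ra = [("A", "AT"), ("AT", "A"), ("A", "G")][kind]
                if rng.random() < 0.5:
                    edits.append(_le(int(rng.integers(0, 26)), ra, n_induced=1))
                else:
                    edits.append(_le(int(rng.integers(0, 26)), ra, n_fixed=1))
            single = sweep_gq(edits, "single", unchanged_errors=20)
            triple = sweep_gq(edits, "ins1+del1+rest", unchanged_errors=20)
            assert triple.delta_qv >= single.delta_qv - 1e-12

    def test_matches_independent_exhaustive_enumeration(self):
        from hapolish.finalize import classify_edit

        rng = np.random.default_rng(7)
        edits = []
        for _ in range(20):
            kind = rng.integers(0, 3)
            ra = [("A", "AT"), ("AT", "A"), ("A", "G")][kind]
            edits.append(
                _le(int(rng.integers(0, 26)), ra,
                    n_fixed=int(rng.integers(0, 3)), n_induced=int(rng.integers(0, 3)))
            )
        unchanged = 15
        res = sweep_gq(edits, "ins1+del1+rest", unchanged_errors=unchanged)

        before = unchanged + sum(le.n_fixed for le in edits)
        best = (-math.inf, None)
        for ci in range(26):
            for cd in range(26):
                for co in range(26):
                    cut = {"INS1": ci, "DEL1": cd, "OTHER": co}
                    after = before
                    for le in edits:
                        if le.edit.gq >= cut[classify_edit(le.edit)]:
                            after += le.n_induced - le.n_fixed
                    d = 99.0 if after <= 0 else min(99.0, -10 * math.log10(after / before))
                    if d > best[0]:
                        best = (d, cut)
        assert res.delta_qv == pytest.approx(best[0])
        assert res.curve[
            (res.cutoffs["INS1"], res.cutoffs["DEL1"], res.cutoffs["OTHER"])
        ] == pytest.approx(best[0])

    def test_degenerate_no_edits(self):
        res = sweep_gq([], "single")
        assert res.delta_qv == 0.0


class TestContextStratification:
    def test_eleven_base_homopolymer_detected_at_boundary(self):
        seq = "GCGC" + "A" * 11 + "GCGC"
        counts = stratify_error_context(
            [GenomicInterval("c", 4, 15)], {"c": seq}
        )
        assert counts["homopolymer"] == 1
        counts10 = stratify_error_context(
            [GenomicInterval("c", 4, 15)], {"c": "GCGC" + "A" * 10 + "GCGCG"}
        )
        assert counts10["homopolymer"] == 0

    def test_gc_fraction_above_threshold(self):
        kmer = "G" * 5 + "C" * 17 + "A" * 9  # 22/31 = 0.71
        counts = stratify_error_context([GenomicInterval("c", 0, 31)], {"c": kmer})
        assert counts["high_gc"] == 1
        low = "G" * 5 + "C" * 16 + "A" * 10  # 21/31 = 0.677
        assert stratify_error_context([GenomicInterval("c", 0, 31)], {"c": low})["high_gc"] == 0

    def test_uniform_high_depth_has_no_low_coverage_overlap(self):
        seq = "ACGT" * 25
        depth = {"c": np.full(100, 30)}
        counts = stratify_error_context(
            [GenomicInterval("c", 10, 40)], {"c": seq}, depth
        )
        assert counts["low_coverage"] == 0
        assert counts["cov_10_150"] == 1

    def test_low_coverage_band_assignment(self):
        seq = "ACGT" * 25
        depth = {"c": np.concatenate([np.full(50, 2), np.full(50, 30)])}
        counts = stratify_error_context(
            [GenomicInterval("c", 40, 60)], {"c": seq}, depth
        )
        assert counts["low_coverage"] == 1
        assert counts["cov_0_5"] == 1


class TestGeneImpact:
    def test_frameshift_rule_disjunction(self):
        rng = np.random.default_rng(9)
        ref = "ATG" + "".join(rng.choice(list("ACGT"), 60)) + "TAA"  # 66 nt
        for gap, expect in ((3, 0), (4, 1), (33, 1)):
            asm = ref[:12] + ref[12 + gap :]
            aln = align_cds("tx", ref, asm)
            found = detect_frameshifts(aln)
            assert len(found) == expect, (gap, found)

    def test_terminal_stop_is_not_premature(self):
        assert detect_premature_stops("ATGAAATAA") == []

    def test_internal_stop_detected(self):
        assert detect_premature_stops("ATGTAAAAATAA") == [1]

    def test_premature_stops_match_frame_walk_oracle(self):
        rng = np.random.default_rng(8)
        seq = "".join(rng.choice(list("ACGT"), 900))
        got = detect_premature_stops(seq)
        want = [
            i
            for i in range(len(seq) // 3 - 1)
            if seq[3 * i : 3 * i + 3] in {"TAA", "TAG", "TGA"}
        ]
        assert got == want

    def test_synonymous_change_excluded(self):
        assert detect_nonsynonymous("CTTAAA", "CTCAAA") == []

    def test_nonsynonymous_change_reported_with_amino_acids(self):
        assert detect_nonsynonymous("CTTAAA", "CCTAAA") == [(0, "L", "P")]

    def test_identical_sequences_empty(self):
        assert detect_nonsynonymous("ATGGCT", "ATGGCT") == []

    def test_length_mismatch_is_an_error(self):
        with pytest.raises(ValueError):
            detect_nonsynonymous("ATGGCT", "ATGGC")

    def test_error_reduction_closed_form(self):
        assert error_reduction(3.0103) == pytest.approx(0.5, abs=1e-4)
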