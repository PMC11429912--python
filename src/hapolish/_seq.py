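"""Low-level sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

BASES = "ACGT"
_BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def seq_to_codes(seq: str) -> np.ndarray:
    """2-bit codes (A=0, C=1, G=2, T=3); anything else becomes 4."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, 4, dtype=np.uint8)
    for base, code in _BASE_TO_CODE.items():
        codes[arr == ord(base)] = code
    return codes


def codes_to_seq(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def homopolymer_runs(seq: str, min_len: int) -> list[tuple[int, int]]:
    """Maximal single-base runs of length >= min_len as 0-based [start, end)."""
    if not seq:
        return []
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    change = np.flatnonzero(arr[1:] != arr[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(arr)]))
    keep = (ends - starts) >= min_len
    return list(zip(starts[keep].tolist(), ends[keep].tolist()))


def homopolymer_mask(seq: str, min_len: int) -> np.ndarray:
    mask = np.zeros(len(seq), dtype=bool)
    for s, e in homopolymer_runs(seq, min_len):
        mask[s:e] = True
    return mask


def apply_variant_list(seq: str, variants) -> str:
    """Apply sorted, non-overlapping VCF-style (pos, ref, alt) records.

    ``pos`` is 0-based on ``seq``; ``ref`` must match the sequence (checked).
    Raises ValueError naming the locus on any REF mismatch, which guards
    against coordinate bookkeeping bugs upstream.
    """
    pieces = []
    cursor = 0
    last_end = -1
    for pos, ref, alt in variants:
        if pos < last_end:
            raise ValueError(f"overlapping edits at position {pos}")
        if seq[pos : pos + len(ref)] != ref:
            raise ValueError(
                f"REF mismatch at position {pos}: expected {ref!r}, "
                f"assembly has {seq[pos:pos + len(ref)]!r}"
            )
        pieces.append(seq[cursor:pos])
        pieces.append(alt)
        cursor = pos + len(ref)
        last_end = cursor
    pieces.append(seq[cursor:])
    return "".join(pieces)
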