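"""Shared low-level helpers: 2-bit-ish sequence codes and indel normalization."""

from __future__ import annotations

import numpy as np

# byte-code mapping: A=0 C=1 G=2 T=3 N=4
_CODE = np.full(256, 255, dtype=np.uint8)
for i, c in enumerate("ACGTN"):
    _CODE[ord(c)] = i
_CHARS = np.frombuffer(b"ACGTN", dtype=np.uint8)
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def encode_seq(seq: str) -> np.ndarray:
    """Uppercase ACGTN string -> uint8 code array."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CODE[raw]
    if (codes == 255).any():
        bad = chr(raw[int(np.argmax(codes == 255))])
        raise ValueError(f"invalid nucleotide {bad!r}")
    return codes


def decode_seq(codes: np.ndarray) -> str:
    return _CHARS[codes].tobytes().decode("ascii")


def revcomp_arr(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes][::-1]


def complement_arr(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes]


def left_align_indel(ref_seq: str, ref_pos: int, seq: str) -> tuple[int, str]:
    """Shift an indel maximally left within its reference context.

    ``ref_pos`` is the 0-based reference base immediately preceding the event;
    ``seq`` is the inserted (or deleted) bases as they read on the reference
    forward strand.  Returns the normalized ``(ref_pos, seq)``.  The rule is
    the VCF one: while the base before the event equals the last base of the
    indel sequence, rotate the sequence right and step left.
    """
    while ref_pos >= 1 and seq and ref_seq[ref_pos] == seq[-1]:
        seq = ref_seq[ref_pos] + seq[:-1]
        ref_pos -= 1
    return ref_pos, seq
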