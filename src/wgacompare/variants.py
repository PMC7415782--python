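"""SNP and indel extraction from one-to-one alignment blocks.

Walking each block's edit path yields one SNP per mismatch column and one
indel per maximal run of insertion/deletion columns.  Query coordinates and
bases are strand-adjusted: for reverse blocks the reported query base is the
complement of the query genome's forward-strand base at the mapped position.
Indels are left-aligned within their reference context (the VCF convention).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

from .align import AlignmentBlock, check_one_to_one, _align_gap, _merge_runs
from .errors import ParameterError, PreconditionError
from .io import GenomeSequence
from .util import decode_seq, encode_seq, left_align_indel, revcomp_arr

_COMP = str.maketrans("ACGTN", "TGCAN")

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
SUBSTITUTION_TYPES = [f"{a}>{b}" for a in "ACGT" for b in "ACGT" if a != b]


@dataclass(frozen=True)
class SNPRecord:
    ref_chrom: str
    ref_pos: int            # 0-based
    ref_base: str
    qry_base: str           # on the reference forward strand
    qry_chrom: str
    qry_pos: int            # 0-based, original query coordinates
    block_id: str


@dataclass(frozen=True)
class IndelRecord:
    ref_chrom: str
    ref_pos: int            # 0-based base preceding the event
    kind: str               # insertion | deletion
    seq: str                # inserted/deleted bases (reference orientation)
    length: int
    qry_chrom: str
    qry_pos: int
    block_id: str


def call_variants(blocks: list[AlignmentBlock], ref: list[GenomeSequence],
                  qry: list[GenomeSequence], mask_near_gap: int = 0
                  ) -> tuple[list[SNPRecord], list[IndelRecord]]:
    """Extract SNPs and indels from one-to-one blocks with edit paths.

    ``mask_near_gap > 0`` drops SNPs within that many alignment columns of an
    indel column (sensitivity analysis; default keeps them, show-snp-like).
    Raises :class:`PreconditionError` when blocks are not one-to-one.
    """
    check_one_to_one(blocks)
    ref_by = {g.id: g.seq for g in ref}
    qry_by = {g.id: g.seq for g in qry}

    snps: list[SNPRecord] = []
    indels: list[IndelRecord] = []
    for b in blocks:
        if not b.edit_path:
            raise PreconditionError(f"block {b.id} has no edit path")
        rseq = ref_by[b.ref_chrom]
        qseq = qry_by[b.qry_chrom]
        if b.strand == "-":
            q_oriented = decode_seq(revcomp_arr(encode_seq(
                qseq[b.qry_start:b.qry_end])))
        else:
            q_oriented = qseq[b.qry_start:b.qry_end]

        # column classes for the optional near-gap mask
        gap_cols: list[tuple[int, int]] = []
        col = 0
        for op, n in b.edit_path:
            if op in "ID":
                gap_cols.append((col, col + n))
            col += n

        def near_gap(c: int) -> bool:
            if mask_near_gap <= 0:
                return False
            return any(s - mask_near_gap <= c < e + mask_near_gap
                       for s, e in gap_cols)

        rp = b.ref_start          # absolute ref position
        qp = 0                    # position in oriented query segment
        col = 0
        for op, n in b.edit_path:
            if op == "=":
                rp += n
                qp += n
            elif op == "X":
                for i in range(n):
                    if not near_gap(col + i):
                        qpos = _orig_qpos(b, qp + i)
                        qbase = q_oriented[qp + i]
                        snps.append(SNPRecord(
                            b.ref_chrom, rp + i, rseq[rp + i], qbase,
                            b.qry_chrom, qpos, b.id))
                rp += n
                qp += n
            elif op == "D":       # bases present in ref, absent in qry
                seq = rseq[rp: rp + n]
                pos, seq_n = left_align_indel(rseq, rp - 1, seq)
                qpos = _orig_qpos(b, qp - 1 if qp > 0 else 0)
                indels.append(IndelRecord(
                    b.ref_chrom, pos, "deletion", seq_n, n,
                    b.qry_chrom, qpos, b.id))
                rp += n
            elif op == "I":       # bases present in qry, absent in ref
                seq = q_oriented[qp: qp + n]
                pos, seq_n = left_align_indel(rseq, rp - 1, seq)
                qpos = _orig_qpos(b, qp)
                indels.append(IndelRecord(
                    b.ref_chrom, pos, "insertion", seq_n, n,
                    b.qry_chrom, qpos, b.id))
                qp += n
            else:
                raise PreconditionError(f"unknown edit op {op!r}")
            col += n

    snps.sort(key=lambda s: (s.ref_chrom, s.ref_pos))
    indels.sort(key=lambda d: (d.ref_chrom, d.ref_pos))
    return snps, indels


def _orig_qpos(b: AlignmentBlock, qp_oriented: int) -> int:
    if b.strand == "+":
        return b.qry_start + qp_oriented
    return b.qry_end - 1 - qp_oriented


@dataclass
class SNPSpectrum:
    """Counts and fractions of the 12 directed substitution types."""

    counts: dict[str, int]
    total: int
    zero_total: bool

    @property
    def fractions(self) -> dict[str, float]:
        if self.total == 0:
            return {k: float("nan") for k in self.counts}
        return {k: v / self.total for k, v in self.counts.items()}

    @property
    def transition_fraction(self) -> float:
        if self.total == 0:
            return float("nan")
        ts = sum(v for k, v in self.counts.items()
                 if (k[0], k[2]) in TRANSITIONS)
        return ts / self.total


def spectrum(snps: list[SNPRecord]) -> SNPSpectrum:
    """Directed substitution spectrum (ref base -> query base)."""
    c = Counter(f"{s.ref_base}>{s.qry_base}" for s in snps)
    counts = {t: c.get(t, 0) for t in SUBSTITUTION_TYPES}
    total = sum(counts.values())
    return SNPSpectrum(counts=counts, total=total, zero_total=total == 0)


def variant_density(count: int, genome_size: int) -> float:
    """Variants per kilobase, one decimal, round half away from zero."""
    if genome_size <= 0:
        raise ParameterError("genome_size must be > 0")
    dens = Decimal(count) / (Decimal(genome_size) / 1000)
    return float(dens.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class DiffEvent:
    kind: str               # insertion | deletion | substitution
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    length: int


_DNA_ALIGNER = None


def _affine_align(seq_a: str, seq_b: str) -> list[tuple[str, int]]:
    """Global affine-gap alignment (match +1, mismatch -1, gap open -4,
    extend -1) as run-length edit ops; gaps stay contiguous rather than
    fragmenting into equal-cost pieces."""
    global _DNA_ALIGNER
    if _DNA_ALIGNER is None:
        from Bio.Align import PairwiseAligner
        a = PairwiseAligner()
        a.match_score = 1
        a.mismatch_score = -1
        a.open_gap_score = -5       # gap of length k costs 4 + k
        a.extend_gap_score = -1
        a.mode = "global"
        _DNA_ALIGNER = a
    aln = _DNA_ALIGNER.align(seq_a, seq_b)[0]
    runs: list[tuple[str, int]] = []
    ia = ib = 0
    for (sa, ea), (sb, eb) in zip(*aln.aligned):
        if sa > ia:
            runs.append(("D", sa - ia))
        if sb > ib:
            runs.append(("I", sb - ib))
        for k in range(ea - sa):
            runs.append(("=" if seq_a[sa + k] == seq_b[sb + k] else "X", 1))
        ia, ib = ea, eb
    if len(seq_a) > ia:
        runs.append(("D", len(seq_a) - ia))
    if len(seq_b) > ib:
        runs.append(("I", len(seq_b) - ib))
    return _merge_runs(runs)


def promoter_diff(seq_a: str, seq_b: str, min_event: int = 5
                  ) -> list[DiffEvent]:
    """Large difference events between two (promoter-scale) sequences.

    Globally aligns the two sequences with affine gap costs and reports
    maximal gap runs and substitution runs of length >= ``min_event`` with
    coordinates in both.  Insertions are bases present in B only; deletions
    present in A only.
    """
    if not seq_a or not seq_b:
        raise ParameterError("both sequences must be non-empty")
    runs = _affine_align(seq_a, seq_b)
    events = []
    ap = bp = 0
    for op, n in runs:
        if op == "X" and n >= min_event:
            events.append(DiffEvent("substitution", ap, ap + n, bp, bp + n, n))
        elif op == "I" and n >= min_event:
            events.append(DiffEvent("insertion", ap, ap, bp, bp + n, n))
        elif op == "D" and n >= min_event:
            events.append(DiffEvent("deletion", ap, ap + n, bp, bp, n))
        if op in "=X":
            ap += n
            bp += n
        elif op == "D":
            ap += n
        else:
            bp += n
    return events
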