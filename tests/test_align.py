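"""Whole-genome aligner: MUM anchors against a quadratic oracle, chain
selection against exhaustive search, block construction and one-to-one
selection invariants."""

import numpy as np
import pytest

from wgacompare.align import (align_genomes, best_chain, brute_force_chain,
                              chain_and_extend, chain_precedes, filter_blocks,
                              find_anchors, one_to_one, read_blocks,
                              trim_block, write_blocks, AlignmentBlock)
from wgacompare.io import GenomeSequence, revcomp
from wgacompare.simulate import generate_ancestor


def count_overlapping(hay: str, needle: str) -> int:
    c = i = 0
    while True:
        i = hay.find(needle, i)
        if i < 0:
            return c
        c += 1
        i += 1


def brute_mums(ref: str, qry: str, min_len: int) -> set:
    """Quadratic all-substring MUM scan (forward strand)."""
    out = set()
    for i in range(len(ref)):
        for j in range(len(qry)):
            if ref[i] != qry[j]:
                continue
            if i > 0 and j > 0 and ref[i - 1] == qry[j - 1]:
                continue
            l = 0
            while (i + l < len(ref) and j + l < len(qry)
                   and ref[i + l] == qry[j + l]):
                l += 1
            if l < min_len:
                continue
            sub = ref[i:i + l]
            if (count_overlapping(ref, sub) == 1
                    and count_overlapping(qry, sub) == 1):
                out.add((i, j, l))
    return out


class TestFindAnchors:
    def test_identity_genome_single_forward_anchor(self):
        s = "ACGTACGTTTTTGGGGCCCCAAAA"
        g = [GenomeSequence("c1", s)]
        fwd = [a for a in find_anchors(g, g, 10) if a.strand == "+"]
        assert len(fwd) == 1
        assert fwd[0].length == len(s) and fwd[0].ref_start == 0

    def test_reverse_complement_gives_minus_anchor(self):
        s = "ACGTACGTTTTTGGGGCCCCAAAA"
        g = [GenomeSequence("c1", s)]
        g2 = [GenomeSequence("c1", revcomp(s))]
        an = find_anchors(g, g2, 10)
        assert any(a.strand == "-" and a.length == len(s)
                   and a.ref_start == 0 and a.qry_start == 0 for a in an)

    def test_repeated_kmer_yields_no_anchor_in_repeat(self):
        core = "ACGGTCAATCGGTAC"          # repeated 15-mer
        ref = "TTGCAT" + core + "GACCTAGG" + core + "CTTAAGC"
        qry = ref
        got = {(a.ref_start, a.qry_start, a.length)
               for a in find_anchors([GenomeSequence("r", ref)],
                                     [GenomeSequence("q", qry)], 10)
               if a.strand == "+"}
        assert got == brute_mums(ref, qry, 10)
        assert not any(s <= 6 < s + l <= 21 and l <= 15 for s, _q, l in got)

    @pytest.mark.parametrize("seed", range(10))
    def test_fuzz_matches_quadratic_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(30, 120))
        ref = "".join("ACGT"[i] for i in rng.integers(0, 4, n))
        q = list(ref)
        for _ in range(int(rng.integers(0, 6))):
            p = int(rng.integers(0, n))
            q[p] = "ACGT"[int(rng.integers(0, 4))]
        qry = "".join(q)
        min_len = int(rng.integers(5, 12))
        got = {(a.ref_start, a.qry_start, a.length)
               for a in find_anchors([GenomeSequence("r", ref)],
                                     [GenomeSequence("q", qry)], min_len)
               if a.strand == "+"}
        assert got == brute_mums(ref, qry, min_len)

    def test_anchor_set_symmetric_under_role_swap(self):
        genomes, _ = generate_ancestor(1, 5000, 0, seed=4)
        other = [GenomeSequence("c1", genomes[0].seq[:2500]
                                + revcomp(genomes[0].seq[3000:4000])
                                + genomes[0].seq[2500:3000])]
        fwd = find_anchors(genomes, other, 20)
        back = find_anchors(other, genomes, 20)
        assert {(a.ref_start, a.qry_start, a.length, a.strand)
                for a in fwd} == \
               {(a.qry_start, a.ref_start, a.length, a.strand)
                for a in back}

    def test_n_bases_never_inside_anchors(self):
        genomes, _ = generate_ancestor(1, 2000, 0, seed=5)
        seq = genomes[0].seq[:1000] + "N" * 10 + genomes[0].seq[1010:]
        withn = [GenomeSequence("c1", seq)]
        for a in find_anchors(withn, withn, 15):
            assert "N" not in seq[a.ref_start:a.ref_start + a.length]


class TestChaining:
    def test_collinear_subset_selected(self):
        # of three anchors, the off-diagonal one is dropped
        r = np.array([0, 10, 6])
        q = np.array([0, 10, 20])
        L = np.array([5, 5, 5])
        chain, w = best_chain(r, q, L)
        assert sorted(chain) == [0, 1] and w == 10
        assert brute_force_chain(r, q, L) == 10

    @pytest.mark.parametrize("seed", range(12))
    def test_fuzz_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 9))
        r = rng.integers(0, 200, n)
        q = rng.integers(0, 200, n)
        L = rng.integers(3, 60, n)
        _, w = best_chain(r, q, L)
        assert w == brute_force_chain(r, q, L)

    def test_precedence_predicate_orders_strictly(self):
        assert chain_precedes(0, 0, 5, 10, 10, 5)
        assert not chain_precedes(10, 10, 5, 0, 0, 5)
        assert not chain_precedes(0, 20, 5, 10, 10, 5)


class TestBlocks:
    def test_identical_genomes_single_perfect_block(self):
        genomes, _ = generate_ancestor(1, 10_000, 0, seed=3)
        blocks = align_genomes(genomes, genomes)
        assert len(blocks) == 1
        b = blocks[0]
        assert b.identity == 100.0
        assert b.edit_path == [("=", 10_000)]
        assert (b.ref_end - b.ref_start) == 10_000

    def test_single_snp_identity_and_path(self):
        genomes, _ = generate_ancestor(1, 10_000, 0, seed=3)
        s = genomes[0].seq
        alt = "A" if s[5000] != "A" else "C"
        qry = [GenomeSequence("chr1", s[:5000] + alt + s[5001:])]
        (b,) = align_genomes(genomes, qry)
        assert abs(b.identity - 99.99) < 0.011
        assert sum(1 for op, _n in b.edit_path if op == "X") == 1

    def test_identity_recomputable_from_path(self):
        genomes, _ = generate_ancestor(1, 20_000, 0, seed=6)
        s = genomes[0].seq
        qry = [GenomeSequence("chr1", s[:8000] + s[8100:15000]
                              + "ACGT" * 5 + s[15000:])]
        for b in align_genomes(genomes, qry):
            ident, cols = b.recompute_identity()
            assert abs(ident - b.identity) <= 0.01
            assert cols == b.aligned_columns

    def test_full_pipeline_covers_self_alignment(self):
        genomes, _ = generate_ancestor(2, 30_000, 3, seed=7)
        blocks = align_genomes(genomes, genomes)
        cov = sum(b.ref_end - b.ref_start for b in blocks)
        total = sum(g.length for g in genomes)
        assert cov >= 0.999 * total
        assert all(b.identity == 100.0 for b in blocks)

    def test_blocks_tsv_round_trip(self, tmp_path):
        genomes, _ = generate_ancestor(1, 10_000, 0, seed=8)
        s = genomes[0].seq
        qry = [GenomeSequence("chr1", s[:4000] + s[4020:])]
        blocks = align_genomes(genomes, qry)
        p, sp = tmp_path / "b.tsv", tmp_path / "p.tsv"
        write_blocks(blocks, p, sp)
        back = read_blocks(p, sp)
        assert [(b.ref_start, b.ref_end, b.qry_start, b.qry_end, b.strand,
                 b.edit_path) for b in back] == \
               [(b.ref_start, b.ref_end, b.qry_start, b.qry_end, b.strand,
                 b.edit_path) for b in blocks]


def _mk_block(k, rs, re_, qs, qe, ident=100.0, strand="+", chrom="c"):
    L = re_ - rs
    qL = qe - qs
    path = [("=", min(L, qL))]
    if L > qL:
        path.append(("D", L - qL))
    elif qL > L:
        path.append(("I", qL - L))
    nmis = 0
    b = AlignmentBlock(id=f"b{k}", ref_chrom=chrom, ref_start=rs, ref_end=re_,
                       qry_chrom=chrom, qry_start=qs, qry_end=qe,
                       strand=strand, edit_path=path)
    b.finalize()
    b.identity = ident       # synthetic identity for weighting tests
    return b


class TestFilterAndOneToOne:
    def test_identity_boundary_is_inclusive(self):
        blocks = [_mk_block(0, 0, 30000, 0, 30000, ident=79.9),
                  _mk_block(1, 40000, 70000, 40000, 70000, ident=80.0)]
        kept = filter_blocks(blocks, 80, 20000)
        assert [b.id for b in kept] == ["b1"]

    def test_zero_thresholds_keep_everything(self):
        blocks = [_mk_block(0, 0, 100, 0, 100), _mk_block(1, 0, 50, 200, 250)]
        assert filter_blocks(blocks, 0, 0) == blocks

    def test_predicate_count_matches_survivors(self):
        rng = np.random.default_rng(0)
        blocks = []
        for k in range(30):
            rs = int(rng.integers(0, 10**6))
            ln = int(rng.integers(100, 50_000))
            blocks.append(_mk_block(k, rs, rs + ln, rs, rs + ln,
                                    ident=float(rng.uniform(60, 100))))
        kept = filter_blocks(blocks, 85, 10_000)
        expect = sum(1 for b in blocks
                     if b.identity >= 85 and b.ref_end - b.ref_start >= 10_000)
        assert len(kept) == expect

    def test_non_overlapping_input_unchanged(self):
        blocks = [_mk_block(0, 0, 1000, 0, 1000),
                  _mk_block(1, 2000, 3000, 2000, 3000)]
        assert [b.id for b in one_to_one(blocks)] == ["b0", "b1"]

    def test_dominant_block_wins_total_overlap(self):
        # same reference span: weight 100 bases x 99% beats 50 x 80%
        b0 = _mk_block(0, 0, 100, 0, 100, ident=99.0)
        b1 = _mk_block(1, 0, 50, 200, 250, ident=80.0)
        assert [b.id for b in one_to_one([b0, b1], overlap_tol=0)] == ["b0"]

    @pytest.mark.parametrize("seed", range(10))
    def test_fuzz_matches_two_pass_exhaustive(self, seed):
        import itertools
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 8))
        blocks = []
        for k in range(n):
            rs = int(rng.integers(0, 500))
            ln = int(rng.integers(50, 300))
            qs = int(rng.integers(0, 500))
            blocks.append(_mk_block(k, rs, rs + ln, qs, qs + ln,
                                    ident=float(rng.uniform(70, 100))))
        tol = 0

        def conflict(x, y, side):
            s1, e1 = getattr(x, f"{side}_start"), getattr(x, f"{side}_end")
            s2, e2 = getattr(y, f"{side}_start"), getattr(y, f"{side}_end")
            return min(e1, e2) - max(s1, s2) > tol

        def best_subset(blks, side):
            best, best_w = [], -1.0
            for mask in range(1 << len(blks)):
                sel = [b for i, b in enumerate(blks) if mask >> i & 1]
                if any(conflict(x, y, side)
                       for x, y in itertools.combinations(sel, 2)):
                    continue
                w = sum(b.weight for b in sel)
                if w > best_w:
                    best_w, best = w, sel
            return best

        expected = sum(b.weight
                       for b in best_subset(best_subset(blocks, "ref"),
                                            "qry"))
        got = sum(b.weight for b in one_to_one(blocks, overlap_tol=tol))
        assert abs(got - expected) < 1e-9


class TestTrimBlock:
    def test_ref_front_trim_shifts_both_coordinates(self):
        b = _mk_block(0, 100, 200, 500, 600)
        t = trim_block(b, ref_front=10)
        assert (t.ref_start, t.qry_start) == (110, 510)
        assert t.edit_path == [("=", 90)]

    def test_trim_to_nothing_returns_none(self):
        b = _mk_block(0, 0, 50, 0, 50)
        assert trim_block(b, ref_front=50) is None

    def test_minus_strand_qry_trim_maps_to_path_end(self):
        b = AlignmentBlock(id="b", ref_chrom="c", ref_start=0, ref_end=100,
                           qry_chrom="c", qry_start=300, qry_end=400,
                           strand="-", edit_path=[("=", 100)])
        b.finalize()
        t = trim_block(b, qry_front=10)
        # original-coordinate low end of a '-' block is the path's tail
        assert (t.qry_start, t.qry_end) == (310, 400)
        assert (t.ref_start, t.ref_end) == (0, 90)
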