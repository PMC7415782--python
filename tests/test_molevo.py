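"""Molecular evolution: 4DTv degeneracy rules, NG86 Ks against an
independent pathway-enumeration oracle, peak detection, LTR dating and
synteny-based ortholog pairing."""

import itertools
import math

import numpy as np
import pytest

from wgacompare.align import align_genomes
from wgacompare.errors import ParameterError
from wgacompare.molevo import (FOURFOLD_PREFIXES, CodonAlignment,
                               UnreliablePairError, build_codon_alignment,
                               compute_4dtv, compute_ks, extract_cds,
                               is_transversion, ks_peak, ltr_age,
                               pair_orthologs)
from wgacompare.simulate import MutationConfig, evolve_pair, generate_ancestor

BASES = "ACGT"
STOPS = {"TAA", "TAG", "TGA"}

# independent genetic-code table for the oracle, spelled out by hand
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def oracle_ks(seq1: str, seq2: str) -> float:
    """Brute-force NG86-JC: explicit site counts and full pathway
    enumeration, written against the hand-typed code table above."""
    def sites(codon):
        s = n = 0
        for pos, b0 in enumerate(codon):
            for b in BASES:
                if b == b0:
                    continue
                alt = codon[:pos] + b + codon[pos + 1:]
                if alt in STOPS:
                    n += 1
                elif GENETIC_CODE[alt] == GENETIC_CODE[codon]:
                    s += 1
                else:
                    n += 1
        return 3 * s / (s + n)

    S = Sd = 0.0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i:i + 3], seq2[i:i + 3]
        S += (sites(c1) + sites(c2)) / 2
        diff = [k for k in range(3) if c1[k] != c2[k]]
        if not diff:
            continue
        paths = list(itertools.permutations(diff))
        for order in paths:
            cur = c1
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
                if (cur not in STOPS and nxt not in STOPS
                        and GENETIC_CODE[cur] == GENETIC_CODE[nxt]):
                    Sd += 1 / len(paths)
                cur = nxt
    ps = Sd / S
    return -0.75 * math.log(1 - ps * 4 / 3)


def rand_cds(rng, n):
    out = []
    while len(out) < n:
        c = "".join(BASES[i] for i in rng.integers(0, 4, 3))
        if c not in STOPS:
            out.append(c)
    return "".join(out)


class TestFourDTv:
    def test_fourfold_prefix_set_matches_code_table(self):
        expected = {p for p in map("".join,
                                   itertools.product(BASES, repeat=2))
                    if len({GENETIC_CODE[p + b] for b in BASES}) == 1}
        assert FOURFOLD_PREFIXES == expected
        assert expected == {"TC", "CT", "CC", "CG", "AC", "GT", "GC", "GG"}

    def test_worked_example_one_half(self):
        # GGT/GGA: T<->A transversion at a 4D site; GGT/GGC: transition
        st = compute_4dtv(CodonAlignment("a", "b", "GGTGGT", "GGAGGC"))
        assert st.n_4d_sites == 2 and st.n_4d_transversions == 1
        assert st.fourdtv_raw == 0.5

    def test_identical_sequences_zero(self):
        st = compute_4dtv(CodonAlignment("a", "b", "GGTGGT", "GGTGGT"))
        assert st.fourdtv_raw == 0.0

    def test_non_fourfold_codons_flagged_undefined(self):
        st = compute_4dtv(CodonAlignment("a", "b", "ATGATG", "ATGATG"))
        assert "undefined" in st.flags
        assert math.isnan(st.fourdtv_raw)

    def test_transition_only_divergence_gives_zero(self):
        rng = np.random.default_rng(3)
        a = rand_cds(rng, 500)
        trans = {"A": "G", "G": "A", "C": "T", "T": "C"}
        b = list(a)
        for i in range(2, len(a), 3):       # transitions at third positions
            if rng.random() < 0.3:
                cod = a[i - 2:i + 1]
                alt = cod[:2] + trans[cod[2]]
                if alt not in STOPS:
                    b[i] = trans[cod[2]]
        st = compute_4dtv(CodonAlignment("a", "b", a, "".join(b)))
        assert st.fourdtv_raw == 0.0

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(4)
        a, b = rand_cds(rng, 200), rand_cds(rng, 200)
        s1 = compute_4dtv(CodonAlignment("a", "b", a, b))
        s2 = compute_4dtv(CodonAlignment("b", "a", b, a))
        assert s1.n_4d_sites == s2.n_4d_sites
        assert s1.fourdtv_raw == s2.fourdtv_raw


class TestKs:
    def test_identical_sequences_zero(self):
        rng = np.random.default_rng(0)
        a = rand_cds(rng, 100)
        assert compute_ks(CodonAlignment("a", "b", a, a)).ks == 0.0

    def test_nonsynonymous_only_changes_give_zero(self):
        a = "ATGATGATGATG" * 10
        b = "AAGAAGAAGAAG" * 10          # ATG->AAG is nonsynonymous
        assert compute_ks(CodonAlignment("a", "b", a, b)).ks == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pathway_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(20):
            n = int(rng.integers(30, 60))
            a = rand_cds(rng, n)
            b = list(a)
            for _k in range(int(rng.integers(1, 8))):
                p = int(rng.integers(0, 3 * n))
                cand = list(b)
                cand[p] = BASES[int(rng.integers(0, 4))]
                cod = "".join(cand[3 * (p // 3):3 * (p // 3) + 3])
                if cod not in STOPS:
                    b = cand
            b = "".join(b)
            mine = compute_ks(CodonAlignment("a", "b", a, b)).ks
            assert mine == pytest.approx(oracle_ks(a, b), abs=1e-9)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(9)
        a = rand_cds(rng, 100)
        b = list(a)
        for p in rng.integers(0, 300, 12):
            cand = list(b)
            cand[p] = BASES[int(rng.integers(0, 4))]
            if "".join(cand[3 * (p // 3):3 * (p // 3) + 3]) not in STOPS:
                b = cand
        b = "".join(b)
        assert compute_ks(CodonAlignment("a", "b", a, b)).ks == \
            pytest.approx(compute_ks(CodonAlignment("b", "a", b, a)).ks)

    def test_few_codons_flagged_low_confidence(self):
        st = compute_ks(CodonAlignment("a", "b", "GGTGGT", "GGTGGT"))
        assert "low_confidence" in st.flags

    def test_parameter_recovery_at_true_ks(self):
        """Synonymous-only mutation at true Ks 0.1 over 10,000 codons."""
        from wgacompare.molevo import _ng86_site_count, _FORWARD
        rng = np.random.default_rng(42)
        codons = [rand_cds(rng, 1)[0:3] for _ in range(10_000)]

        def syn_neighbors(c):
            out = []
            for pos in range(3):
                for b in BASES:
                    if b == c[pos]:
                        continue
                    alt = c[:pos] + b + c[pos + 1:]
                    if alt not in STOPS and _FORWARD[alt] == _FORWARD[c]:
                        out.append(alt)
            return out

        S = np.array([_ng86_site_count(c) for c in codons])
        n_events = rng.poisson(0.1 * S.sum())
        hits = rng.choice(len(codons), size=n_events, p=S / S.sum())
        mutated = list(codons)
        for t in hits:
            nb = syn_neighbors(mutated[t])
            if nb:
                mutated[t] = nb[int(rng.integers(0, len(nb)))]
        st = compute_ks(CodonAlignment("a", "b", "".join(codons),
                                       "".join(mutated)))
        assert abs(st.ks - 0.1) / 0.1 <= 0.15


class TestKsPeak:
    def test_concentrated_values_single_mode(self):
        vals = np.clip(np.random.default_rng(1).normal(0.05, 0.01, 500),
                       0, None)
        modes = ks_peak(vals)
        assert len(modes) == 1 and 0.02 < modes[0] < 0.08

    def test_uniform_values_no_mode(self):
        vals = np.random.default_rng(2).uniform(0, 3, 500)
        assert ks_peak(vals) == []

    def test_too_few_values_insufficient(self):
        assert ks_peak([0.1] * 10) == "insufficient"


class TestLtrAge:
    def test_identical_repeats_age_zero(self):
        el = ltr_age("e0", "ACGT" * 50, "ACGT" * 50)
        assert el.K == 0.0 and el.age_years == 0.0

    def test_closed_form_arithmetic(self):
        # K = 0.026 at the default rate dates to 1.0 Myr
        assert 0.026 / (2 * 1.3e-8) == pytest.approx(1.0e6)

    def test_divergence_recovery_on_simulated_pair(self):
        rng = np.random.default_rng(5)
        ltr = "".join(BASES[i] for i in rng.integers(0, 4, 1000))

        def mutate(s, d):
            out = list(s)
            for i in np.nonzero(rng.random(len(s)) < d)[0]:
                out[i] = BASES[(BASES.index(out[i])
                                + int(rng.integers(1, 4))) % 4]
            return "".join(out)

        el = ltr_age("e1", mutate(ltr, 0.02), mutate(ltr, 0.02))
        expected_age = 0.04 / (2 * 1.3e-8)
        assert abs(el.age_years - expected_age) / expected_age <= 0.25

    def test_short_repeats_rejected(self):
        with pytest.raises(ParameterError):
            ltr_age("e2", "ACGT" * 10, "ACGT" * 10)

    def test_saturated_pair_rejected(self):
        rng = np.random.default_rng(6)
        a = "".join(BASES[i] for i in rng.integers(0, 4, 300))
        b = "".join(BASES[i] for i in rng.integers(0, 4, 300))
        with pytest.raises(UnreliablePairError):
            ltr_age("e3", a, b)


class TestPairOrthologs:
    def test_single_sided_simulation_recovers_truth_pairs(self,
                                                          small_ancestor):
        anc, models = small_ancestor
        ga, gfa, gb, gfb, truth = evolve_pair(
            anc, models, MutationConfig(),
            MutationConfig(snp_rate=0.003), seed=31)
        blocks = align_genomes(ga, gb)
        pairs, unpaired = pair_orthologs(blocks, gfa, gfb)
        assert dict(pairs) == truth.ortholog_pairs

    def test_deleted_gene_lands_in_unpaired_list(self, small_ancestor):
        anc, models = small_ancestor
        ga, gfa, gb, gfb, truth = evolve_pair(
            anc, models, MutationConfig(), MutationConfig(), seed=32)
        victim = gfb[0].gene_id
        gfb = [g for g in gfb if g.gene_id != victim]
        blocks = align_genomes(ga, gb)
        pairs, unpaired = pair_orthologs(blocks, gfa, gfb)
        assert victim not in dict(pairs)
        assert victim in unpaired

    def test_codon_alignment_of_true_orthologs_is_clean(self,
                                                        small_ancestor):
        anc, models = small_ancestor
        ga, gfa, gb, gfb, truth = evolve_pair(
            anc, models, MutationConfig(),
            MutationConfig(snp_rate=0.002), seed=33)
        ga_by = {g.gene_id: g for g in gfa}
        gb_by = {g.gene_id: g for g in gfb}
        checked = 0
        for ida, idb in list(truth.ortholog_pairs.items())[:5]:
            if ida not in ga_by or idb not in gb_by:
                continue
            cds_a = extract_cds(ga, ga_by[ida])
            cds_b = extract_cds(gb, gb_by[idb])
            if len(cds_a) % 3 or len(cds_b) % 3:
                continue
            aln = build_codon_alignment(ida, cds_a, idb, cds_b)
            st = compute_ks(aln)
            assert st.ks < 0.1
            checked += 1
        assert checked >= 3
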