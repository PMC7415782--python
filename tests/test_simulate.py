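"""Synthetic genome-pair generator: determinism, truth-coordinate exactness
and the conservation laws the downstream recovery tests rely on."""

import numpy as np
import pytest
from Bio.Seq import Seq

from wgacompare.errors import CapacityError, ParameterError
from wgacompare.io import revcomp
from wgacompare.simulate import (MutationConfig, TruthSet, evolve_pair,
                                 generate_ancestor, simulate_reads)


def _chrom(genomes, name):
    return next(g for g in genomes if g.id == name)


class TestGenerateAncestor:
    def test_deterministic_for_fixed_seed(self):
        a1 = generate_ancestor(1, 50_000, 5, gc=0.39, seed=7)
        a2 = generate_ancestor(1, 50_000, 5, gc=0.39, seed=7)
        assert [g.seq for g in a1[0]] == [g.seq for g in a2[0]]
        assert [g.gene_id for g in a1[1]] == [g.gene_id for g in a2[1]]

    def test_gc_content_concentrates(self):
        genomes, _ = generate_ancestor(1, 1_000_000, 0, gc=0.5, seed=1)
        seq = genomes[0].seq
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.5) < 0.01

    def test_zero_genes_gives_empty_annotation(self):
        genomes, models = generate_ancestor(1, 10_000, 0, seed=2)
        assert models == [] and genomes[0].length == 10_000

    def test_cds_are_translatable(self, small_ancestor):
        genomes, models = small_ancestor
        for g in models:
            cds = "".join(_chrom(genomes, g.chrom).seq[iv.start:iv.end]
                          for iv in g.cds)
            if g.strand == "-":
                cds = str(Seq(cds).reverse_complement())
            assert len(cds) % 3 == 0
            aa = str(Seq(cds).translate())
            assert aa.startswith("M") and aa.endswith("*")
            assert "*" not in aa[:-1]

    def test_infeasible_packing_raises(self):
        with pytest.raises(CapacityError):
            generate_ancestor(1, 30_000, 100, seed=3)


class TestEvolvePair:
    def test_all_zero_configs_reproduce_ancestor(self, small_ancestor,
                                                 empty_config):
        anc, models = small_ancestor
        ga, gfa, gb, gfb, truth = evolve_pair(
            anc, models, MutationConfig(), MutationConfig(), seed=1)
        assert [g.seq for g in ga] == [g.seq for g in anc]
        assert [g.seq for g in gb] == [g.seq for g in anc]
        assert not truth.snps and not truth.indels and not truth.svs
        assert len(truth.ortholog_pairs) == len(models)

    def test_snp_count_matches_binomial(self, small_ancestor):
        anc, models = small_ancestor
        rate = 0.005
        total = sum(g.length for g in anc)
        _, _, _, _, truth = evolve_pair(
            anc, models, MutationConfig(),
            MutationConfig(snp_rate=rate), seed=2)
        mean = total * rate
        assert abs(len(truth.snps) - mean) < 4 * np.sqrt(mean)

    def test_snp_truth_bases_match_genomes(self, small_ancestor):
        anc, models = small_ancestor
        ga, _, gb, _, truth = evolve_pair(
            anc, models, MutationConfig(),
            MutationConfig(snp_rate=0.002), seed=3)
        for r in truth.snps[:100]:
            assert r["aligned"]
            assert _chrom(ga, r["chrom_a"]).seq[r["pos_a"]] == r["base_a"]
            assert _chrom(gb, r["chrom_b"]).seq[r["pos_b"]] == r["base_b"]
            assert r["base_a"] != r["base_b_on_a"]

    def test_single_inversion_is_reverse_complement(self, small_ancestor):
        anc, models = small_ancestor
        ga, _, gb, _, truth = evolve_pair(
            anc, models, MutationConfig(),
            MutationConfig(n_inversions=1, inversion_size_range=(5000, 5000)),
            seed=4)
        (sv,) = truth.svs
        a = _chrom(ga, sv["chrom_a"]).seq
        b = _chrom(gb, sv["chrom_b"]).seq
        assert sv["end_a"] - sv["start_a"] == 5000
        assert b[sv["start_b"]:sv["end_b"]] == \
            revcomp(a[sv["start_a"]:sv["end_a"]])
        assert b[:sv["start_b"]] == a[:sv["start_a"]]

    def test_moved_segments_match_verbatim(self, small_ancestor):
        anc, models = small_ancestor
        ga, _, gb, _, truth = evolve_pair(
            anc, models, MutationConfig(),
            MutationConfig(n_translocations=2, n_relocations=2,
                           translocation_size_range=(8000, 12000),
                           relocation_size_range=(8000, 12000)), seed=5)
        kinds = sorted(s["sv_type"] for s in truth.svs)
        assert kinds == ["relocation", "relocation",
                         "translocation", "translocation"]
        for sv in truth.svs:
            a = _chrom(ga, sv["chrom_a"]).seq
            b = _chrom(gb, sv["chrom_b"]).seq
            assert b[sv["start_b"]:sv["end_b"]] == \
                a[sv["start_a"]:sv["end_a"]]
            if sv["sv_type"] == "translocation":
                assert sv["chrom_a"] != sv["chrom_b"]
            else:
                assert sv["chrom_a"] == sv["chrom_b"]

    def test_length_conservation_single_sided(self, small_ancestor):
        anc, models = small_ancestor
        ga, _, gb, _, truth = evolve_pair(
            anc, models, MutationConfig(),
            MutationConfig(indel_rate=0.0005, te_insertions=3), seed=6)
        delta = sum(g.length for g in gb) - sum(g.length for g in ga)
        ins = sum(r["length"] for r in truth.indels
                  if r["kind"] == "insertion")
        dele = sum(r["length"] for r in truth.indels
                   if r["kind"] == "deletion")
        te = sum(t["length"] for t in truth.te_insertions)
        assert delta == ins - dele + te

    def test_ltr_pair_divergence_tracks_parameter(self, small_ancestor):
        anc, models = small_ancestor
        div = 0.02
        _, _, gb, _, truth = evolve_pair(
            anc, models, MutationConfig(),
            MutationConfig(te_insertions=6, ltr_fraction=1.0,
                           ltr_divergence=div), seed=8)
        diffs = []
        for te in truth.te_insertions:
            b = _chrom(gb, te["chrom"]).seq
            l5 = b[te["ltr5"][0]:te["ltr5"][1]]
            l3 = b[te["ltr3"][0]:te["ltr3"][1]]
            diffs.append(sum(x != y for x, y in zip(l5, l3)) / len(l5))
        # each repeat mutated independently at `div`: expected difference
        # ~ 2 x div x (1 - small back-mutation term)
        assert 0.5 * 2 * div < np.mean(diffs) < 1.5 * 2 * div

    def test_lifted_genes_stay_valid_and_orthologs_cover(self,
                                                         small_ancestor):
        anc, models = small_ancestor
        ga, gfa, gb, gfb, truth = evolve_pair(
            anc, models, MutationConfig(),
            MutationConfig(snp_rate=0.001, indel_rate=0.0002), seed=9)
        for g in gfb:
            g.validate()
        assert set(truth.ortholog_pairs) <= {g.gene_id for g in gfa}
        assert len(truth.ortholog_pairs) >= 0.9 * len(models)

    def test_invalid_rate_rejected(self, small_ancestor):
        anc, models = small_ancestor
        with pytest.raises(ParameterError):
            evolve_pair(anc, models, MutationConfig(),
                        MutationConfig(snp_rate=1.5), seed=1)

    def test_truth_json_round_trip(self, small_ancestor, tmp_path):
        anc, models = small_ancestor
        _, _, _, _, truth = evolve_pair(
            anc, models, MutationConfig(),
            MutationConfig(snp_rate=0.001, n_inversions=1), seed=10)
        p = tmp_path / "truth.json"
        truth.to_json(p)
        back = TruthSet.from_json(p)
        assert back.snps == truth.snps and back.svs == truth.svs


class TestSimulateReads:
    def test_read_count_arithmetic(self):
        genomes, _ = generate_ancestor(1, 100_000, 0, seed=1)
        reads = simulate_reads(genomes, 50, 150, 0.0, seed=2)
        assert abs(len(reads) - 100_000 * 50 / 150) <= 1

    def test_error_free_reads_are_genome_substrings(self):
        genomes, _ = generate_ancestor(1, 50_000, 0, seed=3)
        reads = simulate_reads(genomes, 2, 100, 0.0, seed=4)
        genome = genomes[0].seq
        rc = revcomp(genome)
        for _, seq in reads[:50]:
            assert seq in genome or seq in rc

    def test_deterministic_fastq(self, tmp_path):
        genomes, _ = generate_ancestor(1, 20_000, 0, seed=5)
        p1, p2 = tmp_path / "a.fq", tmp_path / "b.fq"
        simulate_reads(genomes, 1, 100, 0.01, seed=6, path=p1)
        simulate_reads(genomes, 1, 100, 0.01, seed=6, path=p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_read_longer_than_chromosome_rejected(self):
        genomes, _ = generate_ancestor(1, 1000, 0, seed=7)
        with pytest.raises(ParameterError):
            simulate_reads(genomes, 1, 2000, 0.0, seed=8)
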