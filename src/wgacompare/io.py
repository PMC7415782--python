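"""Standard-format readers/writers and the shared coordinate conventions.

Everything internal is 0-based half-open.  GFF3 and VCF are converted at the
boundary (1-based inclusive); BED stays 0-based half-open.  Sequences are
uppercase strings over ``{A, C, G, T, N}``; ``U`` is normalized to ``T`` on
input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ConsistencyError, FormatError

VALID_BASES = frozenset("ACGTN")
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase nucleotide string."""
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class GenomeSequence:
    """One assembled sequence (chromosome, scaffold or contig)."""

    id: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)

    def __post_init__(self) -> None:
        bad = set(self.seq) - VALID_BASES
        if bad:
            pos = next(i for i, c in enumerate(self.seq) if c in bad)
            raise FormatError(
                f"sequence {self.id!r}: invalid character {self.seq[pos]!r} "
                f"at position {pos}"
            )


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ConsistencyError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in "+-.":
            raise ConsistencyError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GeneModel:
    """A protein-coding gene: exons, CDS and (optional) UTRs.

    One transcript per gene; when a GFF3 gene carries several mRNAs the one
    with the longest total CDS is kept.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval]
    cds: list[GenomicInterval]
    five_prime_utr: GenomicInterval | None = None
    three_prime_utr: GenomicInterval | None = None

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def cds_length(self) -> int:
        return sum(iv.length for iv in self.cds)

    def validate(self) -> None:
        if self.strand not in "+-":
            raise FormatError(f"gene {self.gene_id}: strand must be + or -")
        if not self.exons:
            raise FormatError(f"gene {self.gene_id}: no exons")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise FormatError(
                    f"gene {self.gene_id}: overlapping exons "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )
        for c in self.cds:
            if not any(e.start <= c.start and c.end <= e.end for e in self.exons):
                raise FormatError(
                    f"gene {self.gene_id}: CDS [{c.start},{c.end}) outside exons"
                )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a (multi-)FASTA file into uppercase, U->T normalized records."""
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        bad = set(seq) - VALID_BASES
        if bad:
            raise FormatError(
                f"{path}: record {rec.id!r} contains invalid character(s) "
                f"{sorted(bad)}"
            )
        records.append(GenomeSequence(id=rec.id, seq=seq))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(genomes: Iterable[GenomeSequence], path: str | Path,
                width: int = 70) -> None:
    recs = [SeqRecord(Seq(g.seq), id=g.id, description="") for g in genomes]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _iv(f: gffutils.Feature) -> GenomicInterval:
    # GFF3 is 1-based inclusive -> 0-based half-open
    return GenomicInterval(f.seqid, f.start - 1, f.end, f.strand)


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse a GFF3 file into GeneModels (one transcript per gene).

    Genes are built from gene/mRNA/exon/CDS/five_prime_UTR/three_prime_UTR
    features linked by Parent attributes.  For multi-mRNA genes the mRNA with
    the longest total CDS is retained.
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    # orphan CDS check
    for f in db.features_of_type("CDS"):
        parents = list(db.parents(f))
        if not parents:
            raise FormatError(f"{path}: CDS at {f.seqid}:{f.start} has no parent")

    genes = []
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if not mrnas:
            raise FormatError(f"{path}: gene {gene.id} has no mRNA child")

        def cds_len(m):
            return sum(c.end - c.start + 1 for c in db.children(m, featuretype="CDS"))

        mrna = max(mrnas, key=lambda m: (cds_len(m), m.id))
        exons = sorted((_iv(f) for f in db.children(mrna, featuretype="exon")),
                       key=lambda iv: iv.start)
        cds = sorted((_iv(f) for f in db.children(mrna, featuretype="CDS")),
                     key=lambda iv: iv.start)
        utr5 = [_iv(f) for f in db.children(mrna, featuretype="five_prime_UTR")]
        utr3 = [_iv(f) for f in db.children(mrna, featuretype="three_prime_UTR")]
        model = GeneModel(
            gene_id=gene.id,
            chrom=gene.seqid,
            strand=gene.strand,
            exons=exons,
            cds=cds,
            five_prime_utr=utr5[0] if utr5 else None,
            three_prime_utr=utr3[0] if utr3 else None,
        )
        model.validate()
        genes.append(model)
    return genes


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write GeneModels as GFF3 (1-based inclusive coordinates)."""

    def line(chrom, ftype, start, end, strand, attrs):
        return (f"{chrom}\twgacompare\t{ftype}\t{start + 1}\t{end}\t.\t"
                f"{strand}\t.\t{attrs}")

    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            mrna_id = f"{g.gene_id}.t1"
            fh.write(line(g.chrom, "gene", g.start, g.end, g.strand,
                          f"ID={g.gene_id}") + "\n")
            fh.write(line(g.chrom, "mRNA", g.start, g.end, g.strand,
                          f"ID={mrna_id};Parent={g.gene_id}") + "\n")
            for iv in g.exons:
                fh.write(line(g.chrom, "exon", iv.start, iv.end, g.strand,
                              f"Parent={mrna_id}") + "\n")
            for iv in g.cds:
                fh.write(line(g.chrom, "CDS", iv.start, iv.end, g.strand,
                              f"ID={mrna_id}.cds;Parent={mrna_id}") + "\n")
            if g.five_prime_utr is not None:
                iv = g.five_prime_utr
                fh.write(line(g.chrom, "five_prime_UTR", iv.start, iv.end,
                              g.strand, f"Parent={mrna_id}") + "\n")
            if g.three_prime_utr is not None:
                iv = g.three_prime_utr
                fh.write(line(g.chrom, "three_prime_UTR", iv.start, iv.end,
                              g.strand, f"Parent={mrna_id}") + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_variants(snps, indels, reference: Sequence[GenomeSequence],
                   path: str | Path) -> None:
    """Write called SNPs and indels as a minimal VCF v4.2 file.

    Indels are emitted left-anchored with one preceding reference base, per
    VCF convention.  INFO carries the supporting alignment block and the
    query-genome coordinate.
    """
    ref_by_id = {g.id: g for g in reference}
    header = pysam.VariantHeader()
    header.add_meta("source", "wgacompare")
    for g in reference:
        header.contigs.add(g.id, length=g.length)
    header.info.add("BLK", 1, "String", "Supporting alignment block id")
    header.info.add("QCHROM", 1, "String", "Query chromosome")
    header.info.add("QPOS", 1, "Integer", "Query position (1-based)")
    header.info.add("TYPE", 1, "String", "Variant class (snp/ins/del)")

    rows = []
    for s in snps:
        chrom = ref_by_id.get(s.ref_chrom)
        if chrom is None or s.ref_pos >= chrom.length:
            raise ConsistencyError(
                f"SNP at {s.ref_chrom}:{s.ref_pos} beyond chromosome end")
        rows.append((s.ref_chrom, s.ref_pos, s.ref_base, s.qry_base,
                     "snp", s.block_id, s.qry_chrom, s.qry_pos))
    for d in indels:
        chrom = ref_by_id.get(d.ref_chrom)
        if chrom is None or d.ref_pos >= chrom.length:
            raise ConsistencyError(
                f"indel at {d.ref_chrom}:{d.ref_pos} beyond chromosome end")
        anchor = chrom.seq[d.ref_pos]
        if d.kind == "deletion":
            ref_allele = anchor + d.seq
            alt_allele = anchor
        else:
            ref_allele = anchor
            alt_allele = anchor + d.seq
        rows.append((d.ref_chrom, d.ref_pos, ref_allele, alt_allele,
                     "ins" if d.kind == "insertion" else "del",
                     d.block_id, d.qry_chrom, d.qry_pos))

    order = {g.id: i for i, g in enumerate(reference)}
    rows.sort(key=lambda r: (order[r[0]], r[1]))

    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for chrom, pos, ref_a, alt_a, vtype, blk, qchrom, qpos in rows:
            rec = vcf.new_record(
                contig=chrom, start=pos, alleles=(ref_a, alt_a))
            rec.info["TYPE"] = vtype
            if blk is not None:
                rec.info["BLK"] = str(blk)
            if qchrom is not None:
                rec.info["QCHROM"] = qchrom
                rec.info["QPOS"] = int(qpos) + 1
            vcf.write(rec)


# ---------------------------------------------------------------------------
# BED / TSV helpers
# ---------------------------------------------------------------------------

def write_bed(intervals: Iterable[tuple], path: str | Path) -> None:
    """Write (chrom, start, end[, name[, score[, strand]]]) tuples as BED."""
    with open(path, "w") as fh:
        for row in intervals:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for ln in fh:
            if not ln.strip() or ln.startswith(("#", "track", "browser")):
                continue
            parts = ln.rstrip("\n").split("\t")
            strand = parts[5] if len(parts) > 5 else "."
            out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2]),
                                       strand))
    return out


def read_config(path: str | Path) -> dict[str, str]:
    """Flat key=value config file; '#' starts a comment."""
    cfg = {}
    with open(path) as fh:
        for ln in fh:
            ln = ln.split("#", 1)[0].strip()
            if not ln:
                continue
            if "=" not in ln:
                raise FormatError(f"{path}: expected key=value, got {ln!r}")
            k, v = ln.split("=", 1)
            cfg[k.strip()] = v.strip()
    return cfg


def echo_config(cfg: dict, out_dir: str | Path, name: str = "run_config.json"):
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / name, "w") as fh:
        json.dump(cfg, fh, indent=2, sort_keys=True, default=str)
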