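"""Gene-anatomy region index and element classification.

Genes are decomposed into exon, intron, promoter (default 2 kb upstream of
the 5' UTR) and downstream (default 1 kb beyond the 3' UTR) regions,
strand-aware and truncated at chromosome ends.  TE or SV intervals are then
classified by overlap, either with a fixed precedence
(exon > intron > promoter > downstream > intergenic, one category per
element) or multi-counting every overlapped category.  Paired per-gene
counts across an ortholog map are compared with an exact two-sided sign
test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from intervaltree import IntervalTree
from scipy.stats import binomtest

from .errors import ParameterError
from .io import GeneModel, GenomicInterval

CATEGORIES = ("exon", "intron", "promoter", "downstream")
PRECEDENCE = {c: i for i, c in enumerate(CATEGORIES)}


@dataclass
class FeatureIndex:
    """Per-chromosome interval map position -> (gene_id, category)."""

    trees: dict[str, IntervalTree]
    promoter_len: int
    downstream_len: int
    genes: list[str]
    genes_missing_utr: list[str] = field(default_factory=list)

    def regions_of_gene(self, gene_id: str) -> list[tuple[str, int, int, str]]:
        out = []
        for chrom, tree in self.trees.items():
            for iv in tree:
                if iv.data[0] == gene_id:
                    out.append((chrom, iv.begin, iv.end, iv.data[1]))
        return sorted(out)


def build_index(gene_models: list[GeneModel], promoter_len: int = 2000,
                downstream_len: int = 1000,
                chrom_lengths: dict[str, int] | None = None) -> FeatureIndex:
    """Strand-aware gene-anatomy index.

    For a + strand gene whose 5' UTR starts at ``p`` the promoter is
    ``[p - promoter_len, p)``; for a - strand gene it mirrors off the high
    end.  Genes lacking a UTR fall back to the CDS boundary (recorded in
    ``genes_missing_utr``).  Overlapping genes are indexed independently.
    """
    trees: dict[str, IntervalTree] = {}
    missing: list[str] = []

    def add(chrom, start, end, gene_id, category):
        if chrom_lengths is not None:
            end = min(end, chrom_lengths.get(chrom, end))
        start = max(start, 0)
        if start < end:
            trees.setdefault(chrom, IntervalTree()).addi(
                start, end, (gene_id, category))

    for g in gene_models:
        g.validate()
        for iv in g.exons:
            add(g.chrom, iv.start, iv.end, g.gene_id, "exon")
        for a, b in zip(g.exons, g.exons[1:]):
            add(g.chrom, a.end, b.start, g.gene_id, "intron")

        has_utr5 = g.five_prime_utr is not None
        has_utr3 = g.three_prime_utr is not None
        if not (has_utr5 and has_utr3):
            missing.append(g.gene_id)
        if g.strand == "+":
            p5 = (g.five_prime_utr.start if has_utr5 else g.cds[0].start)
            p3 = (g.three_prime_utr.end if has_utr3 else g.cds[-1].end)
            add(g.chrom, p5 - promoter_len, p5, g.gene_id, "promoter")
            add(g.chrom, p3, p3 + downstream_len, g.gene_id, "downstream")
        else:
            p5 = (g.five_prime_utr.end if has_utr5 else g.cds[-1].end)
            p3 = (g.three_prime_utr.start if has_utr3 else g.cds[0].start)
            add(g.chrom, p5, p5 + promoter_len, g.gene_id, "promoter")
            add(g.chrom, p3 - downstream_len, p3, g.gene_id, "downstream")

    return FeatureIndex(trees=trees, promoter_len=promoter_len,
                        downstream_len=downstream_len,
                        genes=[g.gene_id for g in gene_models],
                        genes_missing_utr=missing)


@dataclass
class RegionCounts:
    """Element counts per category, aggregate and per gene."""

    mode: str
    total_elements: int
    aggregate: dict[str, int]
    intergenic: int
    per_gene: dict[str, dict[str, int]]
    genes_hit: dict[str, int]          # per category: number of genes with >=1 hit

    def conserved_total(self) -> int:
        return sum(self.aggregate.values()) + self.intergenic


def classify_elements(elements: list[GenomicInterval], index: FeatureIndex,
                      mode: str = "precedence") -> RegionCounts:
    """Classify intervals into gene-anatomy categories by >= 1 bp overlap.

    ``precedence`` assigns each element exactly one category
    (exon > intron > promoter > downstream, intergenic when nothing
    overlaps); ``multi`` tallies every overlapped category once per element.
    """
    if mode not in ("precedence", "multi"):
        raise ParameterError(f"unknown mode {mode!r}")
    aggregate = {c: 0 for c in CATEGORIES}
    per_gene: dict[str, dict[str, int]] = {}
    intergenic = 0
    for el in elements:
        tree = index.trees.get(el.chrom)
        hits = tree.overlap(el.start, el.end) if tree is not None else set()
        if not hits:
            intergenic += 1
            continue
        if mode == "precedence":
            best = min(hits, key=lambda iv: (PRECEDENCE[iv.data[1]],
                                             iv.begin, iv.data[0]))
            gene, cat = best.data
            aggregate[cat] += 1
            per_gene.setdefault(gene, {c: 0 for c in CATEGORIES})[cat] += 1
        else:
            seen = set()
            for iv in hits:
                gene, cat = iv.data
                if (gene, cat) in seen:
                    continue
                seen.add((gene, cat))
                aggregate[cat] += 1
                per_gene.setdefault(gene,
                                    {c: 0 for c in CATEGORIES})[cat] += 1
    genes_hit = {c: sum(1 for g in per_gene.values() if g[c] > 0)
                 for c in CATEGORIES}
    return RegionCounts(mode=mode, total_elements=len(elements),
                        aggregate=aggregate, intergenic=intergenic,
                        per_gene=per_gene, genes_hit=genes_hit)


@dataclass
class PairedComparison:
    category: str
    sum_a: int
    sum_b: int
    n_a_greater: int
    n_b_greater: int
    n_ties: int
    p_value: float


def compare_paired_counts(counts_a: RegionCounts, counts_b: RegionCounts,
                          ortholog_pairs: dict[str, str]
                          ) -> list[PairedComparison]:
    """Per-category paired comparison across ortholog pairs with an exact
    two-sided sign test on the non-tied pairs."""
    if not ortholog_pairs:
        raise ParameterError("empty ortholog pairing")
    out = []
    zero = {c: 0 for c in CATEGORIES}
    for cat in CATEGORIES:
        gt = lt = tie = sa = sb = 0
        for ga, gb in ortholog_pairs.items():
            a = counts_a.per_gene.get(ga, zero)[cat]
            b = counts_b.per_gene.get(gb, zero)[cat]
            sa += a
            sb += b
            if a > b:
                gt += 1
            elif b > a:
                lt += 1
            else:
                tie += 1
        n = gt + lt
        p = binomtest(gt, n, 0.5).pvalue if n else 1.0
        out.append(PairedComparison(cat, sa, sb, gt, lt, tie, float(p)))
    return out


def write_counts_tsv(counts: RegionCounts, path) -> None:
    with open(path, "w") as fh:
        fh.write("#gene_id\t" + "\t".join(CATEGORIES) + "\n")
        for gene in sorted(counts.per_gene):
            row = counts.per_gene[gene]
            fh.write(gene + "\t" + "\t".join(str(row[c]) for c in CATEGORIES)
                     + "\n")
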