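"""Molecular-evolution statistics on gene pairs and LTR elements.

* 4DTv — fraction of fourfold-degenerate third-codon sites (both codons
  sharing an identical fourfold prefix) that differ by a transversion; a
  saturation-resistant signal for whole-genome duplication analysis.  An
  optional Kimura-style correction for multiple transversion hits is stored
  alongside the raw fraction.
* Ks — synonymous substitutions per synonymous site by Nei–Gojobori (1986)
  counting with pathway averaging and Jukes–Cantor correction
  (method tag ``NG86-JC``).  Mutations to stop codons count as
  nonsynonymous, matching the common implementation convention.
* Ks-distribution peak detection via Gaussian KDE (Silverman bandwidth).
* LTR insertion age — Jukes–Cantor distance K between the element's two
  terminal repeats, age = K / (2 mu); the repeats are identical at insertion
  and diverge independently at the neutral rate ``mu`` afterwards.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data import CodonTable
from Bio.Seq import Seq
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

from .align import AlignmentBlock, _align_gap, _merge_runs
from .errors import ParameterError, PreconditionError, WgaCompareError
from .io import GeneModel, GenomeSequence

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_FORWARD = dict(_STANDARD.forward_table)
_STOPS = set(_STANDARD.stop_codons)

#: dinucleotide prefixes whose third position is fourfold degenerate
FOURFOLD_PREFIXES = frozenset(
    p for p in ("".join(t) for t in itertools.product("ACGT", repeat=2))
    if len({_FORWARD.get(p + b) for b in "ACGT"}) == 1
    and (p + "A") not in _STOPS
)

_PURINES = {"A", "G"}


def is_transversion(b1: str, b2: str) -> bool:
    return b1 != b2 and ((b1 in _PURINES) != (b2 in _PURINES))


class UnreliablePairError(WgaCompareError):
    """LTR pair too diverged to align reliably."""


# ---------------------------------------------------------------------------
# codon alignment
# ---------------------------------------------------------------------------

@dataclass
class CodonAlignment:
    """Codon-aligned CDS pair: equal-length strings, gaps in codon units."""

    id_a: str
    id_b: str
    aligned_a: str
    aligned_b: str

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ParameterError("aligned sequences must have equal length")
        if len(self.aligned_a) % 3:
            raise ParameterError("alignment length must be divisible by 3")

    def codon_pairs(self) -> list[tuple[str, str]]:
        """Gap-free, stop-free codon pairs."""
        out = []
        for i in range(0, len(self.aligned_a), 3):
            c1 = self.aligned_a[i:i + 3]
            c2 = self.aligned_b[i:i + 3]
            if "-" in c1 or "-" in c2:
                continue
            if c1 in _STOPS or c2 in _STOPS:
                continue
            out.append((c1, c2))
        return out

    @property
    def n_codon_pairs(self) -> int:
        return len(self.codon_pairs())


_PROT_ALIGNER: PairwiseAligner | None = None


def _protein_aligner() -> PairwiseAligner:
    global _PROT_ALIGNER
    if _PROT_ALIGNER is None:
        a = PairwiseAligner()
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -10
        a.extend_gap_score = -0.5
        a.mode = "global"
        _PROT_ALIGNER = a
    return _PROT_ALIGNER


def build_codon_alignment(id_a: str, cds_a: str, id_b: str, cds_b: str
                          ) -> CodonAlignment:
    """Codon alignment by aligning translated proteins (global, BLOSUM62)
    and threading the codons back through the protein alignment."""
    for name, cds in ((id_a, cds_a), (id_b, cds_b)):
        if len(cds) % 3:
            raise ParameterError(f"{name}: CDS length not divisible by 3")

    def prep(cds):
        codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
        if codons and codons[-1] in _STOPS:
            codons = codons[:-1]
        return codons, str(Seq("".join(codons)).translate())

    codons_a, prot_a = prep(cds_a.upper())
    codons_b, prot_b = prep(cds_b.upper())
    aln = _protein_aligner().align(prot_a, prot_b)[0]
    out_a, out_b = [], []
    ia = ib = 0
    for (sa, ea), (sb, eb) in zip(*aln.aligned):
        while ia < sa:
            out_a.append(codons_a[ia]); out_b.append("---"); ia += 1
        while ib < sb:
            out_a.append("---"); out_b.append(codons_b[ib]); ib += 1
        for _ in range(ea - sa):
            out_a.append(codons_a[ia]); out_b.append(codons_b[ib])
            ia += 1; ib += 1
    while ia < len(codons_a):
        out_a.append(codons_a[ia]); out_b.append("---"); ia += 1
    while ib < len(codons_b):
        out_a.append("---"); out_b.append(codons_b[ib]); ib += 1
    return CodonAlignment(id_a, id_b, "".join(out_a), "".join(out_b))


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

@dataclass
class EvoStats:
    id_a: str = ""
    id_b: str = ""
    n_4d_sites: int = 0
    n_4d_transversions: int = 0
    fourdtv_raw: float = float("nan")
    fourdtv_corrected: float = float("nan")
    ks: float = float("nan")
    ks_method: str = ""
    n_codon_pairs: int = 0
    flags: list[str] = field(default_factory=list)


def compute_4dtv(aln: CodonAlignment, correct: bool = True) -> EvoStats:
    """Fourfold-degenerate transversion fraction of a codon alignment.

    A 4D site requires both codons to share the same fourfold-degenerate
    dinucleotide prefix.  With ``correct`` a Kimura-style transversion
    correction ``-0.5 ln(1 - 2 x raw)`` is stored in ``fourdtv_corrected``.
    Zero 4D sites flags the result ``undefined`` (never reported as 0).
    """
    n4d = ntv = 0
    for c1, c2 in aln.codon_pairs():
        if c1[:2] == c2[:2] and c1[:2] in FOURFOLD_PREFIXES:
            n4d += 1
            if is_transversion(c1[2], c2[2]):
                ntv += 1
    stats = EvoStats(id_a=aln.id_a, id_b=aln.id_b, n_4d_sites=n4d,
                     n_4d_transversions=ntv,
                     n_codon_pairs=aln.n_codon_pairs)
    if n4d == 0:
        stats.flags.append("undefined")
        return stats
    stats.fourdtv_raw = ntv / n4d
    if correct:
        if stats.fourdtv_raw < 0.5:
            stats.fourdtv_corrected = -0.5 * math.log(
                1 - 2 * stats.fourdtv_raw) + 0.0
        else:
            stats.flags.append("4dtv_saturated")
    return stats


def _ng86_site_count(codon: str) -> float:
    """Synonymous site count of one codon (stop neighbours nonsynonymous,
    normalized so synonymous + nonsynonymous sites = 3)."""
    aa = _FORWARD[codon]
    s = n = 0
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt in _STOPS:
                n += 1
            elif _FORWARD[alt] == aa:
                s += 1
            else:
                n += 1
    return 3 * s / (s + n)


def _ng86_diff_count(c1: str, c2: str) -> float:
    """Pathway-averaged synonymous difference count between two codons."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0
    sd = 0.0
    paths = list(itertools.permutations(diff))
    w = 1.0 / len(paths)
    for path in paths:
        cur = c1
        for pos in path:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            a1 = _FORWARD.get(cur)
            a2 = _FORWARD.get(nxt)
            if a1 is not None and a1 == a2:
                sd += w
            cur = nxt
    return sd


def compute_ks(aln: CodonAlignment) -> EvoStats:
    """Nei–Gojobori Ks with Jukes–Cantor correction (``NG86-JC``).

    Synonymous site counts are averaged over the two sequences; synonymous
    differences are pathway-averaged for codons differing at 1–3 positions.
    ``ps >= 3/4`` saturates the correction and is reported as +inf with a
    flag; fewer than 30 codon pairs flags ``low_confidence``.
    """
    pairs = aln.codon_pairs()
    stats = EvoStats(id_a=aln.id_a, id_b=aln.id_b, ks_method="NG86-JC",
                     n_codon_pairs=len(pairs))
    if not pairs:
        stats.flags.append("undefined")
        return stats
    if len(pairs) < 30:
        stats.flags.append("low_confidence")
    s_sites = sum((_ng86_site_count(c1) + _ng86_site_count(c2)) / 2
                  for c1, c2 in pairs)
    sd = sum(_ng86_diff_count(c1, c2) for c1, c2 in pairs)
    if s_sites == 0:
        stats.flags.append("undefined")
        return stats
    ps = sd / s_sites
    if ps >= 0.75:
        stats.ks = float("inf")
        stats.flags.append("saturated")
        return stats
    stats.ks = -0.75 * math.log(1 - ps * 4 / 3) + 0.0
    return stats


def ks_peak(values, min_values: int = 50, grid: int = 1024,
            prominence_frac: float = 0.05, upper: float = 3.0):
    """Mode locations of a Ks distribution, sorted by height.

    Gaussian KDE with Silverman bandwidth on values in [0, ``upper``];
    modes must have prominence >= ``prominence_frac`` of the global maximum
    and rise above twice the flat-background density over the data range
    (otherwise the boundary bump of a near-uniform distribution would count
    as a mode).  Returns mode positions sorted by height, or the string
    ``"insufficient"`` when fewer than ``min_values`` finite values are
    supplied.
    """
    vals = np.asarray([v for v in values if np.isfinite(v)
                       and 0 <= v <= upper], dtype=float)
    if len(vals) < min_values:
        return "insufficient"
    kde = gaussian_kde(vals, bw_method="silverman")
    xs = np.linspace(0, upper, grid)
    ys = kde(xs)
    span = float(vals.max() - vals.min())
    background = 1.0 / span if span > 0 else 0.0
    peaks, _props = find_peaks(ys, prominence=prominence_frac * ys.max())
    peaks = [p for p in peaks if ys[p] >= 2 * background]
    order = np.argsort(ys[peaks])[::-1] if peaks else []
    return [float(xs[p]) for p in np.asarray(peaks, dtype=int)[order]]


# ---------------------------------------------------------------------------
# LTR insertion age
# ---------------------------------------------------------------------------

@dataclass
class LTRElement:
    element_id: str
    five_ltr: str
    three_ltr: str
    K: float = float("nan")             # JC distance between the two repeats
    mu: float = float("nan")            # substitutions / site / year
    age_years: float = float("nan")
    identity: float = float("nan")


def ltr_age(element_id: str, five_ltr: str, three_ltr: str,
            mu: float = 1.3e-8, min_len: int = 100,
            min_identity: float = 60.0) -> LTRElement:
    """Insertion age of an LTR element from its terminal-repeat divergence.

    K is the Jukes–Cantor distance over aligned non-gap columns of a global
    alignment of the two repeats; age = K / (2 mu).  ``mu`` defaults to
    1.3e-8 substitutions/site/year and is recorded on the result — reported
    ages scale inversely with it.
    """
    if len(five_ltr) < min_len or len(three_ltr) < min_len:
        raise ParameterError(
            f"{element_id}: LTR sequences must be >= {min_len} bases")
    runs = _merge_runs(_align_gap(five_ltr.upper(), three_ltr.upper()))
    match = sum(n for op, n in runs if op == "=")
    mism = sum(n for op, n in runs if op == "X")
    cols = sum(n for _, n in runs)
    identity = 100.0 * match / cols if cols else 0.0
    if identity < min_identity:
        raise UnreliablePairError(
            f"{element_id}: repeat identity {identity:.1f}% below "
            f"{min_identity}%")
    p = mism / (match + mism)
    if p >= 0.75:
        raise UnreliablePairError(f"{element_id}: repeats saturated (p={p})")
    K = -0.75 * math.log(1 - p * 4 / 3) + 0.0
    return LTRElement(element_id, five_ltr, three_ltr, K=K, mu=mu,
                      age_years=K / (2 * mu), identity=identity)


# ---------------------------------------------------------------------------
# synteny-based ortholog pairing
# ---------------------------------------------------------------------------

def pair_orthologs(blocks: list[AlignmentBlock], genes_a: list[GeneModel],
                   genes_b: list[GeneModel], max_dist: int = 10000
                   ) -> tuple[list[tuple[str, str]], list[str]]:
    """Pair genes whose midpoints map into the same one-to-one block within
    ``max_dist`` of each other; best-reciprocal distance enforces 1:1.

    Returns ``(pairs, unpaired_gene_ids)``.
    """
    by_chrom: dict[str, list[AlignmentBlock]] = {}
    for b in blocks:
        by_chrom.setdefault(b.ref_chrom, []).append(b)
    for lst in by_chrom.values():
        lst.sort(key=lambda b: b.ref_start)

    def map_pos(chrom: str, pos: int):
        for b in by_chrom.get(chrom, []):
            if b.ref_start <= pos < b.ref_end:
                off = pos - b.ref_start
                if b.strand == "+":
                    return b.qry_chrom, b.qry_start + off
                return b.qry_chrom, b.qry_end - 1 - off
        return None

    mids_b: dict[str, list[tuple[int, str]]] = {}
    for g in genes_b:
        mids_b.setdefault(g.chrom, []).append(((g.start + g.end) // 2,
                                               g.gene_id))
    for lst in mids_b.values():
        lst.sort()

    best_ab: dict[str, tuple[int, str]] = {}
    for g in genes_a:
        m = map_pos(g.chrom, (g.start + g.end) // 2)
        if m is None:
            continue
        qchrom, qpos = m
        cands = mids_b.get(qchrom, [])
        if not cands:
            continue
        import bisect
        i = bisect.bisect_left(cands, (qpos, ""))
        for j in (i - 1, i):
            if 0 <= j < len(cands):
                d = abs(cands[j][0] - qpos)
                if d <= max_dist and (g.gene_id not in best_ab
                                      or d < best_ab[g.gene_id][0]):
                    best_ab[g.gene_id] = (d, cands[j][1])
    # reciprocal best: each B gene keeps only its nearest A partner
    best_ba: dict[str, tuple[int, str]] = {}
    for ga, (d, gb) in best_ab.items():
        if gb not in best_ba or d < best_ba[gb][0]:
            best_ba[gb] = (d, ga)
    pairs = sorted((ga, gb) for gb, (d, ga) in best_ba.items())
    paired_a = {ga for ga, _ in pairs}
    paired_b = {gb for _, gb in pairs}
    unpaired = sorted([g.gene_id for g in genes_a
                       if g.gene_id not in paired_a]
                      + [g.gene_id for g in genes_b
                         if g.gene_id not in paired_b and
                         g.gene_id not in paired_a])
    return pairs, unpaired


def extract_cds(genome: list[GenomeSequence], gene: GeneModel) -> str:
    """Spliced CDS of a gene in sense orientation."""
    chrom = next(g for g in genome if g.id == gene.chrom)
    s = "".join(chrom.seq[iv.start:iv.end] for iv in gene.cds)
    if gene.strand == "-":
        s = str(Seq(s).reverse_complement())
    return s
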