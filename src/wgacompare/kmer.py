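"""K-mer depth histogram and genome-profile estimation from reads.

Counts canonical k-mers (lexicographic minimum of a k-mer and its reverse
complement) exactly in memory, builds the depth histogram, and derives the
genome-size, repeat-content and heterozygosity estimates:

* genome size  GS = (total counted k-mer instances) / (main peak depth)
* repeat depth threshold = 2 x peak + 1; k-mer instances deeper than the
  threshold are attributed to repetitive sequence
* heterozygosity ~ (instance fraction in the half-depth window
  [0.4 x peak, 0.6 x peak]) / (2k), the window where k-mers covering a
  heterozygous allele accumulate

Exact hash counting is deliberate: the package targets desk-scale genomes
(tens of Mb of read data), not production sequencing runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .errors import EmptyInputError, NoPeakError, ParameterError
from .util import encode_seq


@dataclass
class KmerHistogram:
    """(depth -> number of distinct canonical k-mers) table."""

    k: int
    depths: np.ndarray          # strictly increasing, >= 1
    distinct: np.ndarray        # distinct k-mers at each depth
    n_short_reads_skipped: int = 0

    @property
    def total_kmers(self) -> int:
        """Total counted k-mer instances (sum of depth x distinct)."""
        return int((self.depths.astype(np.int64)
                    * self.distinct.astype(np.int64)).sum())

    def as_dict(self) -> dict[int, int]:
        return {int(d): int(c) for d, c in zip(self.depths, self.distinct)}

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("#depth\tdistinct_kmers\n")
            for d, c in zip(self.depths, self.distinct):
                fh.write(f"{d}\t{c}\n")

    @classmethod
    def from_rows(cls, k: int, rows: Iterable[tuple[int, int]]) -> "KmerHistogram":
        rows = sorted(rows)
        depths = np.array([r[0] for r in rows], dtype=np.int64)
        distinct = np.array([r[1] for r in rows], dtype=np.int64)
        if len(depths) and ((depths < 1).any() or (distinct <= 0).any()
                            or (np.diff(depths) <= 0).any()):
            raise ParameterError("histogram rows must have unique depths >= 1 "
                                 "and positive counts")
        return cls(k=k, depths=depths, distinct=distinct)


@dataclass
class GenomeProfile:
    """Summary estimates derived from a k-mer histogram."""

    k: int
    peak_depth: int
    genome_size_estimate: int
    heterozygosity_estimate: float
    repetitive_fraction: float
    repeat_depth_threshold: int
    total_kmers: int
    peak_depth_definition: str = "main histogram peak (error spike excluded)"

    def as_dict(self) -> dict:
        from dataclasses import asdict
        return asdict(self)


def _iter_read_seqs(reads) -> Iterable[str]:
    if isinstance(reads, (str, Path)):
        path = Path(reads)
        fmt = "fastq" if path.suffix.lower() in {".fq", ".fastq"} else "fasta"
        for rec in SeqIO.parse(str(path), fmt):
            yield str(rec.seq).upper()
    else:
        for item in reads:
            yield (item[1] if isinstance(item, tuple) else str(item)).upper()


def canonical_kmer_codes(seq: str, k: int) -> np.ndarray:
    """Encoded canonical k-mers of one read (N-containing windows dropped)."""
    codes = encode_seq(seq)
    n = len(codes)
    if n < k:
        return np.empty(0, dtype=np.int64)
    valid = codes < 4
    c64 = codes.astype(np.int64)
    fwd = np.zeros(n - k + 1, dtype=np.int64)
    rev = np.zeros(n - k + 1, dtype=np.int64)
    ok = np.ones(n - k + 1, dtype=bool)
    for s in range(k):
        window = c64[s: n - k + 1 + s]
        fwd += window << (2 * (k - 1 - s))
        rev += (3 - window) << (2 * s)
        ok &= valid[s: n - k + 1 + s]
    return np.minimum(fwd, rev)[ok]


def build_histogram(reads, k: int = 19) -> KmerHistogram:
    """Exact canonical k-mer depth histogram from FASTA/FASTQ or sequences.

    ``k`` must be odd (so no k-mer is its own reverse complement) and at
    most 31 to fit the 2-bit packing in 62 bits.  Reads shorter than ``k``
    are skipped and counted.
    """
    if k % 2 == 0 or not (3 <= k <= 31):
        raise ParameterError(f"k must be odd and in [3, 31], got {k}")
    chunks = []
    n_short = 0
    n_reads = 0
    for seq in _iter_read_seqs(reads):
        n_reads += 1
        if len(seq) < k:
            n_short += 1
            continue
        chunks.append(canonical_kmer_codes(seq, k))
    if n_reads == 0:
        raise EmptyInputError("no reads supplied")
    if not chunks or sum(len(c) for c in chunks) == 0:
        raise EmptyInputError("no countable k-mers in input")
    allk = np.concatenate(chunks)
    _uniq, counts = np.unique(allk, return_counts=True)
    depths, distinct = np.unique(counts, return_counts=True)
    hist = KmerHistogram(k=k, depths=depths.astype(np.int64),
                         distinct=distinct.astype(np.int64),
                         n_short_reads_skipped=n_short)
    return hist


def find_main_peak(hist: KmerHistogram, min_depth: int = 4) -> int:
    """Depth of the main histogram peak, ignoring the low-depth error spike.

    The error spike from sequencing errors sits at depth 1-3, so only depths
    >= ``min_depth`` are considered; ties break to the larger depth.
    """
    if len(hist.depths) == 0:
        raise NoPeakError("empty histogram")
    mask = hist.depths >= min_depth
    if not mask.any():
        raise NoPeakError(f"no histogram mass at depth >= {min_depth}")
    depths = hist.depths[mask]
    distinct = hist.distinct[mask]
    best = distinct.max()
    return int(depths[distinct == best].max())


def estimate_profile(hist: KmerHistogram, min_depth: int = 4) -> GenomeProfile:
    """Genome size, repeat fraction and heterozygosity from the histogram."""
    peak = find_main_peak(hist, min_depth=min_depth)
    total = hist.total_kmers
    gs = int(round(total / peak))
    threshold = 2 * peak + 1
    inst = hist.depths.astype(np.float64) * hist.distinct.astype(np.float64)
    rep = float(inst[hist.depths > threshold].sum() / total)
    lo, hi = 0.4 * peak, 0.6 * peak
    het_mass = float(inst[(hist.depths >= lo) & (hist.depths <= hi)].sum()
                     / total)
    het = het_mass / (2 * hist.k)
    return GenomeProfile(
        k=hist.k, peak_depth=peak, genome_size_estimate=gs,
        heterozygosity_estimate=het, repetitive_fraction=rep,
        repeat_depth_threshold=threshold, total_kmers=total)
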