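"""Synthetic genome-pair generator with exact ground truth.

The module builds an ancestral genome with gene models, then evolves one or
two descendants by implanting SNPs, small indels, inversions, translocations
(segment moved to another chromosome), relocations (segment moved >= 10 kb
away on the same chromosome) and TE insertions (optionally LTR elements whose
two terminal repeats start identical and diverge independently).  Every edit
is recorded with coordinates in both descendant genomes, so downstream
callers can be scored for recall and precision against a known answer.

Coordinate bookkeeping works on a segment map: structural events are planned
on ancestor coordinates (mutually non-overlapping), the descendant is
assembled as an ordered list of ancestor segments plus novel insertions, and
small variants are applied afterwards on the assembled sequence.
"""

from __future__ import annotations

import bisect
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import CapacityError, ParameterError
from .io import GeneModel, GenomeSequence, GenomicInterval, write_bed
from .util import decode_seq, encode_seq, left_align_indel, revcomp_arr

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"
# transitions: A<->G, C<->T
_TRANSITION = {0: 2, 1: 3, 2: 0, 3: 1}


@dataclass
class MutationConfig:
    """Per-descendant mutation parameters.

    Rates are per base of the (post-structural-variant) genome.  Structural
    event counts are totals over the whole genome.  Defaults are all-zero so
    a config only states what it uses.
    """

    snp_rate: float = 0.0
    ts_tv_ratio: float = 2.0
    indel_rate: float = 0.0
    indel_size_geometric_p: float = 0.5
    indel_max_size: int = 50
    n_inversions: int = 0
    inversion_size_range: tuple[int, int] = (2000, 20000)
    n_translocations: int = 0
    translocation_size_range: tuple[int, int] = (5000, 20000)
    n_relocations: int = 0
    relocation_size_range: tuple[int, int] = (5000, 20000)
    relocation_min_shift: int = 10000
    te_insertions: int = 0
    ltr_fraction: float = 0.5
    ltr_length: int = 300
    te_internal_length: int = 1200
    ltr_divergence: float = 0.0
    sv_avoid_genes: bool = False

    def validate(self, min_chrom_len: int) -> None:
        for name in ("snp_rate", "indel_rate", "ltr_divergence"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ParameterError(f"{name} must be in [0, 1), got {v}")
        if not (0.0 < self.indel_size_geometric_p <= 1.0):
            raise ParameterError("indel_size_geometric_p must be in (0, 1]")
        for name in ("n_inversions", "n_translocations", "n_relocations",
                     "te_insertions"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        for name in ("inversion_size_range", "translocation_size_range",
                     "relocation_size_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ParameterError(f"{name} must be positive and ordered")
            if hi >= min_chrom_len:
                raise ParameterError(
                    f"{name} upper bound {hi} not smaller than the shortest "
                    f"chromosome ({min_chrom_len})")

    @property
    def is_empty(self) -> bool:
        return (self.snp_rate == 0 and self.indel_rate == 0
                and self.n_inversions == 0 and self.n_translocations == 0
                and self.n_relocations == 0 and self.te_insertions == 0)


@dataclass
class TruthSet:
    """Implanted edits with coordinates in both descendant genomes.

    ``snps``/``indels`` carry A-genome ("ref") and B-genome ("query")
    coordinates where both exist; edits falling in sequence with no
    counterpart (inside novel insertions, across structural breakpoints, or
    inside inverted context for indels) have ``aligned=False`` and are
    excluded from recovery denominators by the evaluation helpers.
    """

    snps: list[dict] = field(default_factory=list)
    indels: list[dict] = field(default_factory=list)
    svs: list[dict] = field(default_factory=list)
    te_insertions: list[dict] = field(default_factory=list)
    ortholog_pairs: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)

    def write_beds(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        for genome in ("A", "B"):
            key = "chrom_a" if genome == "A" else "chrom_b"
            skey = "start_a" if genome == "A" else "start_b"
            ekey = "end_a" if genome == "A" else "end_b"
            rows = [(sv[key], sv[skey], sv[ekey], sv["sv_type"])
                    for sv in self.svs if sv.get(key) is not None]
            rows += [(te["chrom"], te["start"], te["end"],
                      "te:" + te["family"])
                     for te in self.te_insertions if te["genome"] == genome]
            write_bed(sorted(rows), out_dir / f"truth_{genome}.bed")


# ---------------------------------------------------------------------------
# ancestor
# ---------------------------------------------------------------------------

def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + (n_codons-2) random non-stop codons + stop."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = "".join(_BASES[i] for i in rng.integers(0, 4, 3))
        if c not in _STOPS:
            codons.append(c)
    codons.append(_BASES[int(rng.integers(0, 3)) + 1] if False else
                  ["TAA", "TAG", "TGA"][int(rng.integers(0, 3))])
    return "".join(codons)


def _build_gene(rng: np.random.Generator, gene_id: str, chrom: str,
                strand: str, start: int) -> tuple[GeneModel, str]:
    """Construct one gene and the genomic sequence it occupies.

    Returns the model (genomic, strand-aware coordinates relative to
    ``start``) and the forward-strand genomic sequence of the gene span.
    """
    n_exons = int(rng.integers(2, 6))
    n_codons = int(rng.integers(60, 200))
    cds = _random_cds(rng, n_codons)
    utr5 = decode_seq(rng.integers(0, 4, int(rng.integers(30, 150))).astype(np.uint8))
    utr3 = decode_seq(rng.integers(0, 4, int(rng.integers(30, 150))).astype(np.uint8))

    # split CDS across exons (first exon also carries 5'UTR, last the 3'UTR)
    cuts = sorted(rng.choice(np.arange(3, len(cds) - 3, 3), size=n_exons - 1,
                             replace=False))
    cds_chunks = [cds[a:b] for a, b in zip([0] + cuts, cuts + [len(cds)])]
    introns = [decode_seq(rng.integers(0, 4, int(rng.integers(60, 400)))
                          .astype(np.uint8)) for _ in range(n_exons - 1)]

    # assemble in transcript (sense) orientation and record sense coords
    parts: list[str] = []
    exon_ivs: list[tuple[int, int]] = []
    cds_ivs: list[tuple[int, int]] = []
    pos = 0

    def emit(s: str) -> tuple[int, int]:
        nonlocal pos
        parts.append(s)
        iv = (pos, pos + len(s))
        pos += len(s)
        return iv

    u5 = emit(utr5)
    first_cds = emit(cds_chunks[0])
    exon_ivs.append((u5[0], first_cds[1]))
    cds_ivs.append(first_cds)
    for i in range(1, n_exons):
        emit(introns[i - 1])
        c = emit(cds_chunks[i])
        if i < n_exons - 1:
            exon_ivs.append(c)
            cds_ivs.append(c)
        else:
            u3 = emit(utr3)
            exon_ivs.append((c[0], u3[1]))
            cds_ivs.append(c)
    sense_seq = "".join(parts)
    span = len(sense_seq)
    u5_iv, u3_iv = (u5[0], u5[1]), (pos - len(utr3), pos)

    if strand == "+":
        genomic = sense_seq
        conv = lambda iv: (start + iv[0], start + iv[1])
    else:
        from .io import revcomp
        genomic = revcomp(sense_seq)
        conv = lambda iv: (start + span - iv[1], start + span - iv[0])

    mk = lambda iv: GenomicInterval(chrom, *conv(iv), strand)
    model = GeneModel(
        gene_id=gene_id, chrom=chrom, strand=strand,
        exons=sorted((mk(iv) for iv in exon_ivs), key=lambda x: x.start),
        cds=sorted((mk(iv) for iv in cds_ivs), key=lambda x: x.start),
        five_prime_utr=mk(u5_iv),
        three_prime_utr=mk(u3_iv),
    )
    model.validate()
    return model, genomic


def generate_ancestor(n_chroms: int, chrom_length: int, gene_count: int,
                      gc: float = 0.39, seed: int = 0,
                      ) -> tuple[list[GenomeSequence], list[GeneModel]]:
    """Random ancestral genome: i.i.d. bases at the given GC content with
    non-overlapping gene models placed uniformly.

    Deterministic for a fixed seed.  Raises :class:`CapacityError` when the
    requested gene count cannot be packed.
    """
    if not (0.0 < gc < 1.0):
        raise ParameterError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    genomes = []
    genes: list[GeneModel] = []
    per_chrom = [gene_count // n_chroms + (1 if i < gene_count % n_chroms else 0)
                 for i in range(n_chroms)]
    if gene_count * 3000 > n_chroms * chrom_length / 2:
        raise CapacityError("gene_count too large for the requested genome")

    gid = 0
    for ci in range(n_chroms):
        chrom = f"chr{ci + 1}"
        arr = rng.choice(4, size=chrom_length, p=p).astype(np.uint8)
        occupied: list[tuple[int, int]] = []
        for _ in range(per_chrom[ci]):
            placed = False
            for _attempt in range(200):
                strand = "+" if rng.random() < 0.5 else "-"
                start = int(rng.integers(0, chrom_length - 4000))
                model, gseq = _build_gene(rng, f"g{gid:05d}", chrom, strand,
                                          start)
                end = start + len(gseq)
                if end > chrom_length:
                    continue
                if any(s < end and start < e for s, e in occupied):
                    continue
                arr[start:end] = encode_seq(gseq)
                occupied.append((start, end))
                genes.append(model)
                gid += 1
                placed = True
                break
            if not placed:
                raise CapacityError(
                    f"could not place gene {gid} on {chrom} after 200 tries")
        genomes.append(GenomeSequence(chrom, decode_seq(arr)))
    return genomes, genes


# ---------------------------------------------------------------------------
# descendant assembly
# ---------------------------------------------------------------------------

@dataclass
class _Segment:
    """A run of descendant sequence and where it came from."""
    anc_chrom: str | None      # None for novel sequence
    anc_start: int
    anc_end: int
    strand: int                # +1 / -1 (vs ancestor)
    novel: np.ndarray | None = None
    label: str | None = None   # sv/te identifier for novel or moved pieces

    @property
    def length(self) -> int:
        return (len(self.novel) if self.novel is not None
                else self.anc_end - self.anc_start)


class _Descendant:
    """One evolved genome plus its exact coordinate transform to the ancestor."""

    def __init__(self, label: str):
        self.label = label
        self.chrom_order: list[str] = []
        self.segments: dict[str, list[_Segment]] = {}
        self.seqs: dict[str, np.ndarray] = {}
        # per descendant chrom: sorted arrays describing segment layout
        self._starts: dict[str, np.ndarray] = {}
        # ancestor -> descendant lookup: per anc chrom, list of
        # (anc_start, anc_end, desc_chrom, desc_start, strand)
        self._anc_index: dict[str, list[tuple]] = {}
        self.sv_records: list[dict] = []
        self.te_records: list[dict] = []
        self.indel_events: list[dict] = []
        self.snp_events: list[dict] = []

    # -- layout ------------------------------------------------------------
    def finalize_layout(self) -> None:
        for chrom, segs in self.segments.items():
            starts = np.cumsum([0] + [s.length for s in segs])
            self._starts[chrom] = starts
            for seg, s0 in zip(segs, starts[:-1]):
                if seg.anc_chrom is not None:
                    self._anc_index.setdefault(seg.anc_chrom, []).append(
                        (seg.anc_start, seg.anc_end, chrom, int(s0),
                         seg.strand))
        for k in self._anc_index:
            self._anc_index[k].sort()

    def materialize(self, ancestor: dict[str, np.ndarray]) -> None:
        for chrom in self.chrom_order:
            parts = []
            for seg in self.segments[chrom]:
                if seg.novel is not None:
                    parts.append(seg.novel)
                else:
                    piece = ancestor[seg.anc_chrom][seg.anc_start:seg.anc_end]
                    parts.append(piece if seg.strand > 0 else revcomp_arr(piece))
            self.seqs[chrom] = (np.concatenate(parts) if parts
                                else np.empty(0, dtype=np.uint8))

    # -- coordinate maps (structural layer only) ---------------------------
    def anc_to_desc(self, chrom: str, pos: int) -> tuple[str, int, int] | None:
        """Map an ancestor position to (desc_chrom, pos, strand); None if the
        position has no descendant copy."""
        idx = self._anc_index.get(chrom)
        if not idx:
            return None
        i = bisect.bisect_right(idx, (pos, float("inf"))) - 1
        for j in (i, i + 1):
            if 0 <= j < len(idx):
                a0, a1, dchrom, d0, strand = idx[j]
                if a0 <= pos < a1:
                    if strand > 0:
                        return dchrom, d0 + (pos - a0), 1
                    return dchrom, d0 + (a1 - 1 - pos), -1
        return None

    def desc_to_anc(self, chrom: str, pos: int) -> tuple[str, int, int] | None:
        """Inverse structural map; None inside novel sequence."""
        starts = self._starts[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        seg = self.segments[chrom][i]
        off = pos - int(starts[i])
        if seg.novel is not None:
            return None
        if seg.strand > 0:
            return seg.anc_chrom, seg.anc_start + off, 1
        return seg.anc_chrom, seg.anc_end - 1 - off, -1


def _sample_intervals(rng, chrom_lengths: dict[str, int], count: int,
                      size_range: tuple[int, int], taken: list, genes,
                      avoid_genes: bool, max_tries: int = 2000) -> list:
    """Sample non-overlapping (chrom, start, end) intervals."""
    chroms = list(chrom_lengths)
    weights = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    gene_ivs = [(g.chrom, g.start, g.end) for g in genes] if avoid_genes else []
    out = []
    for _ in range(count):
        for attempt in range(max_tries):
            chrom = chroms[int(rng.choice(len(chroms), p=weights))]
            size = int(rng.integers(size_range[0], size_range[1] + 1))
            if size >= chrom_lengths[chrom]:
                continue
            start = int(rng.integers(0, chrom_lengths[chrom] - size))
            end = start + size
            if any(c == chrom and s < end and start < e for c, s, e in taken):
                continue
            if any(c == chrom and s < end and start < e
                   for c, s, e in gene_ivs):
                continue
            taken.append((chrom, start, end))
            out.append((chrom, start, end))
            break
        else:
            raise CapacityError("could not place structural variant "
                                f"after {max_tries} tries")
    return out


def _sample_points(rng, chrom_lengths, count, taken, max_tries=2000):
    chroms = list(chrom_lengths)
    weights = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    out = []
    for _ in range(count):
        for attempt in range(max_tries):
            chrom = chroms[int(rng.choice(len(chroms), p=weights))]
            pos = int(rng.integers(1, chrom_lengths[chrom] - 1))
            if any(c == chrom and s <= pos < e for c, s, e in taken):
                continue
            taken.append((chrom, pos, pos + 1))
            out.append((chrom, pos))
            break
        else:
            raise CapacityError("could not place insertion point")
    return out


def _make_te_library(rng, cfg: MutationConfig) -> list[dict]:
    n_fam = max(1, cfg.te_insertions // 5)
    lib = []
    for i in range(n_fam):
        is_ltr = rng.random() < cfg.ltr_fraction
        if is_ltr:
            ltr = rng.integers(0, 4, cfg.ltr_length).astype(np.uint8)
            internal = rng.integers(0, 4, cfg.te_internal_length).astype(np.uint8)
            lib.append(dict(family=f"LTRfam{i}", is_ltr=True, ltr=ltr,
                            internal=internal))
        else:
            body = rng.integers(0, 4, cfg.te_internal_length).astype(np.uint8)
            lib.append(dict(family=f"DNAfam{i}", is_ltr=False, body=body))
    return lib


def _mutate_ltr(rng, ltr: np.ndarray, divergence: float) -> np.ndarray:
    out = ltr.copy()
    hits = np.nonzero(rng.random(len(out)) < divergence)[0]
    if len(hits):
        out[hits] = (out[hits] + rng.integers(1, 4, len(hits))) % 4
    return out


def _plan_structure(rng, ancestor: dict[str, np.ndarray], genes,
                    cfg: MutationConfig, desc: _Descendant) -> None:
    """Sample SVs/TEs on ancestor coordinates and assemble the segment list."""
    chrom_lengths = {c: len(a) for c, a in ancestor.items()}
    taken: list[tuple[str, int, int]] = []
    inversions = _sample_intervals(rng, chrom_lengths, cfg.n_inversions,
                                   cfg.inversion_size_range, taken, genes,
                                   cfg.sv_avoid_genes)
    translocs = _sample_intervals(rng, chrom_lengths, cfg.n_translocations,
                                  cfg.translocation_size_range, taken, genes,
                                  cfg.sv_avoid_genes)
    relocs = _sample_intervals(rng, chrom_lengths, cfg.n_relocations,
                               cfg.relocation_size_range, taken, genes,
                               cfg.sv_avoid_genes)
    te_points = _sample_points(rng, chrom_lengths, cfg.te_insertions, taken)

    # destination points for moved segments (must also be outside taken ivs)
    moves = []                      # (src, dst_chrom, dst_pos, kind)
    for (chrom, s, e) in translocs:
        others = [c for c in chrom_lengths if c != chrom]
        if not others:
            raise ParameterError("translocations require >= 2 chromosomes")
        for attempt in range(2000):
            dchrom = others[int(rng.integers(0, len(others)))]
            dpos = int(rng.integers(1, chrom_lengths[dchrom] - 1))
            if any(c == dchrom and ts <= dpos < te for c, ts, te in taken):
                continue
            taken.append((dchrom, dpos, dpos + 1))
            moves.append(((chrom, s, e), dchrom, dpos, "translocation"))
            break
        else:
            raise CapacityError("could not place translocation target")
    for (chrom, s, e) in relocs:
        for attempt in range(2000):
            dpos = int(rng.integers(1, chrom_lengths[chrom] - 1))
            if abs(dpos - s) < cfg.relocation_min_shift or s <= dpos < e:
                continue
            if any(c == chrom and ts <= dpos < te for c, ts, te in taken):
                continue
            taken.append((chrom, dpos, dpos + 1))
            moves.append(((chrom, s, e), chrom, dpos, "relocation"))
            break
        else:
            raise CapacityError("could not place relocation target")

    te_lib = _make_te_library(rng, cfg)
    te_plan = []                    # (chrom, pos, seq, meta)
    for ti, (chrom, pos) in enumerate(te_points):
        fam = te_lib[int(rng.integers(0, len(te_lib)))]
        if fam["is_ltr"]:
            l5 = _mutate_ltr(rng, fam["ltr"], cfg.ltr_divergence)
            l3 = _mutate_ltr(rng, fam["ltr"], cfg.ltr_divergence)
            seq = np.concatenate([l5, fam["internal"], l3])
            meta = dict(family=fam["family"], is_ltr=True,
                        ltr_len=len(fam["ltr"]))
        else:
            seq = fam["body"]
            meta = dict(family=fam["family"], is_ltr=False, ltr_len=0)
        te_plan.append((chrom, pos, seq, dict(meta, te_id=f"te{ti}")))

    # per-chromosome assembly: breakpoints = sv interval edges, excisions,
    # insertion points
    excised = {}                    # (chrom,s,e) -> kind for moved-away spans
    for (src, dchrom, dpos, kind) in moves:
        excised[src] = kind

    inserts: dict[str, list[tuple[int, object]]] = {c: [] for c in chrom_lengths}
    for (src, dchrom, dpos, kind) in moves:
        inserts[dchrom].append((dpos, ("move", src, kind)))
    for (chrom, pos, seq, meta) in te_plan:
        inserts[chrom].append((pos, ("te", seq, meta)))

    inv_set = {(c, s, e) for c, s, e in inversions}

    for chrom, L in chrom_lengths.items():
        cuts = {0, L}
        for (c, s, e) in inversions + list(excised):
            if c == chrom:
                cuts.add(s); cuts.add(e)
        for (pos, _payload) in inserts[chrom]:
            cuts.add(pos)
        cuts = sorted(cuts)
        ins_at = {}
        for pos, payload in sorted(inserts[chrom]):
            ins_at.setdefault(pos, []).append(payload)

        segs: list[_Segment] = []
        for a, b in zip(cuts[:-1], cuts[1:]):
            for payload in ins_at.get(a, []):
                segs.append(_payload_segment(payload))
            if (chrom, a, b) in excised:
                continue
            strand = -1 if (chrom, a, b) in inv_set else 1
            segs.append(_Segment(chrom, a, b, strand))
        for payload in ins_at.get(L, []):
            segs.append(_payload_segment(payload))
        desc.segments[chrom] = segs
        desc.chrom_order.append(chrom)

    desc.finalize_layout()

    # record SV truth (descendant coords via the structural map)
    for (chrom, s, e) in inversions:
        # first descendant base of the inverted span maps from anc base e-1
        m0 = desc.anc_to_desc(chrom, e - 1)
        desc.sv_records.append(dict(
            sv_type="inversion", anc_chrom=chrom, anc_start=s, anc_end=e,
            chrom=m0[0], start=m0[1], end=m0[1] + (e - s), length=e - s))
    for (src, dchrom, dpos, kind) in moves:
        chrom, s, e = src
        m = desc.anc_to_desc(chrom, s)
        desc.sv_records.append(dict(
            sv_type=kind, anc_chrom=chrom, anc_start=s, anc_end=e,
            chrom=m[0], start=m[1], end=m[1] + (e - s), length=e - s))
    for (chrom, pos, seq, meta) in te_plan:
        # descendant start = mapped position of the first ancestor base after
        # the insertion point minus the element length
        m = desc.anc_to_desc(chrom, pos)
        start = m[1] - len(seq)
        desc.te_records.append(dict(
            genome=desc.label, chrom=m[0], start=start, end=m[1],
            anc_chrom=chrom, anc_pos=pos, family=meta["family"],
            is_ltr=meta["is_ltr"], te_id=meta["te_id"],
            ltr5=[start, start + meta["ltr_len"]] if meta["is_ltr"] else None,
            ltr3=[m[1] - meta["ltr_len"], m[1]] if meta["is_ltr"] else None,
            length=len(seq)))


def _payload_segment(payload) -> _Segment:
    if payload[0] == "move":
        _, (chrom, s, e), kind = payload
        return _Segment(chrom, s, e, 1, label=kind)
    _, seq, meta = payload
    return _Segment(None, 0, 0, 1, novel=seq, label=meta["te_id"])


# ---------------------------------------------------------------------------
# small-variant layer (indels then SNPs on the assembled genome)
# ---------------------------------------------------------------------------

class _IndelLayer:
    """Indel events per chromosome in pre-indel (G1) coordinates, with the
    induced bijection between G1 and final coordinates."""

    def __init__(self):
        self.events: dict[str, list[dict]] = {}
        self._p = {}
        self._delta = {}
        self._del_len = {}

    def build(self, chrom: str, events: list[dict]) -> None:
        events = sorted(events, key=lambda e: e["p"])
        self.events[chrom] = events
        p = np.array([e["p"] for e in events], dtype=np.int64)
        delta = np.array([e["size"] if e["kind"] == "insertion" else -e["size"]
                          for e in events], dtype=np.int64)
        self._p[chrom] = p
        self._delta[chrom] = np.concatenate([[0], np.cumsum(delta)])
        self._del_len[chrom] = np.array(
            [e["size"] if e["kind"] == "deletion" else 0 for e in events],
            dtype=np.int64)

    def g1_to_final(self, chrom: str, x: int) -> int | None:
        """Map a pre-indel position; None if it was deleted."""
        p = self._p.get(chrom)
        if p is None or len(p) == 0:
            return x
        i = int(np.searchsorted(p, x, side="left"))
        # events strictly before x are those with p < x, i.e. indices < i
        if i > 0:
            prev = i - 1
            dl = self._del_len[chrom][prev]
            if dl and p[prev] < x <= p[prev] + dl:
                return None                      # inside a deleted span
        # deletion at p deletes (p, p+size]; all earlier events fully apply
        # when x > p + del_len
        j = i
        while j > 0:
            prev = j - 1
            dl = self._del_len[chrom][prev]
            if x > p[prev] + dl:
                break
            if dl and p[prev] < x <= p[prev] + dl:
                return None
            j -= 1
        return x + int(self._delta[chrom][j])

    def final_to_g1(self, chrom: str, y: int) -> tuple[int, bool]:
        """Inverse map; returns (g1_pos, is_novel) where ``is_novel`` marks
        positions inside inserted sequence (g1_pos then is the preceding
        base)."""
        events = self.events.get(chrom, [])
        # walk via binary search on final positions of events
        lo, hi = 0, len(events)
        # final position of event anchor p_k is p_k + cumdelta[k]
        p = self._p.get(chrom)
        if p is None or len(p) == 0:
            return y, False
        anchors_final = p + self._delta[chrom][:-1]
        k = int(np.searchsorted(anchors_final, y, side="right")) - 1
        if k < 0:
            return y, False
        e = events[k]
        af = int(anchors_final[k])
        if e["kind"] == "insertion" and y <= af + e["size"]:
            return int(p[k]), y > af
        return y - int(self._delta[chrom][k + 1]), False


def _apply_indels(rng, seqs: dict[str, np.ndarray], cfg: MutationConfig,
                  ) -> tuple[dict[str, np.ndarray], _IndelLayer]:
    layer = _IndelLayer()
    out = {}
    for chrom, arr in seqs.items():
        L = len(arr)
        events = []
        if cfg.indel_rate > 0 and L > 2:
            cand = np.nonzero(rng.random(L) < cfg.indel_rate)[0]
            spacing = cfg.indel_max_size + 10
            kept = []
            last = -spacing
            for x in cand:
                if x - last >= spacing and 1 <= x < L - cfg.indel_max_size - 1:
                    kept.append(int(x)); last = int(x)
            for ppos in kept:
                size = min(int(rng.geometric(cfg.indel_size_geometric_p)),
                           cfg.indel_max_size)
                if rng.random() < 0.5:
                    seq = rng.integers(0, 4, size).astype(np.uint8)
                    events.append(dict(p=ppos, kind="insertion", size=size,
                                       seq=seq))
                else:
                    seq = arr[ppos + 1: ppos + 1 + size].copy()
                    events.append(dict(p=ppos, kind="deletion", size=size,
                                       seq=seq))
        layer.build(chrom, events)
        if events:
            parts = []
            cur = 0
            for e in sorted(events, key=lambda e: e["p"]):
                parts.append(arr[cur:e["p"] + 1])
                if e["kind"] == "insertion":
                    parts.append(e["seq"])
                    cur = e["p"] + 1
                else:
                    cur = e["p"] + 1 + e["size"]
            parts.append(arr[cur:])
            out[chrom] = np.concatenate(parts)
        else:
            out[chrom] = arr
    return out, layer


def _apply_snps(rng, seqs: dict[str, np.ndarray], cfg: MutationConfig,
                ) -> dict[str, list[dict]]:
    ts_prob = cfg.ts_tv_ratio / (cfg.ts_tv_ratio + 1.0)
    # the two transversion partners per base code
    tv = np.array([[1, 3], [0, 2], [1, 3], [0, 2]], dtype=np.uint8)
    trans = np.array([2, 3, 0, 1], dtype=np.uint8)
    events: dict[str, list[dict]] = {}
    for chrom, arr in seqs.items():
        ev = []
        if cfg.snp_rate > 0:
            pos = np.nonzero(rng.random(len(arr)) < cfg.snp_rate)[0]
            pos = pos[arr[pos] < 4]              # never mutate N
            if len(pos):
                ref = arr[pos]
                is_ts = rng.random(len(pos)) < ts_prob
                alt = np.where(is_ts, trans[ref],
                               tv[ref, rng.integers(0, 2, len(pos))])
                arr[pos] = alt.astype(np.uint8)
                ev = [dict(pos=int(x), ref=int(r), alt=int(a))
                      for x, r, a in zip(pos, ref, alt)]
        events[chrom] = ev
    return events


# ---------------------------------------------------------------------------
# gene lifting
# ---------------------------------------------------------------------------

def _map_final(desc: _Descendant, layer: _IndelLayer, chrom: str, pos: int,
               snap: bool = False):
    """Ancestor position -> final descendant (chrom, pos, flip) or None."""
    m = desc.anc_to_desc(chrom, pos)
    if m is None:
        return None
    dchrom, g1, flip = m
    y = layer.g1_to_final(dchrom, g1)
    if y is None:
        if not snap:
            return None
        step = 0
        while y is None and step < 200:
            step += 1
            y = layer.g1_to_final(dchrom, g1 + step)
        if y is None:
            return None
    return dchrom, int(y), flip


def _lift_gene(desc: _Descendant, layer: _IndelLayer, gene: GeneModel,
               ) -> GeneModel | None:
    s, e = gene.start, gene.end
    idx = desc._anc_index.get(gene.chrom, [])
    overl = [t for t in idx if t[0] < e and t[1] > s]
    if not overl:
        return None
    overl.sort()
    if overl[0][0] > s or overl[-1][1] < e:
        return None                              # part of the gene excised
    for (a, b) in zip(overl, overl[1:]):
        if a[1] != b[0]:
            return None
    chroms = {t[2] for t in overl}
    strands = {t[4] for t in overl}
    if len(chroms) > 1 or len(strands) > 1:
        return None                              # straddles an SV breakpoint
    flip = overl[0][4] < 0
    d0s = [t[3] for t in overl]
    if (not flip and d0s != sorted(d0s)) or (flip and d0s != sorted(d0s, reverse=True)):
        return None                              # pieces reordered

    def mp(pos, snap_dir):
        r = _map_final(desc, layer, gene.chrom, pos, snap=True)
        return r

    def map_iv(iv: GenomicInterval) -> GenomicInterval | None:
        m1 = mp(iv.start, +1)
        m2 = mp(iv.end - 1, -1)
        if m1 is None or m2 is None or m1[0] != m2[0]:
            return None
        lo, hi = sorted((m1[1], m2[1]))
        if hi - lo > iv.length + 50000:
            return None
        strand = iv.strand
        if flip and strand in "+-":
            strand = "-" if strand == "+" else "+"
        try:
            return GenomicInterval(m1[0], lo, hi + 1, strand)
        except Exception:
            return None

    exons = [map_iv(iv) for iv in gene.exons]
    cds = [map_iv(iv) for iv in gene.cds]
    if any(x is None for x in exons + cds):
        return None
    u5 = map_iv(gene.five_prime_utr) if gene.five_prime_utr else None
    u3 = map_iv(gene.three_prime_utr) if gene.three_prime_utr else None
    strand = gene.strand if not flip else ("-" if gene.strand == "+" else "+")
    model = GeneModel(
        gene_id=gene.gene_id, chrom=exons[0].chrom, strand=strand,
        exons=sorted(exons, key=lambda x: x.start),
        cds=sorted(cds, key=lambda x: x.start),
        five_prime_utr=u5, three_prime_utr=u3)
    try:
        model.validate()
    except Exception:
        return None
    return model


# ---------------------------------------------------------------------------
# evolve_pair
# ---------------------------------------------------------------------------

def _evolve_one(ancestor_arrays, genes, cfg: MutationConfig, seed, label):
    rng = np.random.default_rng([seed, 0 if label == "A" else 1])
    desc = _Descendant(label)
    _plan_structure(rng, ancestor_arrays, genes, cfg, desc)
    desc.materialize(ancestor_arrays)
    seqs2, layer = _apply_indels(rng, desc.seqs, cfg)
    snp_events = _apply_snps(rng, seqs2, cfg)
    desc.seqs = seqs2
    return desc, layer, snp_events


def evolve_pair(ancestor: Sequence[GenomeSequence], gene_models,
                config_a: MutationConfig, config_b: MutationConfig,
                seed: int = 0):
    """Evolve two descendants from an ancestor; returns
    ``(genomeA, genesA, genomeB, genesB, truth)``.

    With an all-zero ``config_a`` ("single-sided" mode) genome A equals the
    ancestor and every truth record has exact coordinates in both genomes.
    """
    min_len = min(g.length for g in ancestor)
    config_a.validate(min_len)
    config_b.validate(min_len)
    anc = {g.id: encode_seq(g.seq) for g in ancestor}

    descA, layerA, snpsA = _evolve_one(anc, gene_models, config_a, seed, "A")
    descB, layerB, snpsB = _evolve_one(anc, gene_models, config_b, seed, "B")

    truth = TruthSet()

    def final_pos(desc, layer, chrom, pos, snap=False):
        return _map_final(desc, layer, chrom, pos, snap=snap)

    def other_of(label):
        return ((descB, layerB) if label == "A" else (descA, layerA))

    def self_of(label):
        return ((descA, layerA) if label == "A" else (descB, layerB))

    # --- SNP truth -------------------------------------------------------
    seen_sites = set()
    for label, events in (("B", snpsB), ("A", snpsA)):
        desc, layer = self_of(label)
        odesc, olayer = other_of(label)
        for chrom, evs in events.items():
            for ev in evs:
                pos = ev["pos"]
                g1, novel = layer.final_to_g1(chrom, pos)
                rec = dict(genome=label)
                aligned = not novel
                anc_m = desc.desc_to_anc(chrom, g1) if aligned else None
                if anc_m is None:
                    aligned = False
                om = None
                if aligned:
                    anc_chrom, anc_pos, flip_self = anc_m
                    om = _map_final(odesc, olayer, anc_chrom, anc_pos)
                    if om is None:
                        aligned = False
                if aligned:
                    ochrom, opos, flip_other = om
                    flip = (flip_self < 0) != (flip_other < 0)
                    base_self = int(descA.seqs[chrom][pos] if label == "A"
                                    else descB.seqs[chrom][pos])
                    base_other = int(odesc.seqs[ochrom][opos])
                    if label == "B":
                        a_chrom, a_pos, a_base = ochrom, opos, base_other
                        b_chrom, b_pos, b_base = chrom, pos, base_self
                    else:
                        a_chrom, a_pos, a_base = chrom, pos, base_self
                        b_chrom, b_pos, b_base = ochrom, opos, base_other
                    b_on_a = (3 - b_base) if flip else b_base
                    if a_base == b_on_a or a_base > 3 or b_base > 3:
                        continue                  # no observable difference
                    site = (a_chrom, a_pos)
                    if site in seen_sites:
                        continue
                    seen_sites.add(site)
                    rec.update(chrom_a=a_chrom, pos_a=a_pos,
                               base_a="ACGTN"[a_base],
                               chrom_b=b_chrom, pos_b=b_pos,
                               base_b="ACGTN"[b_base],
                               base_b_on_a="ACGTN"[b_on_a],
                               flip=flip, aligned=True)
                else:
                    rec.update(chrom_a=None, pos_a=None, base_a=None,
                               chrom_b=chrom if label == "B" else None,
                               pos_b=pos if label == "B" else None,
                               base_b=None, base_b_on_a=None,
                               flip=False, aligned=False)
                truth.snps.append(rec)

    # --- indel truth ------------------------------------------------------
    genome_a_str = {c: decode_seq(a) for c, a in descA.seqs.items()}
    for label, layer in (("B", layerB), ("A", layerA)):
        desc, _ = self_of(label)
        odesc, olayer = other_of(label)
        for chrom, events in layer.events.items():
            for e in events:
                p_g1 = e["p"]
                anc_m = desc.desc_to_anc(chrom, p_g1)
                nxt = p_g1 + 1 + (e["size"] if e["kind"] == "deletion" else 0)
                anc_n = desc.desc_to_anc(chrom, nxt)
                rec = dict(genome=label)
                aligned = anc_m is not None and anc_n is not None
                if aligned:
                    flip_ok = anc_m[2] > 0 and anc_n[2] > 0
                    contiguous = (anc_m[0] == anc_n[0]
                                  and anc_n[1] - anc_m[1] == nxt - p_g1)
                    aligned = flip_ok and contiguous
                om = (_map_final(odesc, olayer, anc_m[0], anc_m[1])
                      if aligned else None)
                on = (_map_final(odesc, olayer, anc_n[0], anc_n[1])
                      if aligned else None)
                if om is None or on is None or (aligned and (
                        om[2] < 0 or om[0] != on[0])):
                    aligned = False
                if aligned:
                    # express relative to ref genome A / query genome B
                    if label == "B":
                        kind = e["kind"]
                        a_pos = om[1]
                        a_chrom = om[0]
                        b_pos = layer.g1_to_final(chrom, p_g1)
                        b_chrom = chrom
                        span_ok = (kind != "deletion"
                                   or on[1] - om[1] == nxt - p_g1)
                    else:
                        # an insertion in A reads as a deletion from B's side
                        kind = ("deletion" if e["kind"] == "insertion"
                                else "insertion")
                        a_pos_may = layerA.g1_to_final(chrom, p_g1)
                        a_pos = a_pos_may
                        a_chrom = chrom
                        b_pos = om[1]
                        b_chrom = om[0]
                        span_ok = a_pos is not None
                    if not span_ok or a_pos is None or b_pos is None:
                        aligned = False
                if aligned:
                    if kind == "deletion":
                        seq = genome_a_str[a_chrom][a_pos + 1:
                                                    a_pos + 1 + e["size"]]
                    else:
                        seq = decode_seq(e["seq"])
                    norm_pos, norm_seq = left_align_indel(
                        genome_a_str[a_chrom], a_pos, seq)
                    rec.update(chrom_a=a_chrom, ref_pos=norm_pos,
                               kind=kind, seq=norm_seq, length=e["size"],
                               chrom_b=b_chrom, pos_b=b_pos, aligned=True)
                else:
                    rec.update(chrom_a=None, ref_pos=None, kind=e["kind"],
                               seq=decode_seq(e["seq"]), length=e["size"],
                               chrom_b=None, pos_b=None, aligned=False)
                truth.indels.append(rec)

    # --- SV / TE truth ----------------------------------------------------
    for label in ("A", "B"):
        desc, layer = self_of(label)
        odesc, olayer = other_of(label)
        for sv in desc.sv_records:
            own_start = layer.g1_to_final(sv["chrom"], sv["start"])
            own_end = layer.g1_to_final(sv["chrom"], sv["end"] - 1)
            om1 = _map_final(odesc, olayer, sv["anc_chrom"], sv["anc_start"],
                             snap=True)
            om2 = _map_final(odesc, olayer, sv["anc_chrom"], sv["anc_end"] - 1,
                             snap=True)
            rec = dict(sv_type=sv["sv_type"], genome=label,
                       length=sv["length"])
            if label == "B":
                rec.update(chrom_b=sv["chrom"], start_b=own_start,
                           end_b=None if own_end is None else own_end + 1,
                           chrom_a=None if om1 is None else om1[0],
                           start_a=None if om1 is None else min(om1[1], om2[1]),
                           end_a=None if om2 is None else max(om1[1], om2[1]) + 1)
            else:
                rec.update(chrom_a=sv["chrom"], start_a=own_start,
                           end_a=None if own_end is None else own_end + 1,
                           chrom_b=None if om1 is None else om1[0],
                           start_b=None if om1 is None else min(om1[1], om2[1]),
                           end_b=None if om2 is None else max(om1[1], om2[1]) + 1)
            truth.svs.append(rec)
        for te in desc.te_records:
            s = layer.g1_to_final(te["chrom"], te["start"])
            rec = dict(te)
            rec["start"] = s
            rec["end"] = None if s is None else s + te["length"]
            if te["is_ltr"] and s is not None:
                shift = s - te["start"]
                rec["ltr5"] = [te["ltr5"][0] + shift, te["ltr5"][1] + shift]
                rec["ltr3"] = [te["ltr3"][0] + shift, te["ltr3"][1] + shift]
            truth.te_insertions.append(rec)

    # --- gene lifting -----------------------------------------------------
    genesA, genesB = [], []
    liftedA, liftedB = {}, {}
    for gene in gene_models:
        ga = _lift_gene(descA, layerA, gene)
        gb = _lift_gene(descB, layerB, gene)
        if ga is not None:
            genesA.append(ga); liftedA[gene.gene_id] = ga
        if gb is not None:
            genesB.append(gb); liftedB[gene.gene_id] = gb
    for gid in liftedA:
        if gid in liftedB:
            truth.ortholog_pairs[gid] = gid

    genomeA = [GenomeSequence(c, decode_seq(descA.seqs[c]))
               for c in descA.chrom_order]
    genomeB = [GenomeSequence(c, decode_seq(descB.seqs[c]))
               for c in descB.chrom_order]
    return genomeA, genesA, genomeB, genesB, truth


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def simulate_reads(genomes: Sequence[GenomeSequence], coverage: float,
                   read_length: int, error_rate: float, seed: int,
                   path: str | Path | None = None) -> list[tuple[str, str]]:
    """Uniform error-free-or-noisy single-end reads from both strands.

    Returns ``(read_id, sequence)`` tuples and, if ``path`` is given, also
    writes a FASTQ file (constant quality).  Total bases equal
    ``coverage x genome length`` to within one read.
    """
    if coverage <= 0:
        raise ParameterError("coverage must be > 0")
    shortest = min(g.length for g in genomes)
    if read_length > shortest:
        raise ParameterError(
            f"read_length {read_length} exceeds shortest chromosome {shortest}")
    rng = np.random.default_rng(seed)
    total = sum(g.length for g in genomes)
    n_reads = int(round(coverage * total / read_length))
    weights = np.array([g.length - read_length + 1 for g in genomes],
                       dtype=float)
    weights /= weights.sum()
    chrom_idx = rng.choice(len(genomes), size=n_reads, p=weights)
    arrays = [encode_seq(g.seq) for g in genomes]

    reads: list[tuple[str, str]] = []
    offsets = np.arange(read_length)
    for ci in range(len(genomes)):
        n_c = int((chrom_idx == ci).sum())
        if n_c == 0:
            continue
        starts = rng.integers(0, genomes[ci].length - read_length + 1,
                              size=n_c)
        mat = arrays[ci][starts[:, None] + offsets[None, :]]
        rc = rng.random(n_c) < 0.5
        if rc.any():
            sub = mat[rc]
            sub = (3 - sub) % 5                   # complement (N stays N=4->?)
            sub[sub == 255] = 4
            mat[rc] = sub[:, ::-1]
        if error_rate > 0:
            err = rng.random(mat.shape) < error_rate
            if err.any():
                shift = rng.integers(1, 4, size=int(err.sum()))
                flat = mat[err]
                ok = flat < 4
                flat[ok] = (flat[ok] + shift[ok]) % 4
                mat[err] = flat
        for ri in range(n_c):
            reads.append((f"read_{ci}_{ri}", decode_seq(mat[ri])))

    if path is not None:
        qual = "I" * read_length
        with open(path, "w") as fh:
            for rid, seq in reads:
                fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
    return reads
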