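"""Structural-variant classification from one-to-one alignment blocks.

Three SV classes are recovered from block geometry alone:

* **inversion** — a reverse-strand block (or run of reverse-strand blocks)
  whose nearest forward-strand neighbours on both sides align well; runs
  whose reference gap is at most ``merge_gap`` are merged into one record.
* **translocation** — a well-aligned block lying off the backbone chain whose
  query chromosome differs from the reference chromosome's dominant partner
  (inter-chromosomal move).
* **relocation** — an off-backbone block on the dominant partner chromosome
  (intra-chromosomal move breaking collinear order).

The backbone is the maximum-weight collinear chain of blocks
(weight = reference span x identity) per reference chromosome, computed with
the same chain algorithm used for anchors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import AlignmentBlock, best_chain, check_one_to_one
from .errors import PreconditionError


@dataclass
class SVRecord:
    sv_type: str                  # inversion | translocation | relocation
    ref_chrom: str
    ref_start: int
    ref_end: int
    qry_chrom: str
    qry_start: int
    qry_end: int
    identity: float               # length-weighted mean of support blocks
    support_block_ids: list[str]

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start


def _weighted_identity(blocks: list[AlignmentBlock]) -> float:
    w = sum(b.ref_end - b.ref_start for b in blocks)
    return sum((b.ref_end - b.ref_start) * b.identity for b in blocks) / w


def detect_inversions(blocks: list[AlignmentBlock],
                      flank_min_identity: float = 90.0,
                      merge_gap: int = 50,
                      max_length_discordance: float = 0.2
                      ) -> list[SVRecord]:
    """Inversions from reverse-strand blocks with well-aligned flanks.

    A run of reverse-strand blocks is a candidate when the nearest
    forward-strand blocks on both sides (same chromosome pair) both have
    identity >= ``flank_min_identity``.  Runs with reference gaps
    <= ``merge_gap`` merge into one record.  Records whose reference and
    query spans disagree by more than ``max_length_discordance`` are dropped
    (a deterministic stand-in for manual curation).
    """
    check_one_to_one(blocks)
    out: list[SVRecord] = []
    groups: dict[tuple[str, str], list[AlignmentBlock]] = {}
    for b in blocks:
        groups.setdefault((b.ref_chrom, b.qry_chrom), []).append(b)

    n = 0
    for (rchrom, qchrom), grp in sorted(groups.items()):
        grp = sorted(grp, key=lambda b: b.ref_start)
        i = 0
        while i < len(grp):
            if grp[i].strand != "-":
                i += 1
                continue
            j = i
            while j + 1 < len(grp) and grp[j + 1].strand == "-":
                j += 1
            run = grp[i:j + 1]
            left = grp[i - 1] if i > 0 else None
            right = grp[j + 1] if j + 1 < len(grp) else None
            flanks_ok = (left is not None and right is not None
                         and left.strand == "+" and right.strand == "+"
                         and left.identity >= flank_min_identity
                         and right.identity >= flank_min_identity)
            if flanks_ok:
                # merge sub-runs whose reference gap is <= merge_gap
                sub: list[AlignmentBlock] = [run[0]]
                for b in run[1:]:
                    if b.ref_start - sub[-1].ref_end <= merge_gap:
                        sub.append(b)
                    else:
                        out.append(_inversion_record(sub, n,
                                                     max_length_discordance))
                        n += 1
                        sub = [b]
                out.append(_inversion_record(sub, n, max_length_discordance))
                n += 1
            i = j + 1
    return [r for r in out if r is not None]


def _inversion_record(sub: list[AlignmentBlock], n: int,
                      max_disc: float) -> SVRecord | None:
    ref_start = min(b.ref_start for b in sub)
    ref_end = max(b.ref_end for b in sub)
    qry_start = min(b.qry_start for b in sub)
    qry_end = max(b.qry_end for b in sub)
    rlen, qlen = ref_end - ref_start, qry_end - qry_start
    if abs(rlen - qlen) > max_disc * max(rlen, qlen):
        return None
    return SVRecord(
        sv_type="inversion", ref_chrom=sub[0].ref_chrom, ref_start=ref_start,
        ref_end=ref_end, qry_chrom=sub[0].qry_chrom, qry_start=qry_start,
        qry_end=qry_end, identity=_weighted_identity(sub),
        support_block_ids=[b.id for b in sub])


def detect_transloc_reloc(blocks: list[AlignmentBlock], min_len: int = 100,
                          min_identity: float = 90.0,
                          exclude_block_ids: set[str] | None = None
                          ) -> list[SVRecord]:
    """Translocations and relocations as noncollinear single-copy blocks
    (length > ``min_len``, identity > ``min_identity``; strict inequalities).

    ``exclude_block_ids`` removes blocks already consumed as inversion
    support, so an inversion is never double-reported.
    """
    check_one_to_one(blocks)
    exclude = exclude_block_ids or set()
    by_ref: dict[str, list[AlignmentBlock]] = {}
    for b in blocks:
        by_ref.setdefault(b.ref_chrom, []).append(b)

    out: list[SVRecord] = []
    for rchrom, grp in sorted(by_ref.items()):
        # backbone: best collinear chain among each query chromosome,
        # dominant partner = the heaviest chain over all partners
        best_partner, best_weight, backbone_ids = None, -1.0, set()
        for qchrom in sorted({b.qry_chrom for b in grp}):
            cand = [b for b in grp if b.qry_chrom == qchrom
                    and b.strand == "+"]
            cand.sort(key=lambda b: b.ref_start)
            if not cand:
                continue
            r = np.array([b.ref_start for b in cand], dtype=np.int64)
            q = np.array([b.qry_start for b in cand], dtype=np.int64)
            L = np.array([b.ref_end - b.ref_start for b in cand],
                         dtype=np.int64)
            chain, w = best_chain(r, q, L, slack=0)
            # weight by span x identity for the partner choice
            wsum = sum(cand[i].weight for i in chain)
            if wsum > best_weight:
                best_partner = qchrom
                best_weight = wsum
                backbone_ids = {cand[i].id for i in chain}
        for b in grp:
            if b.id in backbone_ids or b.id in exclude or b.strand == "-":
                continue
            if not (b.ref_end - b.ref_start > min_len
                    and b.identity > min_identity):
                continue
            sv_type = ("relocation" if b.qry_chrom == best_partner
                       else "translocation")
            out.append(SVRecord(
                sv_type=sv_type, ref_chrom=b.ref_chrom, ref_start=b.ref_start,
                ref_end=b.ref_end, qry_chrom=b.qry_chrom,
                qry_start=b.qry_start, qry_end=b.qry_end,
                identity=b.identity, support_block_ids=[b.id]))
    out.sort(key=lambda s: (s.ref_chrom, s.ref_start))
    return out


def call_svs(blocks: list[AlignmentBlock], flank_min_identity: float = 90.0,
             merge_gap: int = 50, min_len: int = 100,
             min_identity: float = 90.0) -> list[SVRecord]:
    """Full SV calling: inversions first, then translocations/relocations on
    the remaining blocks."""
    inversions = detect_inversions(blocks, flank_min_identity, merge_gap)
    used = {bid for r in inversions for bid in r.support_block_ids}
    moved = detect_transloc_reloc(blocks, min_len, min_identity,
                                  exclude_block_ids=used)
    return inversions + moved


def sv_summary(svs: list[SVRecord]) -> dict[str, dict[str, int]]:
    """Counts per sv_type per reference chromosome."""
    out: dict[str, dict[str, int]] = {}
    for s in svs:
        out.setdefault(s.sv_type, {})
        out[s.sv_type][s.ref_chrom] = out[s.sv_type].get(s.ref_chrom, 0) + 1
    return out


def write_sv_beds(svs: list[SVRecord], out_dir, prefix: str = "sv") -> None:
    from pathlib import Path
    from .io import write_bed
    out_dir = Path(out_dir)
    for sv_type in ("inversion", "translocation", "relocation"):
        rows = [(s.ref_chrom, s.ref_start, s.ref_end,
                 f"{s.sv_type}:{i}", int(round(s.identity * 10)))
                for i, s in enumerate(s for s in svs if s.sv_type == sv_type)]
        write_bed(rows, out_dir / f"{prefix}_{sv_type}.bed")
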