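"""Recovery metrics: compare called variants/SVs against a simulated TruthSet.

Only truth records with exact coordinates in both genomes (``aligned=True``)
enter recall denominators; indels match within 1 bp of position plus exact
length, which absorbs residual left-alignment ambiguity in repetitive
context.
"""

from __future__ import annotations

from dataclasses import dataclass

from .simulate import TruthSet


@dataclass
class RecoveryStats:
    n_truth: int
    n_called: int
    n_matched: int

    @property
    def recall(self) -> float:
        return self.n_matched / self.n_truth if self.n_truth else float("nan")

    @property
    def precision(self) -> float:
        return (self.n_matched / self.n_called if self.n_called
                else float("nan"))


def snp_recovery(truth: TruthSet, snps) -> RecoveryStats:
    """Exact position + allele matching on the reference (A) genome."""
    truth_set = {(r["chrom_a"], r["pos_a"], r["base_a"], r["base_b_on_a"])
                 for r in truth.snps if r["aligned"]}
    called = {(s.ref_chrom, s.ref_pos, s.ref_base, s.qry_base) for s in snps}
    return RecoveryStats(len(truth_set), len(called),
                         len(truth_set & called))


def indel_recovery(truth: TruthSet, indels, pos_slack: int = 1
                   ) -> RecoveryStats:
    """Kind + length match with position within ``pos_slack`` bp."""
    truth_recs = [(r["chrom_a"], r["ref_pos"], r["kind"], r["length"])
                  for r in truth.indels if r["aligned"]]
    called_index: dict[tuple, list[int]] = {}
    for d in indels:
        called_index.setdefault((d.ref_chrom, d.kind, d.length), []).append(
            d.ref_pos)
    matched = 0
    used: set[tuple] = set()
    for chrom, pos, kind, length in truth_recs:
        for cand in called_index.get((chrom, kind, length), []):
            key = (chrom, kind, length, cand)
            if abs(cand - pos) <= pos_slack and key not in used:
                used.add(key)
                matched += 1
                break
    return RecoveryStats(len(truth_recs), len(indels), matched)


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0:
        return 0.0
    return min(inter / (a[1] - a[0]), inter / (b[1] - b[0]))


def sv_recovery(truth: TruthSet, svs, sv_types: tuple[str, ...],
                min_reciprocal: float = 0.5, coordinate_side: str = "a"
                ) -> RecoveryStats:
    """Reciprocal-overlap matching of called SVs of the given types against
    truth records of the same types (coordinates on genome A by default)."""
    ck, sk, ek = (f"chrom_{coordinate_side}", f"start_{coordinate_side}",
                  f"end_{coordinate_side}")
    truth_ivs = [(r[ck], r[sk], r[ek]) for r in truth.svs
                 if r["sv_type"] in sv_types and r.get(sk) is not None]
    called = [(s.ref_chrom, s.ref_start, s.ref_end) for s in svs
              if s.sv_type in sv_types]
    matched_truth = set()
    matched_called = set()
    for ti, (tc, ts, te) in enumerate(truth_ivs):
        for ci, (cc, cs, ce) in enumerate(called):
            if cc == tc and ci not in matched_called and \
                    _reciprocal_overlap((ts, te), (cs, ce)) >= min_reciprocal:
                matched_truth.add(ti)
                matched_called.add(ci)
                break
    return RecoveryStats(len(truth_ivs), len(called), len(matched_truth))
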