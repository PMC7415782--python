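"""Pairwise whole-genome alignment from MUM anchors.

The aligner finds maximal exact matches that are unique in both genomes
(MUM anchors) with a suffix array over the concatenated genome pair, chains
them into collinear runs with a maximum-weight sweep, closes the inter-anchor
gaps with bit-vector edit-distance alignment (edlib) and emits gapped
alignment blocks with explicit run-length edit paths.  Blocks can then be
filtered on identity/length and reduced to a one-to-one set in which no base
of either genome is covered twice — the substrate for variant and
structural-variant calling.

Anchor uniqueness is evaluated per strand pass: the forward pass aligns the
query as given, the reverse pass aligns its reverse complement; a match must
be unique in the reference and in the query *in that orientation*.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import edlib
import numpy as np

from .errors import ParameterError, PreconditionError
from .io import GenomeSequence
from .util import decode_seq, encode_seq, revcomp_arr

MIN_CLUSTER = 90        # minimum total anchor length for a chain to survive
CHAIN_SLACK = 50        # tolerated anchor overlap inside one chain


# ---------------------------------------------------------------------------
# suffix array (prefix doubling) and adjacent-suffix LCP
# ---------------------------------------------------------------------------

def _suffix_array(text: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
    """Suffix array of an integer sequence plus the rank array at every
    doubling level (used for O(log n) LCP queries)."""
    n = len(text)
    if n == 0:
        return np.empty(0, dtype=np.int64), []
    _, rank = np.unique(text, return_inverse=True)
    rank = rank.astype(np.int32)
    levels = [rank]
    k = 1
    sa = np.argsort(rank, kind="stable").astype(np.int64)
    while rank[sa[-1]] != n - 1:
        key2 = np.full(n, -1, dtype=np.int32)
        key2[: n - k] = rank[k:]
        sa = np.lexsort((key2, rank))
        r1 = rank[sa]
        r2 = key2[sa]
        diff = np.ones(n, dtype=bool)
        diff[1:] = (r1[1:] != r1[:-1]) | (r2[1:] != r2[:-1])
        new = np.empty(n, dtype=np.int32)
        new[sa] = (np.cumsum(diff) - 1).astype(np.int32)
        rank = new
        levels.append(rank)
        k *= 2
    return sa, levels


def _adjacent_lcp(sa: np.ndarray, levels: list[np.ndarray], n: int
                  ) -> np.ndarray:
    """lcp[i] = longest common prefix of suffixes sa[i-1] and sa[i]."""
    lcp = np.zeros(len(sa), dtype=np.int64)
    if len(sa) < 2:
        return lcp
    i = sa[:-1].copy()
    j = sa[1:].copy()
    out = np.zeros(len(sa) - 1, dtype=np.int64)
    for lev in range(len(levels) - 1, -1, -1):
        k = 1 << lev
        ok = (i + k <= n) & (j + k <= n)
        ii = np.where(ok, i, 0)
        jj = np.where(ok, j, 0)
        eq = ok & (levels[lev][ii] == levels[lev][jj])
        out[eq] += k
        i[eq] += k
        j[eq] += k
    lcp[1:] = out
    return lcp


# ---------------------------------------------------------------------------
# anchors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Anchor:
    """Maximal exact match unique in both genomes.

    ``qry_start`` is in original query coordinates; for ``strand == '-'`` the
    reference segment matches the reverse complement of
    ``qry[qry_start:qry_start+length]``.
    """

    ref_chrom: str
    ref_start: int
    qry_chrom: str
    qry_start: int
    length: int
    strand: str


def _concat(genomes: list[GenomeSequence], offset_base: int
            ) -> tuple[np.ndarray, np.ndarray, list[tuple[str, int, int]]]:
    """Encode genomes into one integer text; Ns and separators become unique
    symbols that can never participate in a match."""
    parts = []
    spans = []
    pos = 0
    uniq = offset_base
    for g in genomes:
        codes = encode_seq(g.seq).astype(np.int64)
        isn = codes >= 4
        if isn.any():
            codes[isn] = uniq + np.arange(int(isn.sum()))
            uniq += int(isn.sum())
        parts.append(codes)
        spans.append((g.id, pos, pos + len(codes)))
        pos += len(codes) + 1
        parts.append(np.array([uniq], dtype=np.int64))
        uniq += 1
    return np.concatenate(parts), np.int64(uniq), spans


def _mums_one_strand(ref: list[GenomeSequence], qry: list[GenomeSequence],
                     min_len: int) -> list[tuple[int, int, int]]:
    """(ref_text_pos, qry_text_pos, length) of all MUMs, coordinates in the
    concatenated texts of each side."""
    rtext, next_sym, rspans = _concat(ref, 10)
    qtext, _, qspans = _concat(qry, int(next_sym))
    text = np.concatenate([rtext, qtext])
    nr = len(rtext)
    sa, levels = _suffix_array(text)
    lcp = _adjacent_lcp(sa, levels, len(text))

    a = sa[:-1]
    b = sa[1:]
    l = lcp[1:]                          # lcp between a and b
    cross = (a < nr) != (b < nr)
    cand = cross & (l >= min_len)
    # uniqueness: no other suffix shares the same l-prefix
    lo = lcp[:-1]                        # lcp(a, previous)
    hi = np.zeros(len(a), dtype=np.int64)
    hi[:-1] = lcp[2:]                    # lcp(b, next)
    cand &= (lo < l) & (hi < l)
    # left-maximality
    pa = np.where(a > 0, a - 1, 0)
    pb = np.where(b > 0, b - 1, 0)
    left_ok = (a == 0) | (b == 0) | (text[pa] != text[pb])
    cand &= left_ok

    idx = np.nonzero(cand)[0]
    out = []
    for i in idx:
        x, y, ln = int(a[i]), int(b[i]), int(l[i])
        if x >= nr:
            x, y = y, x
        out.append((x, y - nr, ln))
    return out, rspans, qspans


def _locate(spans: list[tuple[str, int, int]], pos: int, length: int):
    for name, s, e in spans:
        if s <= pos < e:
            if pos + length > e:
                return None              # would span a separator (impossible)
            return name, pos - s
    return None


def find_anchors(ref: list[GenomeSequence], qry: list[GenomeSequence],
                 min_len: int = 40) -> list[Anchor]:
    """All MUM anchors of length >= ``min_len`` on both strands, sorted by
    (ref_chrom, ref_start)."""
    if not ref or not qry:
        raise ParameterError("both genomes must be non-empty")
    anchors: list[Anchor] = []

    fwd, rspans, qspans = _mums_one_strand(ref, qry, min_len)
    for (rp, qp, ln) in fwd:
        rloc = _locate(rspans, rp, ln)
        qloc = _locate(qspans, qp, ln)
        if rloc and qloc:
            anchors.append(Anchor(rloc[0], rloc[1], qloc[0], qloc[1], ln, "+"))

    qry_rc = [GenomeSequence(g.id, decode_seq(revcomp_arr(encode_seq(g.seq))))
              for g in qry]
    qlen = {g.id: g.length for g in qry}
    rev, rspans, qspans = _mums_one_strand(ref, qry_rc, min_len)
    for (rp, qp, ln) in rev:
        rloc = _locate(rspans, rp, ln)
        qloc = _locate(qspans, qp, ln)
        if rloc and qloc:
            # rc coordinate -> original coordinate of the matched segment
            qstart = qlen[qloc[0]] - (qloc[1] + ln)
            anchors.append(Anchor(rloc[0], rloc[1], qloc[0], qstart, ln, "-"))

    anchors.sort(key=lambda a: (a.ref_chrom, a.ref_start, a.qry_chrom,
                                a.qry_start, a.strand))
    return anchors


# ---------------------------------------------------------------------------
# chaining
# ---------------------------------------------------------------------------

def chain_precedes(rj, qj, lj, ri, qi, li, slack: int = CHAIN_SLACK) -> bool:
    """May anchor j directly precede anchor i in one collinear chain?

    Starts must strictly increase on both axes; ends may overlap the next
    anchor by at most ``slack`` bases (overlaps are trimmed at emission).
    """
    return (rj < ri and qj < qi
            and rj + lj <= ri + slack and qj + lj <= qi + slack)


class _MaxBIT:
    """Fenwick tree for prefix-maximum with payload."""

    def __init__(self, n: int):
        self.n = n
        self.val = [(-1, ())] * (n + 1)

    def update(self, i: int, v, payload) -> None:
        i += 1
        while i <= self.n:
            if v > self.val[i][0] or (v == self.val[i][0]
                                      and payload > self.val[i][1]):
                self.val[i] = (v, payload)
            i += i & (-i)

    def query(self, i: int):
        i += 1
        best = (-1, ())
        while i > 0:
            if self.val[i][0] > best[0] or (self.val[i][0] == best[0]
                                            and self.val[i][1] > best[1]):
                best = self.val[i]
            i -= i & (-i)
        return best


def _best_chain_small(r, q, L, slack) -> tuple[list[int], int]:
    """Exact quadratic DP: maximize total anchor length, break ties by
    minimal total diagonal drift, then by lower (ref_start, qry_start)."""
    n = len(r)
    d = [int(r[i]) - int(q[i]) for i in range(n)]
    order = sorted(range(n), key=lambda i: (r[i], q[i]))
    # dp value: (weight, -drift); parent for reconstruction
    dp = [(int(L[i]), 0) for i in range(n)]
    parent = [-1] * n
    for oi, i in enumerate(order):
        for j in order[:oi]:
            if chain_precedes(r[j], q[j], L[j], r[i], q[i], L[i], slack):
                w = dp[j][0] + int(L[i])
                drift = -dp[j][1] + abs(d[i] - d[j])
                if (w, -drift) > dp[i]:
                    dp[i] = (w, -drift)
                    parent[i] = j
    best = max(range(n), key=lambda i: (dp[i], (-r[i], -q[i])))
    chain = []
    i = best
    while i >= 0:
        chain.append(i)
        i = parent[i]
    chain.reverse()
    return chain, dp[best][0]


def best_chain(r: np.ndarray, q: np.ndarray, L: np.ndarray,
               slack: int = CHAIN_SLACK) -> tuple[list[int], int]:
    """Maximum-weight chain (weight = total anchor length) under
    :func:`chain_precedes`; returns (indices in chain order, weight).

    Small instances use an exact quadratic DP whose tie-break minimizes
    total diagonal drift; large instances use an O(n log n) sweep that is
    weight-optimal with a deterministic positional tie-break.
    """
    n = len(r)
    if n == 0:
        return [], 0
    if n <= 200:
        return _best_chain_small(r, q, L, slack)
    order = np.lexsort((q, r))
    # activation key: j is usable once current r_i >= max(r_end_j - slack, r_j+1)
    act_key = np.maximum(r + L - slack, r + 1)
    qry_key = np.maximum(q + L - slack, q + 1)
    uniq_q = np.unique(np.concatenate([qry_key, q]))
    qpos_of = {int(v): i for i, v in enumerate(uniq_q)}
    bit = _MaxBIT(len(uniq_q))
    act_order = np.argsort(act_key, kind="stable")
    dp = np.zeros(n, dtype=np.int64)
    parent = np.full(n, -1, dtype=np.int64)
    ai = 0
    for oi in order:
        while ai < n and act_key[act_order[ai]] <= r[oi]:
            j = int(act_order[ai])
            bit.update(qpos_of[int(qry_key[j])], int(dp[j]),
                       (-int(r[j]), -int(q[j]), j))
            ai += 1
        # query prefix over qry_key <= q[oi]
        qi = int(np.searchsorted(uniq_q, q[oi], side="right")) - 1
        best = bit.query(qi) if qi >= 0 else (-1, ())
        if best[0] > 0:
            j = best[1][2]
            # payload may predate activation constraints? activation ensured
            dp[oi] = best[0] + L[oi]
            parent[oi] = j
        else:
            dp[oi] = L[oi]
    top = int(np.argmax(dp))
    # deterministic tie-break: smallest (r, q) among maxima
    maxima = np.nonzero(dp == dp[top])[0]
    top = int(min(maxima, key=lambda i: (r[i], q[i])))
    chain = []
    i = top
    while i >= 0:
        chain.append(int(i))
        i = int(parent[i])
    chain.reverse()
    return chain, int(dp[top])


def brute_force_chain(r, q, L, slack: int = CHAIN_SLACK) -> int:
    """Exhaustive best-chain weight (oracle for small instances)."""
    n = len(r)
    best = 0
    order = sorted(range(n), key=lambda i: (r[i], q[i]))
    # DP over all subsets is overkill; simple O(2^n) subset check
    for mask in range(1, 1 << n):
        sel = [i for i in order if mask >> i & 1]
        sel.sort(key=lambda i: (r[i], q[i]))
        ok = all(chain_precedes(r[a], q[a], L[a], r[b], q[b], L[b], slack)
                 for a, b in zip(sel, sel[1:]))
        if ok:
            best = max(best, sum(L[i] for i in sel))
    return best


# ---------------------------------------------------------------------------
# blocks
# ---------------------------------------------------------------------------

@dataclass
class AlignmentBlock:
    """A gapped alignment segment between the two genomes.

    ``edit_path`` is a run-length list of ``(op, length)`` with ops
    ``=`` (match), ``X`` (mismatch), ``I`` (insertion in query),
    ``D`` (deletion from query), oriented along the reference forward strand
    and the query in block orientation (reverse-complemented for ``-``).
    ``qry_start/qry_end`` are always in original query coordinates.
    """

    id: str
    ref_chrom: str
    ref_start: int
    ref_end: int
    qry_chrom: str
    qry_start: int
    qry_end: int
    strand: str
    edit_path: list[tuple[str, int]]
    identity: float = 0.0
    aligned_columns: int = 0

    def recompute_identity(self) -> tuple[float, int]:
        cols = sum(n for _, n in self.edit_path)
        match = sum(n for op, n in self.edit_path if op == "=")
        return (100.0 * match / cols if cols else 0.0), cols

    def finalize(self) -> "AlignmentBlock":
        ref_consumed = sum(n for op, n in self.edit_path if op in "=XD")
        qry_consumed = sum(n for op, n in self.edit_path if op in "=XI")
        if ref_consumed != self.ref_end - self.ref_start:
            raise PreconditionError(
                f"block {self.id}: path consumes {ref_consumed} reference "
                f"bases, interval spans {self.ref_end - self.ref_start}")
        if qry_consumed != self.qry_end - self.qry_start:
            raise PreconditionError(
                f"block {self.id}: path consumes {qry_consumed} query bases, "
                f"interval spans {self.qry_end - self.qry_start}")
        self.identity, self.aligned_columns = self.recompute_identity()
        return self

    @property
    def weight(self) -> float:
        return (self.ref_end - self.ref_start) * self.identity

    def path_string(self) -> str:
        return " ".join(f"{n}{op}" for op, n in self.edit_path)


def _merge_runs(runs: list[tuple[str, int]]) -> list[tuple[str, int]]:
    out: list[tuple[str, int]] = []
    for op, n in runs:
        if n == 0:
            continue
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + n)
        else:
            out.append((op, n))
    return out


def _align_gap(ref_seg: str, qry_seg: str) -> list[tuple[str, int]]:
    """Edit path of a gap between anchors (global alignment)."""
    if not ref_seg and not qry_seg:
        return []
    if not ref_seg:
        return [("I", len(qry_seg))]
    if not qry_seg:
        return [("D", len(ref_seg))]
    res = edlib.align(qry_seg, ref_seg, task="path", mode="NW")
    runs = []
    for n, op in re.findall(r"(\d+)([=XID])", res["cigar"]):
        runs.append((op, int(n)))
    return runs


def chain_and_extend(anchors: list[Anchor], ref: list[GenomeSequence],
                     qry: list[GenomeSequence], max_gap: int = 1000,
                     band: int = 200, min_cluster: int = MIN_CLUSTER
                     ) -> list[AlignmentBlock]:
    """Chain anchors per (ref_chrom, qry_chrom, strand), close inter-anchor
    gaps, and emit alignment blocks with exact edit paths.

    Chains are extracted iteratively by weight, so secondary collinear runs
    (translocated or inverted segments) become their own blocks.  A chain is
    split, never force-aligned, where the gap on either genome exceeds
    ``max_gap`` or the gap sizes differ by more than ``band``.
    """
    ref_by = {g.id: g.seq for g in ref}
    qry_by = {g.id: g.seq for g in qry}
    qry_rc_by: dict[str, str] = {}
    qlen = {g.id: g.length for g in qry}

    groups: dict[tuple[str, str, str], list[Anchor]] = {}
    for a in anchors:
        groups.setdefault((a.ref_chrom, a.qry_chrom, a.strand), []).append(a)

    blocks: list[AlignmentBlock] = []
    bid = 0
    for (rchrom, qchrom, strand), group in sorted(groups.items()):
        # oriented query coordinates: identity for '+', rc space for '-'
        r = np.array([a.ref_start for a in group], dtype=np.int64)
        L = np.array([a.length for a in group], dtype=np.int64)
        if strand == "+":
            q = np.array([a.qry_start for a in group], dtype=np.int64)
        else:
            q = np.array([qlen[qchrom] - (a.qry_start + a.length)
                          for a in group], dtype=np.int64)
        if strand == "-" and qchrom not in qry_rc_by:
            qry_rc_by[qchrom] = decode_seq(
                revcomp_arr(encode_seq(qry_by[qchrom])))
        qseq = qry_by[qchrom] if strand == "+" else qry_rc_by[qchrom]
        rseq = ref_by[rchrom]

        alive = np.ones(len(group), dtype=bool)
        while alive.any():
            idx = np.nonzero(alive)[0]
            chain_local, weight = best_chain(r[idx], q[idx], L[idx])
            if weight < min_cluster or not chain_local:
                break
            chain = [int(idx[i]) for i in chain_local]
            alive[chain] = False
            # split chain at oversized or discordant gaps
            pieces: list[list[int]] = [[chain[0]]]
            for prev, cur in zip(chain, chain[1:]):
                gr = r[cur] - (r[prev] + L[prev])
                gq = q[cur] - (q[prev] + L[prev])
                if gr > max_gap or gq > max_gap or abs(gr - gq) > band:
                    pieces.append([cur])
                else:
                    pieces[-1].append(cur)
            for piece in pieces:
                if sum(int(L[i]) for i in piece) < min_cluster:
                    continue
                block = _emit_block(piece, r, q, L, rseq, qseq, rchrom,
                                    qchrom, strand, qlen, f"b{bid}")
                if block is not None:
                    blocks.append(block)
                    bid += 1
    blocks.sort(key=lambda b: (b.ref_chrom, b.ref_start, b.qry_chrom,
                               b.qry_start))
    return blocks


def _emit_block(piece, r, q, L, rseq, qseq, rchrom, qchrom, strand, qlen,
                block_id) -> AlignmentBlock | None:
    runs: list[tuple[str, int]] = []
    # trim overlaps so coordinates are strictly monotone
    segs = []
    prev_re, prev_qe = None, None
    for i in piece:
        rs, qs, ln = int(r[i]), int(q[i]), int(L[i])
        if prev_re is not None:
            t = max(0, prev_re - rs, prev_qe - qs)
            rs += t
            qs += t
            ln -= t
            if ln <= 0:
                continue
            if rs < prev_re or qs < prev_qe:
                continue
        segs.append((rs, qs, ln))
        prev_re, prev_qe = rs + ln, qs + ln
    if not segs:
        return None
    ref_start, qry_start0 = segs[0][0], segs[0][1]
    for k, (rs, qs, ln) in enumerate(segs):
        if k > 0:
            pr, pq, pl = segs[k - 1]
            gap_r = rseq[pr + pl: rs]
            gap_q = qseq[pq + pl: qs]
            runs.extend(_align_gap(gap_r, gap_q))
        runs.append(("=", ln))
    ref_end = segs[-1][0] + segs[-1][2]
    qry_end0 = segs[-1][1] + segs[-1][2]
    if strand == "+":
        qry_start, qry_end = qry_start0, qry_end0
    else:
        qry_start = qlen[qchrom] - qry_end0
        qry_end = qlen[qchrom] - qry_start0
    block = AlignmentBlock(
        id=block_id, ref_chrom=rchrom, ref_start=ref_start, ref_end=ref_end,
        qry_chrom=qchrom, qry_start=qry_start, qry_end=qry_end,
        strand=strand, edit_path=_merge_runs(runs))
    return block.finalize()


# ---------------------------------------------------------------------------
# filtering and one-to-one selection
# ---------------------------------------------------------------------------

def filter_blocks(blocks: list[AlignmentBlock], min_identity: float = 80.0,
                  min_len: int = 20000) -> list[AlignmentBlock]:
    """Identity/length filter (defaults match a synteny-view setting; variant
    calling typically relaxes ``min_len``)."""
    return [b for b in blocks
            if b.identity >= min_identity
            and (b.ref_end - b.ref_start) >= min_len]


def _trim_front(path: list[tuple[str, int]], amount: int, side: str
                ) -> tuple[list[tuple[str, int]], int, int]:
    """Remove columns from the path front until ``amount`` bases of ``side``
    ('ref' or 'qry') are consumed; returns (path, ref_consumed, qry_consumed).
    Gap runs adjacent to the cut are absorbed."""
    consumes = {"ref": "=XD", "qry": "=XI"}[side]
    rc = qc = 0
    need = amount
    out = list(path)
    while out and need > 0:
        op, n = out[0]
        eats = op in consumes
        take = min(n, need) if eats else n
        if op in "=X":
            rc += take
            qc += take
        elif op == "D":
            rc += take
        else:
            qc += take
        if eats:
            need -= take
        if take == n:
            out.pop(0)
        else:
            out[0] = (op, n - take)
    # absorb leading gap runs left dangling at the cut
    while out and out[0][0] in "ID":
        op, n = out.pop(0)
        if op == "D":
            rc += n
        else:
            qc += n
    return out, rc, qc


def trim_block(b: AlignmentBlock, ref_front: int = 0, ref_back: int = 0,
               qry_front: int = 0, qry_back: int = 0
               ) -> AlignmentBlock | None:
    """Trim a block by the given number of bases on each genome edge
    (``qry_front/back`` in original query coordinates).  Returns None when
    nothing is left."""
    path = list(b.edit_path)
    ref_start, ref_end = b.ref_start, b.ref_end
    qry_start, qry_end = b.qry_start, b.qry_end

    def apply(path, amount, side, at_path_front):
        nonlocal ref_start, ref_end, qry_start, qry_end
        if amount <= 0:
            return path
        if not at_path_front:
            path = [(op, n) for op, n in reversed(path)]
        path, rc, qc = _trim_front(path, amount, side)
        if not at_path_front:
            path = [(op, n) for op, n in reversed(path)]
        # path front is (ref low, qry-oriented low); qry-oriented low is
        # original qry low for '+', original qry high for '-'
        if at_path_front:
            ref_start += rc
            if b.strand == "+":
                qry_start += qc
            else:
                qry_end -= qc
        else:
            ref_end -= rc
            if b.strand == "+":
                qry_end -= qc
            else:
                qry_start += qc
        return path

    path = apply(path, ref_front, "ref", True)
    path = apply(path, ref_back, "ref", False)
    if b.strand == "+":
        path = apply(path, qry_front, "qry", True)
        path = apply(path, qry_back, "qry", False)
    else:
        path = apply(path, qry_front, "qry", False)
        path = apply(path, qry_back, "qry", True)
    if ref_end <= ref_start or qry_end <= qry_start or not path:
        return None
    nb = replace(b, ref_start=ref_start, ref_end=ref_end,
                 qry_start=qry_start, qry_end=qry_end,
                 edit_path=_merge_runs(path))
    return nb.finalize()


def _wis(items: list[tuple[int, int, float, int]]) -> set[int]:
    """Weighted interval scheduling: items are (start, end, weight, key);
    returns the keys of the optimum subset (deterministic tie-break on
    earlier start)."""
    items = sorted(items, key=lambda t: (t[1], t[0], t[3]))
    n = len(items)
    if n == 0:
        return set()
    import bisect as _b
    ends = [t[1] for t in items]
    dp = [0.0] * (n + 1)
    take = [False] * n
    pred = [0] * n
    for i in range(n):
        s, e, w, _k = items[i]
        j = _b.bisect_right(ends, s, hi=i)
        pred[i] = j
        if dp[j] + w > dp[i]:
            dp[i + 1] = dp[j] + w
            take[i] = True
        else:
            dp[i + 1] = dp[i]
    chosen = set()
    i = n
    while i > 0:
        if take[i - 1]:
            chosen.add(items[i - 1][3])
            i = pred[i - 1]
        else:
            i -= 1
    return chosen


def _one_to_one_pass(blocks: list[AlignmentBlock], side: str,
                     overlap_tol: int) -> list[AlignmentBlock]:
    get = lambda b, f: getattr(b, f"{side}_{f}")
    by_chrom: dict[str, list] = {}
    for i, b in enumerate(blocks):
        end_adj = max(get(b, "end") - overlap_tol, get(b, "start"))
        by_chrom.setdefault(get(b, "chrom"), []).append(
            (get(b, "start"), end_adj, b.weight, i))
    keep: set[int] = set()
    for chrom, items in by_chrom.items():
        keep |= _wis(items)
    chosen = [b for i, b in enumerate(blocks) if i in keep]
    # trim residual overlaps (all <= overlap_tol) from the lighter block
    out: list[AlignmentBlock] = []
    by_chrom2: dict[str, list[AlignmentBlock]] = {}
    for b in chosen:
        by_chrom2.setdefault(get(b, "chrom"), []).append(b)
    for chrom, grp in sorted(by_chrom2.items()):
        grp.sort(key=lambda b: (get(b, "start"), get(b, "end")))
        i = 1
        while i < len(grp):
            prev, cur = grp[i - 1], grp[i]
            o = get(prev, "end") - get(cur, "start")
            if o > 0:
                if cur.weight <= prev.weight:
                    t = trim_block(cur, **{f"{side}_front": o})
                    if t is None:
                        grp.pop(i)
                        continue
                    grp[i] = t
                else:
                    t = trim_block(prev, **{f"{side}_back": o})
                    if t is None:
                        grp.pop(i - 1)
                        continue
                    grp[i - 1] = t
            i += 1
        out.extend(grp)
    return out


def one_to_one(blocks: list[AlignmentBlock], overlap_tol: int = 100
               ) -> list[AlignmentBlock]:
    """One-to-one block set: no reference or query base covered twice.

    Two fixed passes of weighted interval scheduling (weight = reference
    span x identity), first on reference then on query coordinates.  Blocks
    conflict only when their overlap exceeds ``overlap_tol`` bases; smaller
    boundary overlaps (breakpoint ambiguity between adjacent chains) are
    resolved by trimming the lighter block instead of discarding it.
    """
    out = _one_to_one_pass(blocks, "ref", overlap_tol)
    out = _one_to_one_pass(out, "qry", overlap_tol)
    out.sort(key=lambda b: (b.ref_chrom, b.ref_start))
    return out


def check_one_to_one(blocks: list[AlignmentBlock]) -> None:
    """Raise :class:`PreconditionError` if any base is covered twice."""
    for side in ("ref", "qry"):
        ivs: dict[str, list[tuple[int, int, str]]] = {}
        for b in blocks:
            chrom = getattr(b, f"{side}_chrom")
            ivs.setdefault(chrom, []).append(
                (getattr(b, f"{side}_start"), getattr(b, f"{side}_end"), b.id))
        for chrom, lst in ivs.items():
            lst.sort()
            for (s1, e1, i1), (s2, e2, i2) in zip(lst, lst[1:]):
                if s2 < e1:
                    raise PreconditionError(
                        f"blocks {i1} and {i2} overlap on {side} {chrom}")


# ---------------------------------------------------------------------------
# TSV I/O (a show-coords-like dialect plus an edit-path sidecar)
# ---------------------------------------------------------------------------

_HEADER = ("#ref_chrom\tref_start\tref_end\tqry_chrom\tqry_start\tqry_end\t"
           "strand\tidentity\taligned_columns\tid\n")


def write_blocks(blocks: list[AlignmentBlock], path: str | Path,
                 paths_sidecar: str | Path | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_HEADER)
        for b in blocks:
            fh.write(f"{b.ref_chrom}\t{b.ref_start}\t{b.ref_end}\t"
                     f"{b.qry_chrom}\t{b.qry_start}\t{b.qry_end}\t{b.strand}\t"
                     f"{b.identity:.2f}\t{b.aligned_columns}\t{b.id}\n")
    if paths_sidecar is not None:
        with open(paths_sidecar, "w") as fh:
            fh.write("#id\tedit_path\n")
            for b in blocks:
                fh.write(f"{b.id}\t{b.path_string()}\n")


def read_blocks(path: str | Path, paths_sidecar: str | Path | None = None
                ) -> list[AlignmentBlock]:
    paths: dict[str, list[tuple[str, int]]] = {}
    if paths_sidecar is not None:
        with open(paths_sidecar) as fh:
            for ln in fh:
                if ln.startswith("#"):
                    continue
                bid, pstr = ln.rstrip("\n").split("\t")
                paths[bid] = [(m[1], int(m[0]))
                              for m in re.findall(r"(\d+)([=XID])", pstr)]
    out = []
    with open(path) as fh:
        for ln in fh:
            if ln.startswith("#"):
                continue
            (rc, rs, re_, qc, qs, qe, strand, ident, cols, bid
             ) = ln.rstrip("\n").split("\t")
            b = AlignmentBlock(
                id=bid, ref_chrom=rc, ref_start=int(rs), ref_end=int(re_),
                qry_chrom=qc, qry_start=int(qs), qry_end=int(qe),
                strand=strand, edit_path=paths.get(bid, []),
                identity=float(ident), aligned_columns=int(cols))
            if b.edit_path:
                b.finalize()
            out.append(b)
    return out


def align_genomes(ref: list[GenomeSequence], qry: list[GenomeSequence],
                  min_anchor: int = 40, max_gap: int = 1000, band: int = 200,
                  min_identity: float = 0.0, min_len: int = 0,
                  one_to_one_blocks: bool = True,
                  min_cluster: int = MIN_CLUSTER) -> list[AlignmentBlock]:
    """Convenience pipeline: anchors -> chains -> filter -> one-to-one."""
    anchors = find_anchors(ref, qry, min_len=min_anchor)
    blocks = chain_and_extend(anchors, ref, qry, max_gap=max_gap, band=band,
                              min_cluster=min_cluster)
    blocks = filter_blocks(blocks, min_identity, min_len)
    if one_to_one_blocks:
        blocks = one_to_one(blocks)
    return blocks
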