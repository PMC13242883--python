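"""Native pairwise chromosome alignment.

Anchors whole-chromosome comparisons on maximal exact matches (MEMs),
chains collinear anchors per strand, closes inter-anchor gaps with
global edit-distance alignment, and applies the block filters used for
assembly-to-assembly comparison (identity > 90%, length > 100 bp).
Filtered blocks are classified into syntenic (SYN) versus rearranged
(INV / TRANS / DUP) sets, the complement of block coverage on the
reference delimits non-syntenic regions, and an all-vs-all mode builds
the shared-sequence catalog used for small-outlier-chromosome (SOC)
architecture comparisons.

Identity is gap-inclusive: matches / alignment columns, where columns
count matches, mismatches and gap columns alike.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from itertools import combinations

import edlib
import numpy as np

_COMP = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")

# encodes A,C,G,T -> 0..3; anything else -> 4 (never matches a k-mer query)
_CODE = np.full(256, 4, dtype=np.uint64)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


class IntegrityError(ValueError):
    """Inconsistent coordinates or invariant violation in alignment input."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# maximal exact match discovery
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class Anchor:
    """One maximal exact match between reference and query.

    ``qry_pos`` is always given on the forward strand of the query; for a
    minus-strand anchor the matching query bases are
    ``revcomp(qry[qry_pos:qry_pos+length])``.
    """

    ref_pos: int
    qry_pos: int
    length: int
    strand: str = "+"


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _kmer_values(codes: np.ndarray, k: int) -> np.ndarray:
    """Packed 2-bit k-mer value at every start position (k <= 31)."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    v = np.zeros(n, dtype=np.uint64)
    bad = np.zeros(n, dtype=bool)
    for t in range(k):
        window = codes[t : t + n]
        v = (v << np.uint64(2)) | (window & np.uint64(3))
        bad |= window > 3
    # poison ambiguous k-mers so they can never match
    v[bad] = np.uint64(0xFFFFFFFFFFFFFFFF)
    return v


def _extend_left(rb: bytes, qb: bytes, i: int, j: int) -> int:
    """Length of the exact common run ending just before (i, j)."""
    n = 0
    chunk = 256
    while i - n > 0 and j - n > 0:
        step = min(chunk, i - n, j - n)
        a = rb[i - n - step : i - n]
        b = qb[j - n - step : j - n]
        if a == b:
            n += step
            continue
        # locate the last mismatch inside the chunk
        for t in range(1, step + 1):
            if a[step - t] != b[step - t]:
                return n + t - 1
        return n  # unreachable
    return n


def _extend_right(rb: bytes, qb: bytes, i: int, j: int) -> int:
    """Length of the exact common run starting at (i, j)."""
    n = 0
    chunk = 256
    lr, lq = len(rb), len(qb)
    while i + n < lr and j + n < lq:
        step = min(chunk, lr - i - n, lq - j - n)
        a = rb[i + n : i + n + step]
        b = qb[j + n : j + n + step]
        if a == b:
            n += step
            continue
        for t in range(step):
            if a[t] != b[t]:
                return n + t
        return n  # unreachable
    return n


def _mems_forward(ref: str, qry: str, k: int) -> list[tuple[int, int, int]]:
    """All MEMs of length >= k between two forward sequences.

    Seed index at word size k: every MEM of length >= k contains a shared
    k-mer on its diagonal, and two distinct MEMs on one diagonal cannot
    touch (their union would contradict maximality), so per-diagonal
    coverage tracking yields the exact MEM set.
    """
    if len(ref) < k or len(qry) < k:
        return []
    rb = ref.encode("ascii")
    qb = qry.encode("ascii")
    rk = _kmer_values(_encode(ref), k)
    qk = _kmer_values(_encode(qry), k)
    order = np.argsort(rk, kind="stable")
    rk_sorted = rk[order]
    lo = np.searchsorted(rk_sorted, qk, side="left")
    hi = np.searchsorted(rk_sorted, qk, side="right")
    hit_js = np.nonzero(hi > lo)[0]

    mems: list[tuple[int, int, int]] = []
    covered: dict[int, int] = {}  # diagonal -> qry end of last MEM
    for j in hit_js.tolist():
        for i in order[lo[j] : hi[j]].tolist():
            d = i - j
            if covered.get(d, -1) > j:
                continue
            left = _extend_left(rb, qb, i, j)
            right = _extend_right(rb, qb, i, j)  # includes the seed
            i0, j0 = i - left, j - left
            length = left + right
            if length >= k:
                mems.append((i0, j0, length))
            covered[d] = j0 + length
    return mems


def find_mems(
    ref_seq: str,
    qry_seq: str,
    min_mem_len: int = 20,
    both_strands: bool = True,
) -> list[Anchor]:
    """Exact set of maximal exact matches of length >= ``min_mem_len``.

    A match is maximal when it cannot be extended by one base on either
    side (sequence boundaries count as non-extendable). With
    ``both_strands`` the query's reverse complement is searched as well
    and minus-strand anchors are reported in forward query coordinates.
    Empty input sequences yield an empty list.
    """
    if min_mem_len < 1:
        raise ValueError("min_mem_len must be >= 1")
    out = [
        Anchor(i, j, ln, "+")
        for i, j, ln in _mems_forward(ref_seq, qry_seq, min_mem_len)
    ]
    if both_strands and qry_seq:
        lq = len(qry_seq)
        qrc = revcomp(qry_seq)
        out.extend(
            Anchor(i, lq - j - ln, ln, "-")
            for i, j, ln in _mems_forward(ref_seq, qrc, min_mem_len)
        )
    out.sort(key=lambda a: (a.ref_pos, a.qry_pos, a.strand))
    return out


# ---------------------------------------------------------------------------
# chaining and gap closure
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChainParams:
    """Chaining/extension controls.

    ``max_gap``: largest inter-anchor gap (bp, either sequence) closed by
    global alignment before the chain is split. ``min_span``: minimum
    reference span of an emitted chain. ``gap_open``/``gap_diff`` set the
    chaining penalty ``gap_open + gap_diff * |ref_gap - qry_gap|``.
    """

    max_gap: int = 500
    min_span: int = 200
    gap_open: float = 5.0
    gap_diff: float = 1.0
    max_overlap: int = 50


@dataclass
class AlignmentBlock:
    """One filtered local alignment between a reference and a query chromosome.

    Query intervals are always forward-strand. ``ops`` holds the full
    column-level alignment as (op, length) runs with op in {'=','X','I','D'}
    — 'I' are query-only columns, 'D' reference-only — laid out along the
    reference; for minus-strand blocks the query side of ``ops`` runs along
    the reverse complement of ``qry_interval``.
    """

    ref_chrom: str
    ref_start: int
    ref_end: int
    qry_chrom: str
    qry_start: int
    qry_end: int
    strand: str
    aligned_length: int
    identity: float
    n_mismatch: int
    n_gapcols: int
    class_label: str = "UNCLASSIFIED"
    ops: list[tuple[str, int]] = field(default_factory=list, repr=False)

    @property
    def ref_span(self) -> int:
        return self.ref_end - self.ref_start


def _cigar_ops(cigar: str) -> list[tuple[str, int]]:
    return [(op, int(n)) for n, op in _CIGAR_RE.findall(cigar)]


def _align_gap(ref_seg: str, qry_seg: str) -> list[tuple[str, int]]:
    """Column runs for a closed gap (global alignment of the two segments)."""
    if not ref_seg and not qry_seg:
        return []
    if not ref_seg:
        return [("I", len(qry_seg))]
    if not qry_seg:
        return [("D", len(ref_seg))]
    res = edlib.align(qry_seg, ref_seg, mode="NW", task="path")
    ops = _cigar_ops(res["cigar"])
    # edlib reports I as query-insertion relative to target=ref already
    return ops


def _merge_runs(ops: list[tuple[str, int]]) -> list[tuple[str, int]]:
    merged: list[tuple[str, int]] = []
    for op, n in ops:
        if n == 0:
            continue
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + n)
        else:
            merged.append((op, n))
    return merged


def _chain_anchors(anchors: list[Anchor], params: ChainParams) -> list[list[Anchor]]:
    """Score-maximal collinear chains (anchors already in one strand frame)."""
    if not anchors:
        return []
    anc = sorted(anchors, key=lambda a: (a.ref_pos, a.qry_pos))
    n = len(anc)
    dp = [float(a.length) for a in anc]
    parent = [-1] * n
    max_len = max(a.length for a in anc)
    reach = params.max_gap + params.max_overlap
    for x in range(n):
        a = anc[x]
        for y in range(x - 1, -1, -1):
            b = anc[y]
            if b.ref_pos + max_len + reach < a.ref_pos:
                break
            rg = a.ref_pos - (b.ref_pos + b.length)
            qg = a.qry_pos - (b.qry_pos + b.length)
            if rg < -params.max_overlap or qg < -params.max_overlap:
                continue
            if rg > params.max_gap or qg > params.max_gap:
                continue
            overlap = max(0, -min(rg, 0), -min(qg, 0))
            pen = params.gap_open + params.gap_diff * abs(rg - qg)
            cand = dp[y] + a.length - overlap - pen
            if cand > dp[x] or (cand == dp[x] and parent[x] >= 0
                                and b.ref_pos < anc[parent[x]].ref_pos):
                dp[x] = cand
                parent[x] = y
    used = [False] * n
    chains: list[list[Anchor]] = []
    for x in sorted(range(n), key=lambda t: -dp[t]):
        if used[x]:
            continue
        chain_idx = []
        t = x
        while t != -1 and not used[t]:
            chain_idx.append(t)
            used[t] = True
            t = parent[t]
        chains.append([anc[t] for t in reversed(chain_idx)])
    return chains


def _trim_overlaps(chain: list[Anchor]) -> list[Anchor]:
    out: list[Anchor] = []
    for a in chain:
        if out:
            prev = out[-1]
            cut = max(
                prev.ref_pos + prev.length - a.ref_pos,
                prev.qry_pos + prev.length - a.qry_pos,
                0,
            )
            if cut >= a.length:
                continue
            if cut:
                a = Anchor(a.ref_pos + cut, a.qry_pos + cut, a.length - cut, a.strand)
        out.append(a)
    return out


def chain_and_extend(
    anchors: list[Anchor],
    ref_seq: str,
    qry_seq: str,
    params: ChainParams | None = None,
    ref_chrom: str = "ref",
    qry_chrom: str = "qry",
) -> list[AlignmentBlock]:
    """Chain MEM anchors per strand and close inter-anchor gaps.

    Chaining is a dynamic program maximising anchored bases minus gap
    penalties; inter-anchor gaps of at most ``max_gap`` on both sequences
    are closed by global alignment, larger gaps split the chain. Blocks
    spanning less than ``min_span`` on the reference are discarded.
    Identity accounting is exact: every emitted column is a match,
    mismatch or gap column.
    """
    params = params or ChainParams()
    lq = len(qry_seq)
    for a in anchors:
        if a.ref_pos < 0 or a.qry_pos < 0 or a.ref_pos + a.length > len(ref_seq) \
                or a.qry_pos + a.length > lq:
            raise IntegrityError(f"anchor out of bounds: {a}")
    qrc = revcomp(qry_seq)
    blocks: list[AlignmentBlock] = []
    for strand in "+-":
        sub = [a for a in anchors if a.strand == strand]
        if not sub:
            continue
        if strand == "-":
            # work in the reverse-complement query frame, collinear ascending
            sub = [Anchor(a.ref_pos, lq - a.qry_pos - a.length, a.length, "-")
                   for a in sub]
            qseq = qrc
        else:
            qseq = qry_seq
        for chain in _chain_anchors(sub, params):
            chain = _trim_overlaps(chain)
            if not chain:
                continue
            # split chain at over-long gaps
            parts: list[list[Anchor]] = [[chain[0]]]
            for a in chain[1:]:
                prev = parts[-1][-1]
                rg = a.ref_pos - (prev.ref_pos + prev.length)
                qg = a.qry_pos - (prev.qry_pos + prev.length)
                if rg > params.max_gap or qg > params.max_gap:
                    parts.append([a])
                else:
                    parts[-1].append(a)
            for part in parts:
                blk = _emit_block(part, ref_seq, qseq, strand, lq,
                                  ref_chrom, qry_chrom)
                if blk is not None and blk.ref_span >= params.min_span:
                    blocks.append(blk)
    blocks.sort(key=lambda b: (b.ref_start, b.qry_start, b.strand))
    return blocks


def _emit_block(part, ref_seq, qseq, strand, lq, ref_chrom, qry_chrom):
    ops: list[tuple[str, int]] = []
    first, last = part[0], part[-1]
    prev = None
    for a in part:
        if prev is not None:
            rseg = ref_seq[prev.ref_pos + prev.length : a.ref_pos]
            qseg = qseq[prev.qry_pos + prev.length : a.qry_pos]
            ops.extend(_align_gap(rseg, qseg))
        ops.append(("=", a.length))
        prev = a
    ops = _merge_runs(ops)
    aligned = sum(n for _, n in ops)
    if aligned == 0:
        return None
    n_mm = sum(n for op, n in ops if op == "X")
    n_gap = sum(n for op, n in ops if op in "ID")
    q0, q1 = first.qry_pos, last.qry_pos + last.length
    if strand == "-":
        qry_start, qry_end = lq - q1, lq - q0
    else:
        qry_start, qry_end = q0, q1
    return AlignmentBlock(
        ref_chrom=ref_chrom,
        ref_start=first.ref_pos,
        ref_end=last.ref_pos + last.length,
        qry_chrom=qry_chrom,
        qry_start=qry_start,
        qry_end=qry_end,
        strand=strand,
        aligned_length=aligned,
        identity=(aligned - n_mm - n_gap) / aligned,
        n_mismatch=n_mm,
        n_gapcols=n_gap,
        ops=ops,
    )


# ---------------------------------------------------------------------------
# filtering and classification
# ---------------------------------------------------------------------------

def filter_blocks(
    blocks: list[AlignmentBlock],
    min_identity: float = 0.90,
    min_length: int = 100,
) -> list[AlignmentBlock]:
    """Keep blocks with identity strictly above ``min_identity`` and
    aligned length strictly above ``min_length`` (both inequalities are
    strict, mirroring delta-filter-style '>90%' / '>100 bp' thresholds)."""
    return [
        b for b in blocks
        if b.identity > min_identity and b.aligned_length > min_length
    ]


def _interval_overlap(a0, a1, b0, b1):
    return max(0, min(a1, b1) - max(a0, b0))


def _reciprocal(a0, a1, b0, b1, frac):
    ov = _interval_overlap(a0, a1, b0, b1)
    return ov >= frac * (a1 - a0) and ov >= frac * (b1 - b0)


def _best_syn_chain(blocks: list[AlignmentBlock], ascending: bool) -> list[int]:
    """Weighted chain of mutually collinear, non-overlapping blocks."""
    idx = sorted(range(len(blocks)), key=lambda t: (blocks[t].ref_start,
                                                    blocks[t].qry_start))
    best = [float(blocks[t].aligned_length) for t in idx]
    par = [-1] * len(idx)
    for x in range(len(idx)):
        bx = blocks[idx[x]]
        for y in range(x):
            by = blocks[idx[y]]
            if by.ref_end > bx.ref_start:
                continue
            ok = (by.qry_end <= bx.qry_start) if ascending \
                else (bx.qry_end <= by.qry_start)
            if not ok:
                continue
            cand = best[y] + bx.aligned_length
            if cand > best[x]:
                best[x] = cand
                par[x] = y
    if not idx:
        return []
    end = max(range(len(idx)), key=lambda t: best[t])
    chain = []
    while end != -1:
        chain.append(idx[end])
        end = par[end]
    return chain[::-1]


def split_block_at_ref(block: AlignmentBlock, ref_cut: int):
    """Split a block into two at a reference coordinate, preserving exact
    column accounting. Query-only ('I') columns at the cut go right."""
    if not block.ref_start < ref_cut < block.ref_end:
        raise IntegrityError("cut outside block")
    left_ops: list[tuple[str, int]] = []
    right_ops: list[tuple[str, int]] = []
    r = block.ref_start
    q = 0  # query consumed, alignment frame
    q_cut = None
    for op, n in block.ops:
        radv = n if op in "=XD" else 0
        qadv = n if op in "=XI" else 0
        if q_cut is None and radv and r + radv > ref_cut:
            take = ref_cut - r
            if take:
                left_ops.append((op, take))
            if n - take:
                right_ops.append((op, n - take))
            q_cut = q + (take if op in "=X" else 0)
            r += radv
            q += qadv
            continue
        if q_cut is None and r == ref_cut and op in "ID":
            q_cut = q  # boundary: gap columns go right
        (left_ops if q_cut is None else right_ops).append((op, n))
        r += radv
        q += qadv
        if q_cut is None and r == ref_cut:
            q_cut = q
    if q_cut is None:
        q_cut = q

    def make(ops, r0, r1, qa0, qa1):
        ops = _merge_runs(ops)
        aligned = sum(n for _, n in ops)
        if aligned == 0:
            return None
        n_mm = sum(n for op, n in ops if op == "X")
        n_gap = sum(n for op, n in ops if op in "ID")
        ql = block.qry_end - block.qry_start
        if block.strand == "+":
            qs, qe = block.qry_start + qa0, block.qry_start + qa1
        else:
            qs, qe = block.qry_start + (ql - qa1), block.qry_start + (ql - qa0)
        return AlignmentBlock(block.ref_chrom, r0, r1, block.qry_chrom,
                              qs, qe, block.strand, aligned,
                              (aligned - n_mm - n_gap) / aligned,
                              n_mm, n_gap, "UNCLASSIFIED", ops)

    total_q = sum(n for op, n in block.ops if op in "=XI")
    left = make(left_ops, block.ref_start, ref_cut, 0, q_cut)
    right = make(right_ops, ref_cut, block.ref_end, q_cut, total_q)
    return left, right


def _split_on_coverage(block, cover):
    """Split a block at the boundaries of a sorted, merged interval list."""
    cuts = sorted({c for s, e in cover for c in (s, e)
                   if block.ref_start < c < block.ref_end})
    pieces = []
    cur = block
    for c in cuts:
        if cur is None or not cur.ref_start < c < cur.ref_end:
            continue
        left, right = split_block_at_ref(cur, c)
        if left:
            pieces.append(left)
        cur = right
    if cur:
        pieces.append(cur)
    return pieces


def classify_blocks(
    blocks: list[AlignmentBlock],
    ref_len: int | None = None,
    dup_overlap: float = 0.5,
    inv_slack: int = 50_000,
) -> tuple[list[AlignmentBlock], list[tuple[int, int]]]:
    """Label filtered blocks of one chromosome pair and delimit
    non-syntenic reference intervals.

    The highest-scoring mutually collinear, strand-consistent subset is
    SYN (both query orientations are tried, so a globally flipped query
    still yields a syntenic backbone). Each remaining block is split at
    the boundaries of syntenic reference coverage, so a chain that runs
    through a duplication junction separates into its duplicated and
    novel parts; pieces overlapping already-assigned reference or query
    intervals by at least ``dup_overlap`` of their own length are DUP,
    collinear same-strand pieces join the syntenic backbone,
    opposite-strand pieces at backbone-consistent positions are INV, and
    order-breaking pieces are TRANS. Non-syntenic reference intervals are
    the maximal intervals with zero filtered-block coverage.
    """
    if not blocks:
        span = (0, ref_len) if ref_len else None
        return [], ([span] if span else [])
    plus = [b for b in blocks if b.strand == "+"]
    minus = [b for b in blocks if b.strand == "-"]
    chain_p = _best_syn_chain(plus, ascending=True) if plus else []
    chain_m = _best_syn_chain(minus, ascending=False) if minus else []
    w_p = sum(plus[i].aligned_length for i in chain_p)
    w_m = sum(minus[i].aligned_length for i in chain_m)
    if w_p >= w_m:
        syn_set, syn_strand = [plus[i] for i in chain_p], "+"
    else:
        syn_set, syn_strand = [minus[i] for i in chain_m], "-"
    syn_ids = {id(b) for b in syn_set}
    for b in syn_set:
        b.class_label = "SYN"
    syn_sorted = sorted(syn_set, key=lambda b: b.ref_start)
    out: list[AlignmentBlock] = list(syn_sorted)
    cover_ref = _merge_intervals([(b.ref_start, b.ref_end) for b in syn_sorted])
    assigned_qry = [(b.qry_start, b.qry_end) for b in syn_sorted]
    assigned_ref = list(cover_ref)

    def frac_covered(s, e, ivals):
        ov = sum(_interval_overlap(s, e, a, b) for a, b in ivals)
        return ov / (e - s) if e > s else 0.0

    rest = sorted((b for b in blocks if id(b) not in syn_ids),
                  key=lambda b: -b.aligned_length)
    for b in rest:
        for piece in _split_on_coverage(b, cover_ref):
            if frac_covered(piece.ref_start, piece.ref_end,
                            assigned_ref) >= dup_overlap or \
               frac_covered(piece.qry_start, piece.qry_end,
                            assigned_qry) >= dup_overlap:
                piece.class_label = "DUP"
            elif piece.strand == syn_strand and \
                    _fits_backbone(piece, syn_sorted, syn_strand):
                piece.class_label = "SYN"
                syn_sorted.append(piece)
                syn_sorted.sort(key=lambda x: x.ref_start)
                cover_ref = _merge_intervals(
                    cover_ref + [(piece.ref_start, piece.ref_end)])
            elif piece.strand != syn_strand:
                piece.class_label = "INV" if _position_consistent(
                    piece, syn_sorted, inv_slack) else "TRANS"
            else:
                piece.class_label = "TRANS"
            assigned_ref.append((piece.ref_start, piece.ref_end))
            assigned_qry.append((piece.qry_start, piece.qry_end))
            out.append(piece)

    if ref_len is None:
        ref_len = max(b.ref_end for b in out)
    covered = sorted((b.ref_start, b.ref_end) for b in out)
    non_syn: list[tuple[int, int]] = []
    cursor = 0
    for s, e in covered:
        if s > cursor:
            non_syn.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < ref_len:
        non_syn.append((cursor, ref_len))
    out.sort(key=lambda b: (b.ref_start, b.qry_start))
    return out, non_syn


def _fits_backbone(piece, syn_sorted, syn_strand, tol=10):
    prev = [s for s in syn_sorted if s.ref_end <= piece.ref_start + tol]
    nxt = [s for s in syn_sorted if s.ref_start + tol >= piece.ref_end]
    if syn_strand == "+":
        lo = prev[-1].qry_end if prev else 0
        hi = nxt[0].qry_start if nxt else float("inf")
    else:
        lo = nxt[0].qry_end if nxt else 0
        hi = prev[-1].qry_start if prev else float("inf")
    return lo - tol <= piece.qry_start and piece.qry_end <= hi + tol


def _position_consistent(b, syn_sorted, slack):
    if not syn_sorted:
        return True
    prev = [s for s in syn_sorted if s.ref_end <= b.ref_start]
    nxt = [s for s in syn_sorted if s.ref_start >= b.ref_end]
    lo = prev[-1].qry_end if prev else 0
    hi = nxt[0].qry_start if nxt else max(s.qry_end for s in syn_sorted) + slack
    if prev and prev[-1].strand == "-" or (nxt and nxt[0].strand == "-"):
        # backbone on minus strand: query order runs opposite to reference
        lo = nxt[0].qry_end if nxt else 0
        hi = prev[-1].qry_start if prev else max(s.qry_end for s in syn_sorted) + slack
    mid = (b.qry_start + b.qry_end) / 2
    return lo - slack <= mid <= hi + slack


# ---------------------------------------------------------------------------
# SOC shared-sequence catalog
# ---------------------------------------------------------------------------

@dataclass
class SharedSequenceRecord:
    strain_a: str
    strain_b: str
    start_a: int
    end_a: int
    start_b: int
    end_b: int
    length: int
    identity: float


def _merge_intervals(ivals: list[tuple[int, int]], join_gap: int = 0):
    if not ivals:
        return []
    ivals = sorted(ivals)
    out = [list(ivals[0])]
    for s, e in ivals[1:]:
        if s <= out[-1][1] + join_gap:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def shared_sequence_catalog(
    soc_assemblies: list[tuple[str, str]],
    min_len: int = 500,
    min_identity: float = 0.90,
    min_block_len: int = 100,
    min_mem_len: int = 20,
    join_gap: int = 100,
) -> tuple[list[SharedSequenceRecord], dict[str, float]]:
    """All-vs-all shared-sequence catalog over SOC sequences.

    For every strain pair, filtered alignment blocks are merged into
    maximal shared intervals (gaps up to ``join_gap`` bp are bridged);
    records shorter than ``min_len`` are suppressed, matching the display
    threshold used for chord diagrams. The per-strain shared fraction is
    the fraction of the strain's SOC covered by at least one record with
    any partner.
    """
    if len(soc_assemblies) < 2:
        raise ValueError("need at least two SOC sequences")
    records: list[SharedSequenceRecord] = []
    cover: dict[str, list[tuple[int, int]]] = {s: [] for s, _ in soc_assemblies}
    params = ChainParams()
    for (name_a, seq_a), (name_b, seq_b) in combinations(soc_assemblies, 2):
        anchors = find_mems(seq_a, seq_b, min_mem_len)
        blocks = chain_and_extend(anchors, seq_a, seq_b, params,
                                  ref_chrom=name_a, qry_chrom=name_b)
        blocks = filter_blocks(blocks, min_identity, min_block_len)
        if not blocks:
            continue
        merged_a = _merge_intervals([(b.ref_start, b.ref_end) for b in blocks],
                                    join_gap)
        for s, e in merged_a:
            members = [b for b in blocks
                       if _interval_overlap(b.ref_start, b.ref_end, s, e) > 0]
            b0 = min(b.qry_start for b in members)
            b1 = max(b.qry_end for b in members)
            w = sum(b.aligned_length for b in members)
            ident = sum(b.identity * b.aligned_length for b in members) / w
            if e - s >= min_len:
                records.append(SharedSequenceRecord(
                    name_a, name_b, s, e, b0, b1, e - s, ident))
                cover[name_a].append((s, e))
                cover[name_b].append((b0, b1))
    shared_frac = {}
    lengths = dict((s, len(q)) for s, q in soc_assemblies)
    for strain, ivals in cover.items():
        covered = sum(e - s for s, e in _merge_intervals(ivals))
        shared_frac[strain] = covered / lengths[strain] if lengths[strain] else 0.0
    return records, shared_frac
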