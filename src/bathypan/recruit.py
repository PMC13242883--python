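"""Competitive metagenomic read recruitment with the four read filters.

Reads are mapped jointly against a set of reference sequences (k-mer seed
voting plus edit-distance extension), then filtered on low-complexity
base fraction (>75% discards), high-complexity base fraction (<30%
discards), aligned read coverage (<80% discards) and identity (<95%
discards), with positional duplicate removal. The surviving counts feed
relative abundance (mapped / sequenced), the two-reference BOC haplotype
ratio with a Wilson 95% confidence interval, and cross-mapping
specificity (fraction of uniquely recruited reads per reference).

Base-level complexity uses a windowed triplet-frequency (DUST-like)
score: tiled windows score sum c_t(c_t-1)/2 / (n_triplets - 1); bases in
windows scoring at or above ``dust_low`` are low-complexity, at or below
``dust_high`` high-complexity (uniform random sequence scores ~0.5,
homopolymers and dimer repeats score far above the low cutoff).
"""

from __future__ import annotations

import re
import zlib
import warnings
from dataclasses import dataclass, field

import edlib
import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .anchor_align import revcomp
from .simgenome import ConfigError, SimRead

_CIG = re.compile(r"(\d+)([=XID])")


@dataclass(frozen=True)
class MapParams:
    k: int = 21
    pad: int = 16
    seed_stride: int = 4
    max_candidates: int = 5
    min_seed_votes: int = 1
    unique_margin: int = 1
    dust_window: int = 64
    dust_low: float = 2.0
    dust_high: float = 1.0


@dataclass
class MappingResult:
    read_id: str
    target_id: str
    target_pos: int
    strand: str
    identity: float          # matches / alignment columns (gap-inclusive)
    aligned_fraction: float  # read bases aligned to target bases / read length
    unique: bool
    low_complexity_frac: float
    high_complexity_frac: float
    read_len: int
    score: int = 0


@dataclass
class RecruitReport:
    n_sequenced: int
    mapped_counts: dict[str, int] = field(default_factory=dict)
    relative_abundance: dict[str, float] = field(default_factory=dict)
    specific_fraction: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# reference index
# ---------------------------------------------------------------------------

class ReferenceIndex:
    """Joint k-mer -> (target, position) index for competitive mapping,
    held as value-sorted parallel arrays for vectorised lookup."""

    def __init__(self, references: list[tuple[str, str]], k: int = 21):
        ids = [t for t, _ in references]
        if len(set(ids)) != len(ids):
            raise ConfigError("duplicate target ids in reference set")
        self.k = k
        self.targets = list(references)
        keys, tis, poss = [], [], []
        for ti, (tid, seq) in enumerate(references):
            if len(seq) < k:
                warnings.warn(f"reference {tid} shorter than k={k}; "
                              "no k-mers indexed")
                continue
            kv = _kmer_ints(seq, k)
            good = kv != np.uint64(_BAD)
            keys.append(kv[good])
            poss.append(np.nonzero(good)[0].astype(np.int64))
            tis.append(np.full(int(good.sum()), ti, dtype=np.int32))
        if keys:
            key_arr = np.concatenate(keys)
            order = np.argsort(key_arr, kind="stable")
            self._keys = key_arr[order]
            self._ti = np.concatenate(tis)[order]
            self._pos = np.concatenate(poss)[order]
        else:
            self._keys = np.empty(0, dtype=np.uint64)
            self._ti = np.empty(0, dtype=np.int32)
            self._pos = np.empty(0, dtype=np.int64)

    def lookup_range(self, values: np.ndarray):
        """(lo, hi) slices into the entry arrays for each query value."""
        lo = np.searchsorted(self._keys, values, side="left")
        hi = np.searchsorted(self._keys, values, side="right")
        return lo, hi

    def entries(self, lo: int, hi: int):
        return self._ti[lo:hi], self._pos[lo:hi]

    @property
    def n_positions(self) -> int:
        return int(self._keys.size)


_CODE = np.full(256, 4, dtype=np.uint64)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_BAD = int(np.uint64(0xFFFFFFFFFFFFFFFF))


def _kmer_ints(seq: str, k: int) -> np.ndarray:
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    v = np.zeros(n, dtype=np.uint64)
    bad = np.zeros(n, dtype=bool)
    for t in range(k):
        w = codes[t : t + n]
        v = (v << np.uint64(2)) | (w & np.uint64(3))
        bad |= w > 3
    v[bad] = np.uint64(_BAD)
    return v


def index_references(references: list[tuple[str, str]], k: int = 21) -> ReferenceIndex:
    return ReferenceIndex(references, k)


# ---------------------------------------------------------------------------
# complexity
# ---------------------------------------------------------------------------

def _dust_score(window: str) -> float:
    n_trip = len(window) - 2
    if n_trip <= 1:
        return 0.0
    arr = _CODE[np.frombuffer(window.encode("ascii"), np.uint8)].astype(np.int64)
    trip = arr[:-2] * 25 + arr[1:-1] * 5 + arr[2:]
    c = np.bincount(trip, minlength=125)
    s = int((c * (c - 1) // 2).sum())
    return s / (n_trip - 1)


def read_complexity(read: str, w: int = 64, dust_low: float = 2.0,
                    dust_high: float = 1.0) -> tuple[float, float]:
    """(low_frac, high_frac): fractions of bases labelled low- and
    high-complexity by the tiled triplet-frequency score."""
    if not read:
        raise ValueError("empty read")
    low = high = 0
    for start in range(0, len(read), w):
        window = read[start : start + w]
        score = _dust_score(window)
        if score >= dust_low:
            low += len(window)
        elif score <= dust_high:
            high += len(window)
    return low / len(read), high / len(read)


# ---------------------------------------------------------------------------
# mapping
# ---------------------------------------------------------------------------

def _align_read(read: str, target_seq: str, pos_lo: int, pos_hi: int):
    """Infix alignment of the read against a target window; returns
    (score, identity, aligned_fraction, start_pos) or None."""
    window = target_seq[pos_lo:pos_hi]
    if not window:
        return None
    res = edlib.align(read, window, mode="HW", task="path")
    if res["editDistance"] < 0:
        return None
    matches = x = i = d = 0
    for n, op in _CIG.findall(res["cigar"]):
        n = int(n)
        if op == "=":
            matches += n
        elif op == "X":
            x += n
        elif op == "I":
            i += n
        else:
            d += n
    cols = matches + x + i + d
    identity = matches / cols if cols else 0.0
    aligned_fraction = (matches + x) / len(read)
    score = matches - (x + i + d)
    start = pos_lo + res["locations"][0][0]
    return score, identity, aligned_fraction, start


def _finish_read(read_id, seq, cand_votes, index, params):
    """Extend the top-voted (target, diagonal, strand) candidates and pick
    the best placement.

    Within one target, ties break by (position, strand); ties in score
    across targets are assigned by a deterministic hash of the read id
    (such reads are flagged non-unique), so tied placements spread evenly
    over equivalent references instead of piling onto one."""
    cands = sorted(cand_votes.items(), key=lambda kv: (-kv[1], kv[0]))
    per_target: dict[int, tuple] = {}  # ti -> (score, start, strand, id, af)
    rc = None
    tried: list[tuple[int, str, int]] = []
    n_ext = 0
    for (ti, diag, strand), nvotes in cands:
        if nvotes < params.min_seed_votes or n_ext >= params.max_candidates:
            continue
        # a nearby diagonal on the same target/strand is already covered
        # by the extension band of an earlier candidate
        if any(t == ti and s == strand and abs(d - diag) <= params.pad
               for t, s, d in tried):
            continue
        tried.append((ti, strand, diag))
        n_ext += 1
        tid, tseq = index.targets[ti]
        if strand == "-":
            rc = rc if rc is not None else revcomp(seq)
            s = rc
        else:
            s = seq
        lo = max(0, diag - params.pad)
        hi = min(len(tseq), diag + len(seq) + params.pad)
        res = _align_read(s, tseq, lo, hi)
        if res is None:
            continue
        score, ident, afrac, start = res
        prev = per_target.get(ti)
        if prev is None or (-score, start, strand) < (-prev[0], prev[1], prev[2]):
            per_target[ti] = (score, start, strand, ident, afrac)
    if not per_target:
        return None
    top = max(v[0] for v in per_target.values())
    tied = sorted(ti for ti, v in per_target.items() if v[0] == top)
    if len(tied) > 1:
        ti = tied[zlib.crc32(read_id.encode()) % len(tied)]
    else:
        ti = tied[0]
    score, start, strand, ident, afrac = per_target[ti]
    second = max((v[0] for t, v in per_target.items() if t != ti),
                 default=None)
    unique = second is None or score - second >= params.unique_margin
    low, high = read_complexity(seq, params.dust_window, params.dust_low,
                                params.dust_high)
    return MappingResult(read_id, index.targets[ti][0], start, strand, ident,
                         afrac, unique, low, high, len(seq), score)


def map_read(read, index: ReferenceIndex,
             params: MapParams | None = None) -> MappingResult | None:
    """Best competitive placement of one read; None when unmapped."""
    out = map_reads([read], index, params)
    return out[0] if out else None


def map_reads(reads, index: ReferenceIndex,
              params: MapParams | None = None) -> list[MappingResult]:
    """Competitive mapping of a read collection.

    Seed lookup is batched: k-mers for all reads (both strands, sampled
    at ``seed_stride``) are matched against the index in one vectorised
    pass, and only reads with at least one seed hit proceed to voting and
    extension. Results preserve input read order.
    """
    params = params or MapParams()
    items = [(r.read_id, r.seq) if isinstance(r, SimRead) else tuple(r)
             for r in reads]
    out: list[MappingResult] = []
    by_len: dict[int, list[int]] = {}
    for i, (_rid, seq) in enumerate(items):
        if len(seq) >= index.k:
            by_len.setdefault(len(seq), []).append(i)
    vote_store: dict[int, dict] = {}
    for length, idxs in by_len.items():
        m = length - index.k + 1
        offs = np.arange(0, m, params.seed_stride, dtype=np.int64)
        enc = np.empty((len(idxs), length), dtype=np.uint8)
        for row, i in enumerate(idxs):
            enc[row] = np.frombuffer(items[i][1].encode("ascii"), np.uint8)
        codes = _CODE[enc]
        rc_codes = np.where(codes[:, ::-1] > 3, np.uint64(4),
                            np.uint64(3) - codes[:, ::-1])
        for sbit, cm in ((0, codes), (1, rc_codes)):
            km = np.zeros((len(idxs), offs.size), dtype=np.uint64)
            bad = np.zeros((len(idxs), offs.size), dtype=bool)
            for t in range(index.k):
                w = cm[:, offs + t]
                km = (km << np.uint64(2)) | (w & np.uint64(3))
                bad |= w > 3
            km[bad] = np.uint64(_BAD)
            lo, hi = index.lookup_range(km)
            rows, cols = np.nonzero(hi > lo)
            if rows.size == 0:
                continue
            l = lo[rows, cols]
            counts = (hi[rows, cols] - l).astype(np.int64)
            total = int(counts.sum())
            base = np.repeat(np.cumsum(counts) - counts, counts)
            eidx = np.repeat(l, counts) + (np.arange(total) - base)
            ti = index._ti[eidx].astype(np.int64)
            diag = index._pos[eidx] - np.repeat(offs[cols], counts)
            rowrep = np.repeat(rows.astype(np.int64), counts)
            # pack (row, target, diagonal): diagonals fit in 34 bits signed
            key = (((rowrep * len(index.targets)) + ti) << np.int64(35)) \
                + (diag + (1 << 34))
            ukey, ucnt = np.unique(key, return_counts=True)
            urow = (ukey >> np.int64(35)) // len(index.targets)
            uti = (ukey >> np.int64(35)) % len(index.targets)
            udiag = (ukey & ((1 << 35) - 1)) - (1 << 34)
            strand = "+" if sbit == 0 else "-"
            for r, t_, d, c in zip(urow.tolist(), uti.tolist(),
                                   udiag.tolist(), ucnt.tolist()):
                vd = vote_store.setdefault(idxs[r], {})
                vd[(t_, d, strand)] = vd.get((t_, d, strand), 0) + c
    results: dict[int, MappingResult] = {}
    for i, votes in vote_store.items():
        rid, seq = items[i]
        res = _finish_read(rid, seq, votes, index, params)
        if res is not None:
            results[i] = res
    return [results[i] for i in sorted(results)]


# ---------------------------------------------------------------------------
# filters and statistics
# ---------------------------------------------------------------------------

def apply_filters(results: list[MappingResult],
                  low_max: float = 0.75,
                  high_min: float = 0.30,
                  cov_min: float = 0.80,
                  id_min: float = 0.95) -> list[MappingResult]:
    """Discard reads failing any of the four thresholds, then remove
    positional duplicates (same target, position, strand and read length;
    the lexicographically first read id survives)."""
    kept = [r for r in results
            if not (r.low_complexity_frac > low_max
                    or r.high_complexity_frac < high_min
                    or r.aligned_fraction < cov_min
                    or r.identity < id_min)]
    kept.sort(key=lambda r: r.read_id)
    seen: set[tuple] = set()
    out = []
    for r in kept:
        key = (r.target_id, r.target_pos, r.strand, r.read_len)
        if key in seen:
            continue
        seen.add(key)
        out.append(r)
    return out


def relative_abundance(filtered: list[MappingResult],
                       n_sequenced_total: int) -> dict[str, float]:
    """Per target: filtered mapped reads / total reads sequenced."""
    if n_sequenced_total <= 0:
        raise ValueError("n_sequenced_total must be positive")
    counts: dict[str, int] = {}
    for r in filtered:
        counts[r.target_id] = counts.get(r.target_id, 0) + 1
    return {t: c / n_sequenced_total for t, c in counts.items()}


@dataclass
class HaplotypeRatio:
    n_a: int
    n_b: int
    ratio_a: float | None
    ci_a: tuple[float, float] | None
    ratio_a_norm: float | None       # region-length normalised
    ci_a_norm: tuple[float, float] | None
    undefined: bool = False


def _length_normalise(p: float, la: int, lb: int) -> float:
    return (p / la) / (p / la + (1 - p) / lb) if 0 <= p <= 1 else p


def unique_region_lengths(region_a: tuple[str, str],
                          region_b: tuple[str, str]) -> tuple[int, int]:
    """Uniquely mappable length of each haplotype reference.

    The two outlier regions share residual homologous segments; reads
    from those map to both references and are excluded by the
    unique-mapping rule, so the count-generating length of each reference
    is its total length minus the cross-homologous coverage. Homology is
    measured by the assembly-alignment stage on the references
    themselves (filtered blocks, both strands)."""
    from . import anchor_align as aa
    anchors = aa.find_mems(region_a[1], region_b[1], 20)
    blocks = aa.filter_blocks(aa.chain_and_extend(
        anchors, region_a[1], region_b[1]))
    cov_a = aa._merge_intervals([(b.ref_start, b.ref_end) for b in blocks])
    cov_b = aa._merge_intervals([(b.qry_start, b.qry_end) for b in blocks])
    la = len(region_a[1]) - sum(e - s for s, e in cov_a)
    lb = len(region_b[1]) - sum(e - s for s, e in cov_b)
    return max(la, 1), max(lb, 1)


def haplotype_ratio(reads, region_a: tuple[str, str], region_b: tuple[str, str],
                    params: MapParams | None = None,
                    unique_only: bool = True,
                    low_max: float = 0.75, high_min: float = 0.30,
                    cov_min: float = 0.80, id_min: float = 0.95,
                    norm_lengths: tuple[int, int] | None = None) -> HaplotypeRatio:
    """Competitive recruitment against the two haplotype outlier-region
    references; ratio_A = nA / (nA + nB) over filtered (optionally
    uniquely mapped) reads, with a Wilson 95% CI. The length-normalised
    ratio divides counts by each reference's uniquely mappable length
    (``unique_region_lengths``, or ``norm_lengths`` when precomputed),
    correcting for the unequal sizes of the two outlier regions.
    """
    params = params or MapParams()
    index = ReferenceIndex([region_a, region_b], params.k)
    results = map_reads(reads, index, params)
    filtered = apply_filters(results, low_max, high_min, cov_min, id_min)
    if unique_only:
        filtered = [r for r in filtered if r.unique]
    n_a = sum(1 for r in filtered if r.target_id == region_a[0])
    n_b = sum(1 for r in filtered if r.target_id == region_b[0])
    if n_a + n_b == 0:
        return HaplotypeRatio(0, 0, None, None, None, None, undefined=True)
    p = n_a / (n_a + n_b)
    lo, hi = proportion_confint(n_a, n_a + n_b, alpha=0.05, method="wilson")
    if norm_lengths is not None:
        la, lb = norm_lengths
    elif unique_only:
        la, lb = unique_region_lengths(region_a, region_b)
    else:
        la, lb = len(region_a[1]), len(region_b[1])
    return HaplotypeRatio(
        n_a, n_b, p, (float(lo), float(hi)),
        _length_normalise(p, la, lb),
        (_length_normalise(float(lo), la, lb),
         _length_normalise(float(hi), la, lb)))


def cross_mapping_specificity(reads, references: list[tuple[str, str]],
                              params: MapParams | None = None,
                              **filter_kwargs) -> dict[str, float]:
    """Per reference: uniquely mapped filtered reads / all filtered reads
    recruited to it under competitive mapping."""
    if len(references) < 2:
        raise ValueError("need at least two references")
    params = params or MapParams()
    index = ReferenceIndex(references, params.k)
    filtered = apply_filters(map_reads(reads, index, params), **filter_kwargs)
    totals: dict[str, int] = {}
    uniq: dict[str, int] = {}
    for r in filtered:
        totals[r.target_id] = totals.get(r.target_id, 0) + 1
        if r.unique:
            uniq[r.target_id] = uniq.get(r.target_id, 0) + 1
    return {t: uniq.get(t, 0) / n for t, n in totals.items()}
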