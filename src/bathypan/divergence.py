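"""Variant extraction and sliding-window divergence statistics.

SNPs and structural variants are read directly off the column-level
alignments produced by the anchoring stage; polymorphism is then
summarised on 20-kb sliding windows as the ratio of local variant
density to the genome-wide density, the statistic used to reveal the
reduced polymorphism of the outlier region. GC profiling, outlier-region
delimitation (low-GC and/or loss-of-synteny evidence) and coding-density
computation complete the chromosome-landscape toolkit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anchor_align import AlignmentBlock, IntegrityError, revcomp


@dataclass(frozen=True)
class SnpRecord:
    ref_chrom: str
    position: int  # 0-based on the reference
    ref_base: str
    alt_base: str
    query_strain: str


@dataclass(frozen=True)
class SvRecord:
    type: str  # INS | DEL | INV | DUP | TRANS
    ref_chrom: str
    ref_start: int
    ref_end: int
    qry_start: int
    qry_end: int
    query_strain: str


@dataclass(frozen=True)
class WindowStat:
    chrom: str
    start: int
    end: int
    n_variants: int
    density: float
    ratio: float


class RangeError(ValueError):
    pass


# ---------------------------------------------------------------------------
# variant calling from alignment blocks
# ---------------------------------------------------------------------------

def call_variants(
    blocks: list[AlignmentBlock],
    ref_seqs: dict[str, str],
    qry_seqs: dict[str, str],
    strain: str,
    min_indel_sv: int = 30,
    gap_ratio: float = 0.2,
) -> tuple[list[SnpRecord], list[SvRecord]]:
    """Extract SNPs and SVs from classified, filtered blocks of one
    strain-vs-reference comparison.

    SNPs come from mismatch columns inside SYN blocks; intra-block indel
    runs and inter-SYN-block gaps of at least ``min_indel_sv`` bp (with
    the opposite sequence's gap below ``gap_ratio`` of it) become INS/DEL;
    INV/DUP/TRANS records are lifted from block class labels. Records are
    deduplicated per locus.
    """
    snps: dict[tuple, SnpRecord] = {}
    svs: list[SvRecord] = []
    syn_by_chrom: dict[str, list[AlignmentBlock]] = {}
    for b in blocks:
        if b.class_label == "SYN":
            syn_by_chrom.setdefault(b.ref_chrom, []).append(b)
        elif b.class_label in ("INV", "DUP", "TRANS"):
            svs.append(SvRecord(b.class_label, b.ref_chrom, b.ref_start,
                                b.ref_end, b.qry_start, b.qry_end, strain))

    for chrom, syn in syn_by_chrom.items():
        syn.sort(key=lambda b: b.ref_start)
        for prev, nxt in zip(syn, syn[1:]):
            if prev.ref_end > nxt.ref_start:
                raise IntegrityError("overlapping SYN blocks on " + chrom)
        ref_seq = ref_seqs[chrom]
        for b in syn:
            _block_variants(b, ref_seq, qry_seqs.get(b.qry_chrom, ""),
                            strain, min_indel_sv, snps, svs)
        for prev, nxt in zip(syn, syn[1:]):
            rg = nxt.ref_start - prev.ref_end
            if prev.strand == "+" and nxt.strand == "+":
                qg = nxt.qry_start - prev.qry_end
            elif prev.strand == "-" and nxt.strand == "-":
                qg = prev.qry_start - nxt.qry_end
            else:
                continue
            if rg >= min_indel_sv and qg <= gap_ratio * rg:
                svs.append(SvRecord("DEL", chrom, prev.ref_end, nxt.ref_start,
                                    0, 0, strain))
            elif qg >= min_indel_sv and rg <= gap_ratio * qg:
                svs.append(SvRecord("INS", chrom, prev.ref_end, prev.ref_end,
                                    0, 0, strain))
    uniq_svs = sorted(set(svs), key=lambda r: (r.ref_chrom, r.ref_start,
                                               r.type, r.qry_start))
    out_snps = sorted(snps.values(), key=lambda r: (r.ref_chrom, r.position))
    return out_snps, uniq_svs


def _block_variants(b, ref_seq, qry_seq, strain, min_indel_sv, snps, svs):
    """Walk one block's column runs; qry cursor runs over the block's
    alignment frame (reverse complement of the interval for '-' blocks)."""
    if b.strand == "+":
        q_aln = qry_seq[b.qry_start:b.qry_end]
    else:
        q_aln = revcomp(qry_seq[b.qry_start:b.qry_end])
    r, q = b.ref_start, 0
    for op, n in b.ops:
        if op == "=":
            r += n
            q += n
        elif op == "X":
            for t in range(n):
                key = (b.ref_chrom, r + t)
                if key not in snps and q + t < len(q_aln):
                    snps[key] = SnpRecord(b.ref_chrom, r + t, ref_seq[r + t],
                                          q_aln[q + t], strain)
            r += n
            q += n
        elif op == "I":
            if n >= min_indel_sv:
                svs.append(SvRecord("INS", b.ref_chrom, r, r, 0, n, strain))
            q += n
        elif op == "D":
            if n >= min_indel_sv:
                svs.append(SvRecord("DEL", b.ref_chrom, r, r + n, 0, 0, strain))
            r += n


# ---------------------------------------------------------------------------
# window statistics
# ---------------------------------------------------------------------------

def variant_positions(records) -> dict[str, np.ndarray]:
    """SNPs count at their position, SVs at their reference midpoint (so a
    long SV is counted once)."""
    by_chrom: dict[str, list[int]] = {}
    for r in records:
        if isinstance(r, SnpRecord):
            by_chrom.setdefault(r.ref_chrom, []).append(r.position)
        else:
            by_chrom.setdefault(r.ref_chrom, []).append(
                (r.ref_start + r.ref_end) // 2)
    return {c: np.sort(np.array(p, dtype=np.int64))
            for c, p in by_chrom.items()}


def window_divergence(
    records,
    chrom_lengths: dict[str, int],
    window: int = 20_000,
    step: int = 5_000,
    genome_wide_density: float | None = None,
    aligned_bp: int | None = None,
) -> list[WindowStat]:
    """Sliding-window variant density relative to the genome-wide density.

    Windows tile [0, chrom_len) at the given step; the final partial
    window is kept and normalised by its true length. The genome-wide
    density defaults to total variants over ``aligned_bp`` (the aligned,
    block-covered fraction of the genome carries all variant information)
    or, failing that, over the summed chromosome lengths.
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    pos = variant_positions(records)
    total = sum(arr.size for arr in pos.values())
    if genome_wide_density is None:
        denom = aligned_bp if aligned_bp else sum(chrom_lengths.values())
        genome_wide_density = total / denom if denom else 0.0
    if genome_wide_density <= 0 and total > 0:
        raise ValueError("genome_wide_density must be positive")
    out: list[WindowStat] = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        arr = pos.get(chrom, np.empty(0, dtype=np.int64))
        for start in range(0, length, step):
            end = min(start + window, length)
            n = int(np.searchsorted(arr, end) - np.searchsorted(arr, start))
            density = n / (end - start)
            ratio = density / genome_wide_density if genome_wide_density else 0.0
            out.append(WindowStat(chrom, start, end, n, density, ratio))
            if end >= length:
                break
    return out


def detect_reduced_polymorphism(
    windows: list[WindowStat],
    ratio_threshold: float = 1.0,
    min_consecutive: int = 3,
) -> list[tuple[str, int, int]]:
    """Maximal runs of >= ``min_consecutive`` consecutive windows whose
    divergence ratio is below threshold, merged into intervals."""
    intervals: list[tuple[str, int, int]] = []
    by_chrom: dict[str, list[WindowStat]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)
    for chrom in sorted(by_chrom):
        ws = sorted(by_chrom[chrom], key=lambda w: w.start)
        run: list[WindowStat] = []
        for w in ws + [None]:
            if w is not None and w.ratio < ratio_threshold:
                run.append(w)
                continue
            if len(run) >= min_consecutive:
                intervals.append((chrom, run[0].start, run[-1].end))
            run = []
    # merge overlapping intervals produced by overlapping windows
    merged: list[tuple[str, int, int]] = []
    for chrom, s, e in sorted(intervals):
        if merged and merged[-1][0] == chrom and s <= merged[-1][2]:
            merged[-1] = (chrom, merged[-1][1], max(merged[-1][2], e))
        else:
            merged.append((chrom, s, e))
    return merged


# ---------------------------------------------------------------------------
# GC landscape and outlier-region delimitation
# ---------------------------------------------------------------------------

def gc_profile(seq: str, window: int = 20_000, step: int = 5_000):
    """Per-window GC fraction along a sequence; the final partial window is
    normalised by its true length."""
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_gc = np.isin(arr, np.frombuffer(b"GCgc", np.uint8)).astype(np.int64)
    cum = np.concatenate([[0], np.cumsum(is_gc)])
    out = []
    for start in range(0, len(seq), step):
        end = min(start + window, len(seq))
        out.append(((start, end), float((cum[end] - cum[start]) / (end - start))))
        if end >= len(seq):
            break
    return out


def _flag_runs(flags, spans, min_span, max_interrupt):
    """Candidate intervals: runs of flagged windows tolerating short
    interruptions, reported as (start, end) and filtered by span."""
    candidates = []
    i = 0
    n = len(flags)
    while i < n:
        if not flags[i]:
            i += 1
            continue
        j = i
        last_true = i
        gap = 0
        while j + 1 < n:
            if flags[j + 1]:
                last_true = j + 1
                gap = 0
            else:
                gap += 1
                if gap > max_interrupt:
                    break
            j += 1
        s, e = spans[i][0], spans[last_true][1]
        if e - s >= min_span:
            candidates.append((s, e))
        i = last_true + 1
    return candidates


def delimit_outlier_region(
    gc_windows=None,
    non_syntenic_ref_intervals=None,
    chrom_len: int | None = None,
    gc_drop_sd: float = 2.0,
    min_span: int = 50_000,
    nonsyn_cov_min: float = 0.5,
    max_interrupt: int = 3,
    window: int = 20_000,
    step: int = 5_000,
) -> tuple[int, int] | None:
    """Delimit the outlier region from depressed GC and/or loss of synteny.

    Two evidence tracks are evaluated per window: a GC z-score at most
    ``-gc_drop_sd`` below the chromosome-wide window mean, and
    non-syntenic coverage of at least ``nonsyn_cov_min``. Runs tolerate up
    to ``max_interrupt`` consecutive non-flagged windows (retained
    segments inside an otherwise haplotype-specific region briefly restore
    synteny). When both tracks yield a candidate the candidates are
    intersected; with one evidence source the available track is used.
    Returns the maximal candidate interval of span >= ``min_span``or None.
    """
    gc_candidate = syn_candidate = None
    if gc_windows:
        spans = [w for w, _ in gc_windows]
        vals = np.array([v for _, v in gc_windows])
        sd = vals.std()
        if sd > 0:
            z = (vals - vals.mean()) / sd
            flags = (z <= -gc_drop_sd).tolist()
            cands = _flag_runs(flags, spans, min_span, max_interrupt)
            if cands:
                gc_candidate = max(cands, key=lambda c: c[1] - c[0])
        if chrom_len is None:
            chrom_len = spans[-1][1]
    if non_syntenic_ref_intervals is not None and chrom_len:
        ivals = sorted(non_syntenic_ref_intervals)
        spans = []
        flags = []
        for start in range(0, chrom_len, step):
            end = min(start + window, chrom_len)
            cov = sum(max(0, min(e, end) - max(s, start)) for s, e in ivals)
            spans.append((start, end))
            flags.append(cov / (end - start) >= nonsyn_cov_min)
            if end >= chrom_len:
                break
        cands = _flag_runs(flags, spans, min_span, max_interrupt)
        if cands:
            syn_candidate = max(cands, key=lambda c: c[1] - c[0])
    if gc_candidate and syn_candidate:
        s = max(gc_candidate[0], syn_candidate[0])
        e = min(gc_candidate[1], syn_candidate[1])
        return (s, e) if e - s >= min_span else None
    return gc_candidate or syn_candidate


def coding_density(genes, interval: tuple[int, int],
                   chrom: str | None = None,
                   chrom_len: int | None = None) -> float:
    """Fraction of the interval covered by at least one gene (union of
    gene intervals, so overlapping models are not double counted)."""
    s0, e0 = interval
    if s0 < 0 or e0 <= s0 or (chrom_len is not None and e0 > chrom_len):
        raise RangeError(f"invalid interval {interval}")
    ivals = sorted(
        (max(g.start, s0), min(g.end, e0))
        for g in genes
        if (chrom is None or g.chrom == chrom) and g.end > s0 and g.start < e0)
    covered = 0
    cursor = s0
    for s, e in ivals:
        s = max(s, cursor)
        if e > s:
            covered += e - s
            cursor = e
    return covered / (e0 - s0)
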