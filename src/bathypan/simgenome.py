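"""Seeded synthetic genomes emulating Mamiellophyceae genome architecture.

Generates haploid multi-chromosome genomes (~15 Mb over 19 chromosomes by
default) with the two hallmark outlier structures of this lineage: a big
outlier chromosome (BOC) whose large distal region exists in two
non-syntenic haplotypes with depressed GC and depressed coding density,
and a small outlier chromosome (SOC) assembled per strain from a shared
block pool behind a conserved distal core. Strain panels descend from the
two haplotype ancestors along a recorded genealogy through substitutions
and placed structural variants, and read sets are drawn from weighted
strain mixtures. Every operation is deterministic for a fixed seed and
returns a truth table sufficient to reconstruct its output exactly.

Coordinates are 0-based half-open throughout; GFF3 emission converts to
1-based closed form. Gene models are mono-exonic and non-overlapping,
mirroring the predominantly mono-exonic gene structure of these genomes;
``cds_seq`` is the sense-strand sequence (reverse complement of the
chromosome slice for minus-strand genes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np

from .anchor_align import revcomp


class ConfigError(ValueError):
    """Impossible or inconsistent simulation configuration."""


class SimulationError(RuntimeError):
    """A sampling step could not be completed (e.g. unplaceable SV)."""


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# configuration and record types
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Study-scale defaults: a 15-Mb, 19-chromosome haploid genome whose
    BOC (chromosome 14) carries a distal outlier region of 400 kb
    (haplotype A) expanding to ~500 kb in haplotype B, genome GC 0.48
    dropping to 0.40 in the outlier, whole-genome coding density 0.787
    dropping to 0.47 in the outlier, and a SOC (chromosome 19) constrained
    to 48-230 kb."""

    seed: int = 0
    n_chromosomes: int = 19
    chrom_lengths: list[int] | None = None
    total_genome_size: int = 15_000_000
    genome_gc: float = 0.48
    outlier_gc: float = 0.40
    boc_chrom: str = "chr14"
    boc_region_len_A: int = 400_000
    boc_region_len_B: int = 500_000
    soc_chrom: str = "chr19"
    soc_len_range: tuple[int, int] = (48_000, 230_000)
    snp_rate: float = 0.005
    sv_counts: dict = field(default_factory=lambda: {
        "INS": 2, "DEL": 2, "INV": 1, "DUP": 1, "TRANS": 1})
    sv_len_ranges: dict = field(default_factory=lambda: {
        "INS": (1_000, 10_000), "DEL": (1_000, 10_000),
        "INV": (5_000, 50_000), "DUP": (1_000, 10_000),
        "TRANS": (1_000, 10_000)})
    gene_density_normal: float = 0.787
    gene_density_outlier: float = 0.47
    # BOC haplotype derivation: retained (alignable, divergent) segments
    # inside the otherwise haplotype-specific outlier region
    boc_n_kept: int = 3
    boc_kept_len: tuple[int, int] = (5_000, 9_000)
    boc_kept_divergence: float = 0.03
    # SOC architecture
    soc_core_len: int = 30_000
    soc_pool_size: int = 12
    soc_block_prob: float = 0.5

    def chromosome_names(self) -> list[str]:
        return [f"chr{i + 1:02d}" for i in range(self.n_chromosomes)]

    def validate(self) -> None:
        names = self.chromosome_names()
        if self.boc_chrom == self.soc_chrom:
            raise ConfigError("boc_chrom and soc_chrom must differ")
        if self.boc_chrom not in names or self.soc_chrom not in names:
            raise ConfigError("boc_chrom/soc_chrom not in chromosome list")
        for name, val in (("genome_gc", self.genome_gc),
                          ("outlier_gc", self.outlier_gc),
                          ("snp_rate", self.snp_rate)):
            if not 0 <= val < 1:
                raise ConfigError(f"{name} must be in [0,1): {val}")
        if self.outlier_gc >= self.genome_gc:
            raise ConfigError("outlier_gc must be below genome_gc")
        for v in (self.boc_region_len_A, self.boc_region_len_B,
                  self.total_genome_size, *(self.chrom_lengths or [1])):
            if v <= 0:
                raise ConfigError("all lengths must be positive")
        lo, hi = self.soc_len_range
        if not 0 < lo <= hi:
            raise ConfigError("invalid soc_len_range")
        lengths = self.resolved_chrom_lengths()
        boc_len = lengths[names.index(self.boc_chrom)]
        if self.boc_region_len_A >= boc_len:
            raise ConfigError(
                f"BOC outlier region ({self.boc_region_len_A} bp) does not "
                f"fit on {self.boc_chrom} ({boc_len} bp)")

    def resolved_chrom_lengths(self) -> list[int]:
        """Per-chromosome lengths; when not supplied, 18 chromosome lengths
        are drawn log-normally (seeded) to split the genome, plus the SOC."""
        if self.chrom_lengths is not None:
            if len(self.chrom_lengths) != self.n_chromosomes:
                raise ConfigError("chrom_lengths does not match n_chromosomes")
            return list(self.chrom_lengths)
        names = self.chromosome_names()
        rng = np.random.default_rng([self.seed, 7])
        soc_len = int(np.mean(self.soc_len_range))
        n_auto = self.n_chromosomes - 1
        raw = rng.lognormal(0.0, 0.35, size=n_auto)
        budget = self.total_genome_size - soc_len
        lengths = np.maximum((raw / raw.sum() * budget).astype(int), 50_000)
        out: list[int] = []
        k = 0
        for name in names:
            if name == self.soc_chrom:
                out.append(soc_len)
            else:
                out.append(int(lengths[k]))
                k += 1
        # the BOC must accommodate its outlier region plus syntenic flanks
        bi = names.index(self.boc_chrom)
        need = self.boc_region_len_A + 250_000
        if out[bi] < need:
            out[bi] = need
        return out


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    cds_seq: str = ""

    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeAssembly:
    """One strain: named chromosome sequences plus mono-exonic gene models."""

    strain_id: str
    chromosomes: list[tuple[str, str]]
    genes: list[GeneModel] = field(default_factory=list)

    def seq(self, chrom: str) -> str:
        for name, s in self.chromosomes:
            if name == chrom:
                return s
        raise KeyError(chrom)

    def set_seq(self, chrom: str, seq: str) -> None:
        for i, (name, _) in enumerate(self.chromosomes):
            if name == chrom:
                self.chromosomes[i] = (chrom, seq)
                return
        raise KeyError(chrom)

    def chrom_names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    def total_length(self) -> int:
        return sum(len(s) for _, s in self.chromosomes)

    def genes_on(self, chrom: str) -> list[GeneModel]:
        return [g for g in self.genes if g.chrom == chrom]

    def validate(self) -> None:
        names = self.chrom_names()
        if len(set(names)) != len(names):
            raise ConfigError("duplicate chromosome names")
        lens = {n: len(s) for n, s in self.chromosomes}
        if any(v == 0 for v in lens.values()):
            raise ConfigError("empty chromosome sequence")
        seen = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ConfigError(f"duplicate gene id {g.gene_id}")
            seen.add(g.gene_id)
            if g.chrom not in lens or not 0 <= g.start < g.end <= lens[g.chrom]:
                raise ConfigError(f"gene {g.gene_id} outside its chromosome")


@dataclass
class TruthSet:
    """Ground truth emitted alongside simulated artifacts.

    ``snps`` rows: (chrom, parent_pos, child_pos, ref, alt).
    ``svs`` rows: (type, chrom, parent_start, parent_end, child_start,
    child_end). ``sv_ops`` holds the replayable per-chromosome operation
    lists; ``events`` the replayable BOC-derivation series.
    """

    snps: list = field(default_factory=list)
    svs: list = field(default_factory=list)
    cluster_design: dict = field(default_factory=dict)
    soc_blocks: list = field(default_factory=list)
    mixture_origins: list = field(default_factory=list)
    events: list = field(default_factory=list)
    sv_ops: dict = field(default_factory=dict)
    regions: dict = field(default_factory=dict)
    topologies: dict = field(default_factory=dict)
    haplotypes: dict = field(default_factory=dict)
    dropped_genes: list = field(default_factory=list)
    strain_truths: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# sequence and gene sampling
# ---------------------------------------------------------------------------

def random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    """i.i.d. sequence with per-base GC probability ``gc`` (no post-hoc
    correction, preserving the independence assumed by complexity filters)."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    draws = rng.choice(4, size=length, p=p)
    return _BASES[draws].tobytes().decode("ascii")


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return float(np.isin(arr, np.frombuffer(b"GCgc", np.uint8)).mean())


def _sample_gene_intervals(rng, region_start, region_end, density,
                           mean_len=1100.0, sigma=0.3):
    """Non-overlapping intervals targeting a coding fraction of ``density``."""
    out = []
    pos = region_start
    gap_mean = mean_len * (1 - density) / max(density, 1e-6)
    while True:
        glen = int(np.clip(rng.lognormal(math.log(mean_len), sigma), 300, 4000))
        if pos + glen > region_end:
            break
        strand = "+" if rng.random() < 0.5 else "-"
        out.append((pos, pos + glen, strand))
        pos += glen + max(20, int(rng.exponential(gap_mean)))
    return out


def _fill_cds(assembly: GenomeAssembly) -> None:
    seqs = dict(assembly.chromosomes)
    for g in assembly.genes:
        s = seqs[g.chrom][g.start:g.end]
        g.cds_seq = s if g.strand == "+" else revcomp(s)


# ---------------------------------------------------------------------------
# ancestor construction
# ---------------------------------------------------------------------------

def build_ancestor(config: SimConfig) -> tuple[GenomeAssembly, TruthSet]:
    """One haploid genome realising the configured composition targets.

    The BOC carries a distal region of ``boc_region_len_A`` bp at
    ``outlier_gc`` and ``gene_density_outlier``; all other sequence is at
    ``genome_gc`` / ``gene_density_normal``. Deterministic per seed.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    names = config.chromosome_names()
    lengths = config.resolved_chrom_lengths()
    chroms: list[tuple[str, str]] = []
    genes: list[GeneModel] = []
    truth = TruthSet()
    gid = 0
    for name, length in zip(names, lengths):
        if name == config.boc_chrom:
            ostart = length - config.boc_region_len_A
            seq = (random_seq(rng, ostart, config.genome_gc)
                   + random_seq(rng, config.boc_region_len_A, config.outlier_gc))
            ivals = (_sample_gene_intervals(rng, 0, ostart - 100,
                                            config.gene_density_normal)
                     + _sample_gene_intervals(rng, ostart, length,
                                              config.gene_density_outlier))
            truth.regions["boc_outlier"] = {"ancestor": (name, ostart, length)}
        else:
            seq = random_seq(rng, length, config.genome_gc)
            ivals = _sample_gene_intervals(rng, 0, length,
                                           config.gene_density_normal)
        chroms.append((name, seq))
        for s, e, strand in ivals:
            gid += 1
            genes.append(GeneModel(f"g{gid:05d}", name, s, e, strand))
    assembly = GenomeAssembly("ancestor", chroms, genes)
    _fill_cds(assembly)
    assembly.validate()
    return assembly, truth


# ---------------------------------------------------------------------------
# BOC haplotype derivation
# ---------------------------------------------------------------------------

def replay_boc_events(seq: str, events: list) -> str:
    """Apply a recorded BOC derivation series to an outlier sequence.

    Event forms: ("replace", s, e, seq) substitutes the interval,
    ("invert", s, e) reverse-complements it in place,
    ("duplicate", s, e, at) inserts a copy of [s,e) at ``at``.
    Events are applied sequentially; an empty list is the identity.
    """
    out = seq
    for ev in events:
        kind = ev[0]
        if kind == "replace":
            _, s, e, new = ev
            out = out[:s] + new + out[e:]
        elif kind == "invert":
            _, s, e = ev
            out = out[:s] + revcomp(out[s:e]) + out[e:]
        elif kind == "duplicate":
            _, s, e, at = ev
            out = out[:at] + out[s:e] + out[at:]
        else:
            raise ValueError(f"unknown BOC event {kind}")
    return out


def _mutate_str(rng, seq: str, rate: float) -> tuple[str, list]:
    """Substitution-only mutation; returns (sequence, [(pos, ref, alt)])."""
    n = len(seq)
    count = rng.poisson(rate * n)
    if count == 0:
        return seq, []
    count = min(count, n)
    pos = np.sort(rng.choice(n, size=count, replace=False))
    arr = bytearray(seq.encode("ascii"))
    snps = []
    shifts = rng.integers(1, 4, size=count)
    order = b"ACGT"
    for p, sh in zip(pos.tolist(), shifts.tolist()):
        ref = arr[p]
        if ref not in order:
            continue
        alt = order[(order.index(ref) + sh) % 4]
        arr[p] = alt
        snps.append((int(p), chr(ref), chr(alt)))
    return arr.decode("ascii"), snps


def derive_boc_haplotypes(
    ancestor: GenomeAssembly,
    config: SimConfig,
    events: list | None = None,
) -> tuple[GenomeAssembly, GenomeAssembly, TruthSet]:
    """Derive the two BOC haplotypes from one ancestor.

    Haplotype A is the ancestor itself. Haplotype B's outlier region is
    produced by a recorded series of segment replacements (novel sequence
    at outlier composition), inversions and a duplication applied to A's
    outlier; a few interior segments are retained with
    ``boc_kept_divergence`` substitution divergence so the two haplotypes
    share alignable, divergent core genes while most of the region is
    haplotype-specific. Flanking arms are untouched (syntenic). Passing an
    explicit empty ``events`` list yields identical outlier regions.
    """
    rng = np.random.default_rng([config.seed, 1])
    names = ancestor.chrom_names()
    boc = config.boc_chrom
    chrom_seq = ancestor.seq(boc)
    length = len(chrom_seq)
    la = config.boc_region_len_A
    ostart = length - la
    s_a = chrom_seq[ostart:]

    kept: list[tuple[int, int, bool]] = []  # (start, end, inverted) within s_a
    explicit = events is not None
    if events is None:
        lo, hi = config.boc_kept_len
        n_kept = config.boc_n_kept
        # evenly spread retained segments with jitter, clear of both edges
        for i in range(n_kept):
            center = int(la * (i + 1) / (n_kept + 1)
                         + rng.integers(-la // 20, la // 20 + 1))
            klen = int(rng.integers(lo, hi + 1))
            s = max(30_000, min(center - klen // 2, la - 30_000 - klen))
            kept.append((s, s + klen, i % 2 == 1))
        kept.sort()
        events = _boc_event_plan(rng, s_a, kept, config)
    s_b = replay_boc_events(s_a, events)
    lb_realized = len(s_b)

    hapl_a = _clone_assembly(ancestor, "haplA")
    hapl_b = _clone_assembly(ancestor, "haplB")
    hapl_b.set_seq(boc, chrom_seq[:ostart] + s_b)
    if explicit:
        if events:  # unknown plan: regenerate outlier gene models de novo
            hapl_b.genes = [g for g in hapl_b.genes
                            if not (g.chrom == boc and g.start >= ostart)]
            gid = 0
            for s, e, strand in _sample_gene_intervals(
                    rng, 50, len(s_b) - 50, config.gene_density_outlier):
                gid += 1
                hapl_b.genes.append(GeneModel(f"haplB_g{gid:04d}", boc,
                                              ostart + s, ostart + e, strand))
    else:
        _lift_boc_genes(hapl_b, config, ostart, la, kept, s_b, rng)
    _fill_cds(hapl_a)
    _fill_cds(hapl_b)
    hapl_b.validate()

    truth = TruthSet(events=list(events))
    truth.regions["boc_outlier"] = {
        "haplA": (boc, ostart, length),
        "haplB": (boc, ostart, ostart + lb_realized),
    }
    truth.regions["boc_kept_segments"] = list(kept)
    return hapl_a, hapl_b, truth


def _boc_event_plan(rng, s_a, kept, config):
    """Right-to-left event series: replace spans between retained segments
    with novel outlier-composition sequence scaled so the final region
    length approximates boc_region_len_B, mutate/inverted the retained
    segments, and duplicate the first retained segment into a span."""
    la = len(s_a)
    spans = []  # replaced spans, left to right
    cursor = 0
    for s, e, _inv in kept:
        spans.append((cursor, s))
        cursor = e
    spans.append((cursor, la))
    kept_total = sum(e - s for s, e, _ in kept)
    dup_src = kept[0]
    dup_len = dup_src[1] - dup_src[0]
    new_total = config.boc_region_len_B - kept_total - dup_len
    old_total = sum(e - s for s, e in spans)
    scale = new_total / max(old_total, 1)
    new_seqs = {}
    for s, e in spans:
        new_seqs[(s, e)] = random_seq(rng, max(1, int((e - s) * scale)),
                                      config.outlier_gc)
    # apply strictly right-to-left so recorded coordinates stay valid
    items = sorted(
        [("span", s, e) for s, e in spans]
        + [("kept", s, e, inv) for s, e, inv in kept],
        key=lambda t: -t[1])
    dup_into = spans[min(1, len(spans) - 1)]
    events: list = []
    for item in items:
        if item[0] == "span":
            _, s, e = item
            events.append(("replace", s, e, new_seqs[(s, e)]))
            if (s, e) == dup_into:
                at = s + len(new_seqs[(s, e)]) // 2
                events.append(("duplicate", dup_src[0], dup_src[1], at))
        else:
            _, s, e, inv = item
            mutated, _ = _mutate_str(rng, s_a[s:e], config.boc_kept_divergence)
            events.append(("replace", s, e, mutated))
            if inv:
                events.append(("invert", s, e))
    return events


def _clone_assembly(asm: GenomeAssembly, strain_id: str) -> GenomeAssembly:
    return GenomeAssembly(
        strain_id,
        list(asm.chromosomes),
        [dc_replace(g) for g in asm.genes],
    )


def _lift_boc_genes(hapl_b, config, ostart, la, kept, s_b, rng):
    """Rebuild haplotype-B gene models over the outlier region: retained
    segments keep (remapped) ancestral genes, replaced spans get novel
    genes at outlier density."""
    boc = config.boc_chrom
    # final layout offsets of retained segments within s_b; mirrors the
    # scaled span lengths used in the event plan
    offsets = {}
    prev = 0
    spans = []
    for s, e, _inv in kept:
        spans.append((prev, s))
        prev = e
    spans.append((prev, la))
    kept_total = sum(e - s for s, e, _ in kept)
    dup_len = kept[0][1] - kept[0][0]
    new_total = config.boc_region_len_B - kept_total - dup_len
    old_total = sum(e - s for s, e in spans)
    scale = new_total / max(old_total, 1)
    cursor = 0
    for i, (s, e) in enumerate(spans):
        span_new = max(1, int((e - s) * scale))
        if i == min(1, len(spans) - 1):
            span_new += dup_len  # duplicated copy sits inside this span
        cursor += span_new
        if i < len(kept):
            ks, ke, inv = kept[i]
            offsets[(ks, ke)] = (cursor, inv)
            cursor += ke - ks

    old_genes = [g for g in hapl_b.genes if g.chrom == boc and g.start >= ostart]
    keep_ids = set()
    new_models = []
    for g in old_genes:
        gs, ge = g.start - ostart, g.end - ostart
        for (ks, ke, inv) in kept:
            if ks <= gs and ge <= ke:
                off, _ = offsets[(ks, ke)]
                if inv:
                    ns = off + (ke - ge)
                    strand = "-" if g.strand == "+" else "+"
                else:
                    ns = off + (gs - ks)
                    strand = g.strand
                new_models.append(GeneModel(g.gene_id, boc, ostart + ns,
                                            ostart + ns + (ge - gs), strand))
                keep_ids.add(g.gene_id)
                break
    hapl_b.genes = [g for g in hapl_b.genes
                    if not (g.chrom == boc and g.start >= ostart)]
    hapl_b.genes.extend(new_models)
    # novel genes on the replaced spans
    covered = sorted((off, off + (ke - ks)) for (ks, ke), (off, _i) in
                     [(k[:2], offsets[k[:2]]) for k in kept])
    gid = 0
    prev_end = 0
    free = []
    for s, e in covered + [(len(s_b), len(s_b))]:
        if s > prev_end:
            free.append((prev_end, s))
        prev_end = max(prev_end, e)
    for fs, fe in free:
        for s, e, strand in _sample_gene_intervals(
                rng, fs + 50, fe - 50, config.gene_density_outlier):
            gid += 1
            hapl_b.genes.append(GeneModel(f"haplB_g{gid:04d}", boc,
                                          ostart + s, ostart + e, strand))
    hapl_b.genes.sort(key=lambda g: (g.chrom, g.start))


# ---------------------------------------------------------------------------
# strain evolution (SNPs + structural variants)
# ---------------------------------------------------------------------------

def _sample_svs(rng, config, chrom_lens, exclude_regions, sv_counts):
    """Place the configured SV counts without overlap (bounded retries)."""
    blocked: dict[str, list[tuple[int, int]]] = {
        c: list(exclude_regions.get(c, [])) for c in chrom_lens}
    names = list(chrom_lens)
    weights = np.array([chrom_lens[c] for c in names], dtype=float)
    weights /= weights.sum()
    ops: dict[str, list] = {c: [] for c in names}

    def conflict(chrom, s, e):
        return any(s < be + 100 and bs - 100 < e for bs, be in blocked[chrom])

    for sv_type in sorted(sv_counts):
        lo, hi = config.sv_len_ranges.get(sv_type, (1_000, 10_000))
        for i in range(sv_counts[sv_type]):
            placed = False
            for _try in range(100):
                chrom = names[int(rng.choice(len(names), p=weights))]
                size = int(math.exp(rng.uniform(math.log(lo), math.log(hi))))
                cl = chrom_lens[chrom]
                if cl < size + 2_000:
                    continue
                s = int(rng.integers(1_000, cl - size - 1_000))
                e = s + size
                if conflict(chrom, s, e):
                    continue
                if sv_type == "TRANS":
                    p = int(rng.integers(1_000, cl - 1_000))
                    if conflict(chrom, p, p + 1) or s - 1000 <= p <= e + 1000:
                        continue
                    blocked[chrom] += [(s, e), (p, p + 1)]
                    ops[chrom].append(("TRANS", s, e, p))
                elif sv_type == "INS":
                    seq = random_seq(rng, size, config.genome_gc)
                    blocked[chrom].append((s, s + 1))
                    ops[chrom].append(("INS", s, s, seq))
                else:
                    blocked[chrom].append((s, e))
                    ops[chrom].append((sv_type, s, e))
                placed = True
                break
            if not placed:
                raise SimulationError(
                    f"could not place {sv_type} #{i + 1} without overlap")
    for c in ops:
        ops[c].sort(key=lambda op: op[1])
    return ops


def apply_sv_ops(parent_seq: str, ops: list):
    """Apply non-overlapping parent-frame SV operations to one chromosome.

    Returns (child_seq, segment_map, sv_rows) where segment_map is a list
    of (parent_start, parent_end, child_start, strand) identity pieces and
    sv_rows are (type, parent_start, parent_end, child_start, child_end).
    """
    # expand TRANS into a linked removal + insertion
    atoms = []
    for op in ops:
        if op[0] == "TRANS":
            _, s, e, p = op
            atoms.append(("TDEL", s, e, None))
            atoms.append(("TINS", p, p, (s, e)))
        elif op[0] == "INS":
            atoms.append(("INS", op[1], op[1], op[3]))
        else:
            atoms.append((op[0], op[1], op[2], None))
    atoms.sort(key=lambda a: (a[1], a[2]))
    out: list[str] = []
    segmap: list[tuple[int, int, int, str]] = []
    rows = []
    cursor = 0
    child = 0

    def emit(ps, pe):
        nonlocal child
        if pe > ps:
            out.append(parent_seq[ps:pe])
            segmap.append((ps, pe, child, "+"))
            child += pe - ps

    for kind, s, e, payload in atoms:
        emit(cursor, s)
        if kind == "DEL":
            rows.append(("DEL", s, e, child, child))
            cursor = e
        elif kind == "INS":
            rows.append(("INS", s, s, child, child + len(payload)))
            out.append(payload)
            child += len(payload)
            cursor = s
        elif kind == "INV":
            seg = revcomp(parent_seq[s:e])
            rows.append(("INV", s, e, child, child + (e - s)))
            out.append(seg)
            segmap.append((s, e, child, "-"))
            child += e - s
            cursor = e
        elif kind == "DUP":
            emit(s, e)
            seg = parent_seq[s:e]
            rows.append(("DUP", s, e, child, child + (e - s)))
            out.append(seg)
            child += e - s
            cursor = e
        elif kind == "TDEL":
            rows.append(("TRANS_SRC", s, e, child, child))
            cursor = e
        elif kind == "TINS":
            src_s, src_e = payload
            seg = parent_seq[src_s:src_e]
            rows.append(("TRANS", src_s, src_e, child, child + len(seg)))
            out.append(seg)
            segmap.append((src_s, src_e, child, "+"))
            child += len(seg)
            cursor = s
    emit(cursor, len(parent_seq))
    return "".join(out), segmap, rows


def _map_point(segmap, p):
    for ps, pe, cs, strand in segmap:
        if ps <= p < pe:
            if strand == "+":
                return cs + (p - ps)
            return cs + (pe - 1 - p)
    return None


def _map_interval(segmap, s, e):
    """Map [s,e) through a single identity segment; None if split."""
    for ps, pe, cs, strand in segmap:
        if ps <= s and e <= pe:
            if strand == "+":
                return cs + (s - ps), cs + (e - ps), False
            return cs + (pe - e), cs + (pe - s), True
    return None


def evolve_strain(
    parent: GenomeAssembly,
    config: SimConfig,
    seed: int,
    strain_id: str | None = None,
    snp_rate: float | None = None,
    sv_counts: dict | None = None,
    exclude_regions: dict | None = None,
) -> tuple[GenomeAssembly, TruthSet]:
    """One generation of strain-level evolution.

    Applies Poisson-distributed substitutions at ``snp_rate`` per bp and
    the configured genome-wide SV counts (placed without overlap, 100
    retries per SV). Gene models are lifted over: genes destroyed or
    disrupted by an SV are dropped and recorded, genes inside inversions
    flip strand, genes inside duplications gain a copy, genes inside
    translocated segments move. Truth lists every SNP and SV with
    coordinates in both parent and child frames. ``exclude_regions``
    (chrom -> intervals) bars SV placement, not substitutions.
    """
    rng = np.random.default_rng([config.seed, 2, seed])
    snp_rate = config.snp_rate if snp_rate is None else snp_rate
    sv_counts = dict(config.sv_counts if sv_counts is None else sv_counts)
    chrom_lens = {n: len(s) for n, s in parent.chromosomes}
    ops = _sample_svs(rng, config, chrom_lens, exclude_regions or {}, sv_counts)
    truth = TruthSet(sv_ops=ops)
    child_chroms: list[tuple[str, str]] = []
    segmaps: dict[str, list] = {}
    for name, seq in parent.chromosomes:
        child_seq, segmap, rows = apply_sv_ops(seq, ops.get(name, []))
        truth.svs.extend((t, name, ps, pe, cs, ce) for t, ps, pe, cs, ce in rows)
        child_chroms.append((name, child_seq))
        segmaps[name] = segmap

    # substitutions on parent coordinates outside SV footprints
    child_seqs = {n: bytearray(s.encode("ascii")) for n, s in child_chroms}
    for name, seq in parent.chromosomes:
        n = len(seq)
        count = min(rng.poisson(snp_rate * n), n)
        if count == 0:
            continue
        pos = np.sort(rng.choice(n, size=count, replace=False))
        blocked = [(op[1], op[2] if op[2] > op[1] else op[1] + 1)
                   for op in ops.get(name, [])]
        shifts = rng.integers(1, 4, size=count)
        order = b"ACGT"
        arr = child_seqs[name]
        for p, sh in zip(pos.tolist(), shifts.tolist()):
            if any(bs <= p < be for bs, be in blocked):
                continue
            cp = _map_point(segmaps[name], p)
            if cp is None:
                continue
            ref = seq[p]
            alt = chr(order[(order.index(ord(ref)) + sh) % 4])
            arr[cp] = ord(alt)
            truth.snps.append((name, int(p), int(cp), ref, alt))
    child_chroms = [(n, child_seqs[n].decode("ascii")) for n, _ in child_chroms]

    genes = _lift_genes(parent.genes, ops, segmaps, truth)
    child = GenomeAssembly(
        strain_id or f"{parent.strain_id}_s{seed}", child_chroms, genes)
    _fill_cds(child)
    child.validate()
    return child, truth


def _lift_genes(parent_genes, ops, segmaps, truth):
    out = []
    for g in parent_genes:
        chrom_ops = ops.get(g.chrom, [])
        segmap = segmaps[g.chrom]
        deleted = any(op[0] == "DEL" and op[1] <= g.start and g.end <= op[2]
                      for op in chrom_ops)
        if deleted:
            truth.dropped_genes.append((g.gene_id, "deleted"))
            continue
        partial = any(
            op[0] in ("DEL", "INV", "DUP", "TRANS")
            and op[1] < g.end and g.start < (op[2] if op[2] > op[1] else op[1] + 1)
            and not (op[1] <= g.start and g.end <= op[2])
            for op in chrom_ops)
        if partial:
            truth.dropped_genes.append((g.gene_id, "disrupted"))
            continue
        mapped = _map_interval(segmap, g.start, g.end)
        if mapped is None:
            truth.dropped_genes.append((g.gene_id, "unmapped"))
            continue
        cs, ce, flipped = mapped
        strand = g.strand if not flipped else ("-" if g.strand == "+" else "+")
        out.append(GeneModel(g.gene_id, g.chrom, cs, ce, strand))
        # a gene fully inside a duplicated segment gains a second copy
        for op in chrom_ops:
            if op[0] == "DUP" and op[1] <= g.start and g.end <= op[2]:
                row = next(r for r in truth.svs
                           if r[0] == "DUP" and r[1] == g.chrom
                           and r[2] == op[1] and r[3] == op[2])
                copy_start = row[4] + (g.start - op[1])
                out.append(GeneModel(g.gene_id + "_d", g.chrom, copy_start,
                                     copy_start + g.length(), g.strand))
    out.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return out


def replay_evolution(parent: GenomeAssembly, truth: TruthSet) -> GenomeAssembly:
    """Reconstruct a child's chromosome sequences from its truth tables."""
    chroms = []
    for name, seq in parent.chromosomes:
        child_seq, segmap, _ = apply_sv_ops(seq, truth.sv_ops.get(name, []))
        arr = bytearray(child_seq.encode("ascii"))
        for c, _pp, cp, _ref, alt in truth.snps:
            if c == name:
                arr[cp] = ord(alt)
        chroms.append((name, arr.decode("ascii")))
    return GenomeAssembly(parent.strain_id + "_replay", chroms, [])


# ---------------------------------------------------------------------------
# SOC architecture
# ---------------------------------------------------------------------------

@dataclass
class SocBlock:
    block_id: str
    seq: str
    genes: list[tuple[int, int, str]]  # block-relative intervals


def make_soc_pool(config: SimConfig, rng: np.random.Generator) -> tuple[SocBlock, list[SocBlock]]:
    """Shared SOC building material: one conserved distal core block plus a
    pool of exchangeable blocks with heavy-tailed sizes. Each block carries
    its own gene complement so shared blocks imply shared gene clusters."""
    def block(bid, length):
        seq = random_seq(rng, length, config.genome_gc)
        genes = _sample_gene_intervals(rng, 100, length - 100,
                                       config.gene_density_normal)
        return SocBlock(bid, seq, genes)

    core = block("core", config.soc_core_len)
    pool = []
    for i in range(config.soc_pool_size):
        length = int(np.clip(rng.lognormal(math.log(9_000), 0.9), 2_000, 45_000))
        pool.append(block(f"pool{i:02d}", length))
    return core, pool


def build_soc_chromosome(
    core: SocBlock,
    pool: list[SocBlock],
    include_ids: list[str],
    rng: np.random.Generator,
    soc_len_range: tuple[int, int] | None = None,
) -> tuple[str, list[GeneModel], list[tuple[str, int, int, str]]]:
    """Concatenate a per-strain SOC: selected pool blocks in shuffled order
    and orientation, then the conserved core distally. Returns the
    sequence, gene models (chrom name left blank) and block placements
    (block_id, start, end, orientation)."""
    chosen = [b for b in pool if b.block_id in set(include_ids)]
    order = rng.permutation(len(chosen))
    placements = []
    parts = []
    genes: list[GeneModel] = []
    cursor = 0

    def place(blk: SocBlock, orient: str):
        nonlocal cursor
        seq = blk.seq if orient == "+" else revcomp(blk.seq)
        parts.append(seq)
        placements.append((blk.block_id, cursor, cursor + len(seq), orient))
        for gi, (gs, ge, gstrand) in enumerate(blk.genes):
            if orient == "+":
                s, e, st = cursor + gs, cursor + ge, gstrand
            else:
                s = cursor + len(seq) - ge
                e = cursor + len(seq) - gs
                st = "-" if gstrand == "+" else "+"
            genes.append(GeneModel(f"{blk.block_id}_g{gi:02d}", "", s, e, st))
        cursor += len(seq)

    # a single-block pool admits no architectural diversity: keep the
    # degenerate case deterministic so such SOCs are byte-identical
    shuffle = len(pool) > 1
    for idx in order.tolist():
        orient = ("+" if rng.random() < 0.5 else "-") if shuffle else "+"
        place(chosen[idx], orient)
    place(core, "+")
    seq = "".join(parts)
    if soc_len_range is not None:
        lo, hi = soc_len_range
        if not lo <= len(seq) <= hi:
            raise ConfigError(
                f"SOC length {len(seq)} outside range {soc_len_range}")
    return seq, genes, placements


def _select_soc_blocks(config, pool, rng):
    lo, hi = config.soc_len_range
    core_len = config.soc_core_len
    if core_len > hi:
        raise ConfigError("SOC core longer than soc_len_range maximum")
    if len(pool) == 1:
        total = core_len + len(pool[0].seq)
        if not lo <= total <= hi:
            raise ConfigError(
                f"SOC length {total} outside range {config.soc_len_range}")
        return [pool[0].block_id]
    for _try in range(200):
        chosen = [b for b in pool if rng.random() < config.soc_block_prob]
        total = core_len + sum(len(b.seq) for b in chosen)
        while total > hi and chosen:
            drop = chosen.pop(int(rng.integers(len(chosen))))
            total -= len(drop.seq)
        if total < lo:
            extras = [b for b in pool if b not in chosen]
            rng.shuffle(extras)
            for b in extras:
                if total + len(b.seq) <= hi:
                    chosen.append(b)
                    total += len(b.seq)
                if total >= lo:
                    break
        if lo <= total <= hi:
            return [b.block_id for b in chosen]
    raise ConfigError("cannot assemble a SOC inside soc_len_range")


# ---------------------------------------------------------------------------
# population assembly
# ---------------------------------------------------------------------------

@dataclass
class ClusterSpec:
    """Designed gene families layered onto the panel's BOC outlier region:
    ``n_core`` in every strain, ``n_clade`` split between the two primary
    clades, ``n_private`` each in a single strain."""

    n_core: int = 5
    n_clade: int = 5
    n_private: int = 5
    gene_len: int = 900


def _balanced_split(items: list) -> tuple[list, list]:
    half = (len(items) + 1) // 2
    return items[:half], items[half:]


def _genealogy_newick(items: list[str]) -> str:
    if len(items) == 1:
        return items[0]
    a, b = _balanced_split(items)
    return f"({_genealogy_newick(a)},{_genealogy_newick(b)})"


def _restricted_newick(items: list[str], keep: set[str]) -> str | None:
    if len(items) == 1:
        return items[0] if items[0] in keep else None
    a, b = _balanced_split(items)
    ra, rb = _restricted_newick(a, keep), _restricted_newick(b, keep)
    if ra and rb:
        return f"({ra},{rb})"
    return ra or rb


def assemble_population(
    config: SimConfig,
    n_strains_per_haplotype: tuple[int, int] = (2, 2),
    seed: int = 0,
    cluster_spec: ClusterSpec | None = None,
    leaf_sv_counts: dict | None = None,
    leaf_snp_rate: float | None = None,
    branch_snp_rate: float | None = None,
) -> tuple[list[GenomeAssembly], TruthSet]:
    """Emit a strain panel descended from the two BOC haplotype ancestors.

    Strains evolve along a balanced binary genealogy (substitutions per
    internal branch, substitutions plus SVs at the leaves, SVs barred from
    the outlier region and the SOC). BOC haplotypes are assigned
    alternately along the leaf order so haplotype is orthogonal to the
    first genealogy split; the haplotype-B outlier evolves in parallel
    along the same genealogy and replaces the backbone outlier in B
    strains. Each strain's SOC is rebuilt from the shared block pool
    behind the conserved distal core. ``cluster_spec`` appends designed
    core/clade-specific/private gene families to the outlier region.
    Truth records SNP/SV tables per strain, SOC block carriers, the design
    matrix, per-strain outlier intervals and both reference topologies
    (genome-wide genealogy; haplotype split for the BOC region).
    """
    config.validate()
    n_a, n_b = n_strains_per_haplotype
    n = n_a + n_b
    if n < 1:
        raise ConfigError("need at least one strain")
    rng = np.random.default_rng([config.seed, 3, seed])
    ancestor, _ = build_ancestor(config)
    hapl_a, hapl_b, truth_ab = derive_boc_haplotypes(ancestor, config)
    boc, soc = config.boc_chrom, config.soc_chrom
    _, b_out_s, b_out_e = truth_ab.regions["boc_outlier"]["haplB"]
    b_outlier_seq = hapl_b.seq(boc)[b_out_s:]
    b_outlier_genes = [g for g in hapl_b.genes
                       if g.chrom == boc and g.start >= b_out_s]
    la = config.boc_region_len_A

    strain_ids = [f"S{i + 1:02d}" for i in range(n)]
    haps = {}
    remaining = {"A": n_a, "B": n_b}
    toggle = "A"
    for sid in strain_ids:
        pick = toggle if remaining[toggle] > 0 else ("B" if toggle == "A" else "A")
        haps[sid] = pick
        remaining[pick] -= 1
        toggle = "B" if toggle == "A" else "A"

    branch_rate = config.snp_rate if branch_snp_rate is None else branch_snp_rate
    truth = TruthSet(haplotypes=dict(haps))
    truth.topologies["genome"] = _genealogy_newick(strain_ids) + ";"
    a_set = {s for s in strain_ids if haps[s] == "A"}
    b_set = set(strain_ids) - a_set
    if a_set and b_set:
        truth.topologies["boc"] = "({},{});".format(
            _restricted_newick(strain_ids, a_set),
            _restricted_newick(strain_ids, b_set))
    else:
        truth.topologies["boc"] = truth.topologies["genome"]

    core_blk, pool = make_soc_pool(config, rng)
    leaves: dict[str, tuple[GenomeAssembly, str]] = {}

    def descend(items, backbone, b_out):
        if len(items) == 1:
            leaves[items[0]] = (backbone, b_out)
            return
        for part in _balanced_split(items):
            nb = _clone_assembly(backbone, backbone.strain_id)
            mutated = []
            for cname, cseq in nb.chromosomes:
                mseq, _ = _mutate_str(rng, cseq, branch_rate)
                mutated.append((cname, mseq))
            nb.chromosomes = mutated
            nbo, _ = _mutate_str(rng, b_out, branch_rate)
            descend(part, nb, nbo)

    root = _clone_assembly(hapl_a, "backbone")
    descend(strain_ids, root, b_outlier_seq)

    strains: list[GenomeAssembly] = []
    soc_placements: dict[str, list] = {}
    for idx, sid in enumerate(strain_ids):
        backbone, b_out = leaves[sid]
        genome = _clone_assembly(backbone, sid)
        if haps[sid] == "B":
            chrom = genome.seq(boc)
            ostart = len(chrom) - la
            genome.set_seq(boc, chrom[:ostart] + b_out)
            genome.genes = [g for g in genome.genes
                            if not (g.chrom == boc and g.start >= ostart)]
            for g in b_outlier_genes:
                genome.genes.append(GeneModel(
                    f"{g.gene_id}", boc,
                    ostart + (g.start - b_out_s),
                    ostart + (g.end - b_out_s), g.strand))
        _fill_cds(genome)
        out_len = la if haps[sid] == "A" else len(b_out)
        boc_len = len(genome.seq(boc))
        exclude = {
            boc: [(boc_len - out_len, boc_len)],
            soc: [(0, len(genome.seq(soc)))],
        }
        child, t = evolve_strain(
            genome, config, seed=1_000 + idx, strain_id=sid,
            snp_rate=config.snp_rate if leaf_snp_rate is None else leaf_snp_rate,
            sv_counts=leaf_sv_counts, exclude_regions=exclude)
        # rebuild the SOC from the shared pool
        include = _select_soc_blocks(config, pool, rng)
        soc_seq, soc_genes, placements = build_soc_chromosome(
            core_blk, pool, include, rng, config.soc_len_range)
        child.set_seq(soc, soc_seq)
        child.genes = [g for g in child.genes if g.chrom != soc]
        for g in soc_genes:
            g.chrom = soc
            g.gene_id = f"{sid}_{g.gene_id}"
            child.genes.append(g)
        soc_placements[sid] = placements
        boc_len = len(child.seq(boc))
        truth.regions.setdefault("boc_outlier", {})[sid] = (
            boc, boc_len - out_len, boc_len)
        truth.strain_truths[sid] = t
        _fill_cds(child)
        strains.append(child)

    block_carriers: dict[str, list] = {}
    for sid, placements in soc_placements.items():
        for bid, s, e, orient in placements:
            block_carriers.setdefault(bid, []).append((sid, s, e, orient))
    truth.soc_blocks = [(bid, rows) for bid, rows in sorted(block_carriers.items())]

    if cluster_spec is not None:
        _insert_designed_families(strains, truth, cluster_spec, haps, rng,
                                  config)
    for s in strains:
        s.validate()
    return strains, truth


def _insert_designed_families(strains, truth, spec, haps, rng, config):
    """Append designed gene families distally on the BOC outlier region so
    carrier strains hold byte-identical copies."""
    boc = config.boc_chrom
    ids = [s.strain_id for s in strains]
    clade1, clade2 = _balanced_split(ids)
    fams: list[tuple[str, list[str]]] = []
    for i in range(spec.n_core):
        fams.append((f"famcore{i:02d}", list(ids)))
    for i in range(spec.n_clade):
        carriers = clade1 if i % 2 == 0 else clade2
        fams.append((f"famclade{i:02d}", list(carriers)))
    for i in range(spec.n_private):
        fams.append((f"fampriv{i:02d}", [ids[i % len(ids)]]))
    spacer_len = 150
    fam_seqs = {fid: random_seq(rng, spec.gene_len, config.genome_gc)
                for fid, _ in fams}
    by_id = {s.strain_id: s for s in strains}
    for fid, carriers in fams:
        truth.cluster_design[fid] = sorted(carriers)
        for sid in carriers:
            asm = by_id[sid]
            chrom = asm.seq(boc)
            spacer = random_seq(rng, spacer_len, config.outlier_gc)
            start = len(chrom) + spacer_len
            asm.set_seq(boc, chrom + spacer + fam_seqs[fid])
            asm.genes.append(GeneModel(f"{fid}|{sid}", boc, start,
                                       start + spec.gene_len, "+",
                                       fam_seqs[fid]))
            c, s0, _e = truth.regions["boc_outlier"][sid]
            truth.regions["boc_outlier"][sid] = (c, s0, len(asm.seq(boc)))


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

@dataclass
class SimRead:
    read_id: str
    seq: str


def simulate_reads(
    mixture: list[tuple[GenomeAssembly, float]],
    n_reads: int,
    read_len: int = 100,
    err_rate: float = 0.005,
    seed: int = 0,
) -> tuple[list[SimRead], TruthSet]:
    """Draw reads from a weighted strain mixture.

    Genomes contribute proportionally to weight x genome length, start
    positions are uniform, strands random, and per-base substitution
    errors occur at ``err_rate``. Truth records each read's origin strain,
    chromosome, position and strand. Deterministic per seed.
    """
    if not mixture or any(w < 0 for _, w in mixture):
        raise ConfigError("weights must be non-negative")
    if sum(w for _, w in mixture) <= 0:
        raise ConfigError("weights must sum to a positive value")
    shortest = min(len(s) for asm, _ in mixture for _, s in asm.chromosomes)
    if read_len > shortest:
        raise SimulationError(
            f"read_len {read_len} exceeds shortest chromosome ({shortest} bp)")
    rng = np.random.default_rng([seed, 11])
    weights = np.array([w * asm.total_length() for asm, w in mixture])
    probs = weights / weights.sum()
    counts = rng.multinomial(n_reads, probs)
    reads: list[SimRead] = []
    truth = TruthSet()
    ridx = 0
    sub_shift = None
    for (asm, _w), count in zip(mixture, counts):
        if count == 0:
            continue
        chrom_names = [n for n, _ in asm.chromosomes]
        starts_per = np.array([len(s) - read_len + 1 for _, s in asm.chromosomes])
        cum = np.concatenate([[0], np.cumsum(starts_per)])
        offs = rng.integers(0, cum[-1], size=count)
        chrom_idx = np.searchsorted(cum, offs, side="right") - 1
        pos = offs - cum[chrom_idx]
        strands = rng.integers(0, 2, size=count)
        err_mask = rng.random((count, read_len)) < err_rate
        err_shift = rng.integers(1, 4, size=(count, read_len))
        order = b"ACGT"
        lut = {ord(b): i for i, b in enumerate("ACGT")}
        for t in range(count):
            ci = int(chrom_idx[t])
            p = int(pos[t])
            s = asm.chromosomes[ci][1][p:p + read_len]
            if strands[t]:
                s = revcomp(s)
            if err_mask[t].any():
                arr = bytearray(s.encode("ascii"))
                for e_pos in np.nonzero(err_mask[t])[0].tolist():
                    base = lut.get(arr[e_pos])
                    if base is None:
                        continue
                    arr[e_pos] = order[(base + int(err_shift[t, e_pos])) % 4]
                s = arr.decode("ascii")
            rid = f"r{ridx:07d}"
            reads.append(SimRead(rid, s))
            truth.mixture_origins.append(
                (rid, asm.strain_id, chrom_names[ci], p,
                 "-" if strands[t] else "+"))
            ridx += 1
    return reads, truth
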