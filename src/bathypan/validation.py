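"""Truth-driven validation experiments at the simulated study conditions.

Each function sets up a seeded synthetic scenario with a known truth,
runs the relevant pipeline stages from scratch, and returns measured
recovery statistics as plain numbers. The experiments double as the
package's acceptance checks and as end-to-end regression tests:
maximal-exact-match discovery against a brute-force enumerator,
structural-variant and outlier-region recovery from assembly alignment,
the sliding-window divergence statistic on an implanted
low-polymorphism region, haplotype-ratio recovery from read mixtures
under the full filter stack, designed-occupancy recovery, the
clade-versus-haplotype tree contrast, recruitment filter boundary
behaviour, and determinism/conservation checks.

Problem sizes are desk-scale: chromosome-scale sequences of a few
hundred kb to 2 Mb and panels of 8-12 strains, with generator
composition parameters (GC, coding density, outlier-region sizes,
SNP rates) at the study conditions.
"""

from __future__ import annotations

import numpy as np

from . import anchor_align as aa
from . import divergence as dv
from . import pangenome as pg
from . import phylo as ph
from . import recruit as rc
from . import simgenome as sg


# ---------------------------------------------------------------------------
# shared scenario builders
# ---------------------------------------------------------------------------

def boc_pair_config(seed: int) -> sg.SimConfig:
    """650-kb BOC chromosome (400-kb distal outlier + 250-kb flank) plus
    two companion chromosomes; composition at study conditions."""
    return sg.SimConfig(
        seed=seed, n_chromosomes=3,
        chrom_lengths=[350_000, 650_000, 140_000],
        boc_chrom="chr02", soc_chrom="chr03", snp_rate=0.002)


def align_chromosome(ref_seq: str, qry_seq: str, chrom: str = "chr"):
    """find_mems -> chain -> filter -> classify for one chromosome pair."""
    anchors = aa.find_mems(ref_seq, qry_seq, 20)
    blocks = aa.chain_and_extend(anchors, ref_seq, qry_seq,
                                 ref_chrom=chrom, qry_chrom=chrom)
    blocks = aa.filter_blocks(blocks)
    return aa.classify_blocks(blocks, ref_len=len(ref_seq))


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    ov = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    if ov == 0:
        return 0.0
    return min(ov / (a[1] - a[0]), ov / (b[1] - b[0]))


# ---------------------------------------------------------------------------
# 1. MEM discovery vs brute force
# ---------------------------------------------------------------------------

def _brute_mems(ref: str, qry: str, k: int) -> set:
    """Quadratic maximal-common-substring enumeration, both strands."""
    out = set()

    def one(r: str, q: str, minus: bool):
        ra = np.frombuffer(r.encode(), np.uint8)
        qa = np.frombuffer(q.encode(), np.uint8)
        n, m = ra.size, qa.size
        if n == 0 or m == 0:
            return
        L = np.zeros((n + 1, m + 1), dtype=np.int32)
        for i in range(n - 1, -1, -1):
            L[i, :m] = np.where(ra[i] == qa, L[i + 1, 1 : m + 1] + 1, 0)
        left_ok = np.ones((n, m), dtype=bool)
        left_ok[1:, 1:] = ra[:-1, None] != qa[None, :-1]
        ii, jj = np.nonzero((L[:n, :m] >= k) & left_ok)
        for i, j in zip(ii.tolist(), jj.tolist()):
            length = int(L[i, j])
            if minus:
                out.add((i, m - j - length, length, "-"))
            else:
                out.add((i, j, length, "+"))

    one(ref, qry, False)
    one(ref, aa.revcomp(qry), True)
    return out


def mem_brute_force_agreement(seed: int, n_pairs: int = 200,
                              max_len: int = 2000) -> dict:
    """Fraction of random sequence pairs on which find_mems returns
    exactly the brute-force MEM set (both strands)."""
    rng = np.random.default_rng([seed, 41])
    bases = np.frombuffer(b"ACGT", np.uint8)
    agree = 0
    for _ in range(n_pairs):
        n = int(rng.integers(20, max_len + 1))
        m = int(rng.integers(20, max_len + 1))
        ref = bases[rng.integers(0, 4, n)].tobytes().decode()
        qry = bases[rng.integers(0, 4, m)].tobytes().decode()
        if rng.random() < 0.5 and n > 60:
            s = int(rng.integers(0, n - 50))
            seg = ref[s : s + int(rng.integers(20, 50))]
            if rng.random() < 0.5:
                seg = aa.revcomp(seg)
            cut = int(rng.integers(0, m))
            qry = qry[:cut] + seg + qry[cut:]
        k = int(rng.integers(8, 16))
        got = {(a.ref_pos, a.qry_pos, a.length, a.strand)
               for a in aa.find_mems(ref, qry, k)}
        agree += got == _brute_mems(ref, qry, k)
    return {"n_pairs": n_pairs, "agreement_rate": agree / n_pairs}


# ---------------------------------------------------------------------------
# 2. structural-variant recovery
# ---------------------------------------------------------------------------

def sv_recovery(seed: int, n_seeds: int = 5, min_recip: float = 0.90) -> dict:
    """On a 2-Mb chromosome carrying 10 inversions (5-50 kb), 5
    duplications and 5 deletions (>=1 kb), the fraction of truth SVs
    recovered with the correct type and >= 90% reciprocal overlap."""
    rates = []
    for i in range(n_seeds):
        cfg = sg.SimConfig(
            seed=seed * 100 + i, n_chromosomes=2,
            chrom_lengths=[2_000_000, 140_000],
            boc_chrom="chr01", soc_chrom="chr02", snp_rate=0.001,
            sv_counts={"INV": 10, "DEL": 5, "DUP": 5},
            sv_len_ranges={"INV": (5_000, 50_000), "DEL": (1_000, 10_000),
                           "DUP": (1_000, 10_000)})
        anc, _ = sg.build_ancestor(cfg)
        child, truth = sg.evolve_strain(anc, cfg, seed=1)
        ref, qry = anc.seq("chr01"), child.seq("chr01")
        blocks, _ = align_chromosome(ref, qry, "chr01")
        _snps, svs = dv.call_variants(blocks, {"chr01": ref},
                                      {"chr01": qry}, "child")
        truth_svs = [(t, ps, pe) for t, c, ps, pe, _cs, _ce in truth.svs
                     if t in ("INV", "DEL", "DUP") and c == "chr01"]
        hit = sum(
            any(sv.type == t and reciprocal_overlap(
                (ps, pe), (sv.ref_start, sv.ref_end)) >= min_recip
                for sv in svs)
            for t, ps, pe in truth_svs)
        rates.append(hit / len(truth_svs))
    return {"n_seeds": n_seeds, "recovery_rates": rates,
            "min_recovery": min(rates), "mean_recovery": float(np.mean(rates))}


# ---------------------------------------------------------------------------
# 3. outlier-region recovery
# ---------------------------------------------------------------------------

def outlier_recovery(seed: int) -> dict:
    """Simulated BOC haplotype pair: reciprocal overlap of the delimited
    outlier region with truth, and SYN coverage of the syntenic flank."""
    cfg = boc_pair_config(seed)
    anc, _ = sg.build_ancestor(cfg)
    hapl_a, hapl_b, truth = sg.derive_boc_haplotypes(anc, cfg)
    chrom = cfg.boc_chrom
    ref, qry = hapl_a.seq(chrom), hapl_b.seq(chrom)
    blocks, nonsyn = align_chromosome(ref, qry, chrom)
    _c, t_s, t_e = truth.regions["boc_outlier"]["haplA"]
    gc = dv.gc_profile(ref)
    region = dv.delimit_outlier_region(gc, nonsyn, chrom_len=len(ref))
    recip = reciprocal_overlap(region, (t_s, t_e)) if region else 0.0
    flank = (0, t_s)
    syn_cov = sum(
        max(0, min(b.ref_end, flank[1]) - max(b.ref_start, flank[0]))
        for b in blocks if b.class_label == "SYN") / (flank[1] - flank[0])
    uncovered = sum(min(e, t_e) - max(s, t_s)
                    for s, e in nonsyn if e > t_s and s < t_e)
    return {"reciprocal_overlap": recip,
            "flank_syn_coverage": syn_cov,
            "outlier_uncovered_fraction": uncovered / (t_e - t_s)}


# ---------------------------------------------------------------------------
# 4. reduced-polymorphism window statistic
# ---------------------------------------------------------------------------

def reduced_polymorphism_recovery(seed: int, n_seeds: int = 20,
                                  chrom_len: int = 1_000_000,
                                  region: tuple[int, int] = (400_000, 600_000),
                                  background_rate: float = 0.005,
                                  reduction: float = 10.0) -> dict:
    """An implanted 200-kb region with a 10x reduced SNP rate against a
    0.5% background: fraction of fully-contained 20-kb windows with
    divergence ratio < 1, and reciprocal truth overlap of the detected
    reduced-polymorphism interval, per seed."""
    succ = 0
    low_fracs, overlaps = [], []
    for i in range(n_seeds):
        rng = np.random.default_rng([seed, 51, i])
        records = []
        for lo, hi, rate in ((0, region[0], background_rate),
                             (region[0], region[1], background_rate / reduction),
                             (region[1], chrom_len, background_rate)):
            n = rng.poisson(rate * (hi - lo))
            for p in rng.integers(lo, hi, size=n).tolist():
                records.append(dv.SnpRecord("chr", int(p), "A", "C", "s"))
        windows = dv.window_divergence(records, {"chr": chrom_len},
                                       window=20_000, step=5_000,
                                       aligned_bp=chrom_len)
        inside = [w for w in windows
                  if w.start >= region[0] and w.end <= region[1]]
        low_frac = np.mean([w.ratio < 1 for w in inside])
        detected = dv.detect_reduced_polymorphism(windows)
        best = max((reciprocal_overlap((s, e), region)
                    for _c, s, e in detected), default=0.0)
        low_fracs.append(float(low_frac))
        overlaps.append(best)
        succ += (low_frac >= 0.8) and (best >= 0.8)
    return {"n_seeds": n_seeds, "n_success": succ,
            "mean_low_window_fraction": float(np.mean(low_fracs)),
            "mean_truth_overlap": float(np.mean(overlaps))}


# ---------------------------------------------------------------------------
# 5. haplotype-ratio recovery
# ---------------------------------------------------------------------------

def _ratio_setup(seed: int):
    # ~6-Mb genomes: outlier-region read depth stays low enough that
    # positional duplicate removal does not bias the count ratio
    cfg = sg.SimConfig(
        seed=seed, n_chromosomes=9,
        chrom_lengths=[750_000, 650_000] + [750_000] * 6 + [140_000],
        boc_chrom="chr02", soc_chrom="chr09", snp_rate=0.002)
    anc, _ = sg.build_ancestor(cfg)
    hapl_a, hapl_b, truth = sg.derive_boc_haplotypes(anc, cfg)
    strain_a, _ = sg.evolve_strain(hapl_a, cfg, seed=1, strain_id="strainA",
                                   sv_counts={})
    strain_b, _ = sg.evolve_strain(hapl_b, cfg, seed=2, strain_id="strainB",
                                   sv_counts={})
    _c, a_s, a_e = truth.regions["boc_outlier"]["haplA"]
    _c, b_s, b_e = truth.regions["boc_outlier"]["haplB"]
    region_a = ("BOC_A", hapl_a.seq(cfg.boc_chrom)[a_s:a_e])
    region_b = ("BOC_B", hapl_b.seq(cfg.boc_chrom)[b_s:b_e])
    return strain_a, strain_b, region_a, region_b


def ratio_recovery(seed: int, n_seeds: int = 20,
                   mixtures: tuple = (0.9, 0.7, 0.5),
                   n_reads: int = 50_000) -> dict:
    """Strain mixtures at known weights recruited against the two
    haplotype outlier references with the full filter stack: maximum
    absolute error of the length-normalised ratio estimate and Wilson-CI
    coverage counts per mixture."""
    strain_a, strain_b, region_a, region_b = _ratio_setup(seed)
    norm_lengths = rc.unique_region_lengths(region_a, region_b)
    errors, signed = [], []
    coverage = {w: 0 for w in mixtures}
    for mix_idx, w in enumerate(mixtures):
        for i in range(n_seeds):
            # structured entropy for independent replicate streams
            run_seed = int(np.random.SeedSequence(
                [seed, 5, mix_idx, i]).generate_state(1)[0] >> np.uint32(1))
            reads, _t = sg.simulate_reads(
                [(strain_a, w), (strain_b, 1 - w)], n_reads,
                read_len=100, err_rate=0.005, seed=run_seed)
            hr = rc.haplotype_ratio(reads, region_a, region_b,
                                    norm_lengths=norm_lengths)
            errors.append(abs(hr.ratio_a_norm - w))
            signed.append(hr.ratio_a_norm - w)
            if hr.ci_a_norm[0] <= w <= hr.ci_a_norm[1]:
                coverage[w] += 1
    return {"n_seeds": n_seeds, "mixtures": list(mixtures),
            "max_abs_error": float(max(errors)),
            "mean_abs_error": float(np.mean(errors)),
            "mean_signed_error": float(np.mean(signed)),
            "ci_coverage": {str(w): coverage[w] for w in mixtures},
            "min_ci_coverage": min(coverage.values())}


# ---------------------------------------------------------------------------
# 6. designed-occupancy recovery
# ---------------------------------------------------------------------------

def occupancy_recovery(seed: int) -> dict:
    """12-strain panel with 5 designed core, 5 clade-specific and 5
    private families: exact recovery of the design matrix and occupancy
    classes, and whether the dendrogram's first split separates the
    designed clades."""
    cfg = sg.SimConfig(
        seed=seed, n_chromosomes=4,
        chrom_lengths=[400_000, 650_000, 300_000, 140_000],
        boc_chrom="chr02", soc_chrom="chr04", snp_rate=0.002)
    strains, truth = sg.assemble_population(
        cfg, (12, 0), seed=seed, cluster_spec=sg.ClusterSpec(5, 5, 5))
    ids = [s.strain_id for s in strains]
    cds = []
    for s in strains:
        chrom, rs, _re = truth.regions["boc_outlier"][s.strain_id]
        cds.extend((s.strain_id, g.gene_id, g.cds_seq)
                   for g in s.genes_on(chrom) if g.start >= rs)
    clusters = pg.cluster_genes(cds)
    matrix = pg.build_presence_matrix(clusters, ids)
    cats = pg.classify_occupancy(matrix)
    fam_cluster: dict[str, set] = {}
    for cl in clusters:
        for strain, gid in cl.members:
            if gid.startswith("fam"):
                fam_cluster.setdefault(gid.split("|")[0], set()).add(
                    cl.cluster_id)
    expected = {"famcore": "core", "famclade": "shell", "fampriv": "rare"}
    matrix_exact = categories_exact = True
    for fam, carriers in truth.cluster_design.items():
        if len(fam_cluster.get(fam, ())) != 1:
            matrix_exact = categories_exact = False
            continue
        cid = next(iter(fam_cluster[fam]))
        present = set(matrix.matrix.index[matrix.matrix[cid] == 1])
        if present != set(carriers):
            matrix_exact = False
        want = next(v for k, v in expected.items() if fam.startswith(k))
        if cats[cid] != want:
            categories_exact = False
    dend = pg.strain_dendrogram(matrix)
    left, right = dend.first_split()
    half = (len(ids) + 1) // 2
    clades = {frozenset(ids[:half]), frozenset(ids[half:])}
    split_ok = {frozenset(left), frozenset(right)} == clades
    return {"matrix_exact": matrix_exact,
            "categories_exact": categories_exact,
            "first_split_separates_clades": split_ok}


# ---------------------------------------------------------------------------
# 7. clade-vs-haplotype tree contrast
# ---------------------------------------------------------------------------

def _region_tree(strains, truth, cfg, region: str, max_clusters: int):
    ids = [s.strain_id for s in strains]
    cds, seqs = [], {}
    for s in strains:
        chrom, rs, _re = truth.regions["boc_outlier"][s.strain_id]
        for g in s.genes:
            if g.chrom == cfg.soc_chrom:
                continue
            in_outlier = g.chrom == chrom and g.start >= rs
            if region == "boc" and not in_outlier:
                continue
            if region == "genome" and (in_outlier or g.chrom == chrom):
                continue  # genome tree: chromosomes away from the BOC
            cds.append((s.strain_id, g.gene_id, g.cds_seq))
            seqs[(s.strain_id, g.gene_id)] = g.cds_seq
    clusters = pg.cluster_genes(cds)
    shared = ph.shared_single_copy_clusters(clusters, ids, seqs,
                                            max_clusters=max_clusters)
    dm = ph.concat_distance_matrix(shared)
    return ph.nj_tree(dm), len(shared)


def haplotype_vs_clade_topology(seed: int, n_seeds: int = 10) -> dict:
    """Panels where BOC haplotype alternates across the clade structure:
    Robinson-Foulds distance of the genome-wide tree to the clade
    genealogy and of the BOC-region tree to the haplotype-grouped
    topology, per seed (0 = exact recovery of both groupings)."""
    rf_genome, rf_boc = [], []
    for i in range(n_seeds):
        cfg = boc_pair_config(seed * 100 + i)
        strains, truth = sg.assemble_population(cfg, (4, 4), seed=i)
        g_tree, _n = _region_tree(strains, truth, cfg, "genome", 40)
        b_tree, _n = _region_tree(strains, truth, cfg, "boc", 40)
        rf_genome.append(ph.robinson_foulds(
            g_tree, ph.from_newick(truth.topologies["genome"])))
        rf_boc.append(ph.robinson_foulds(
            b_tree, ph.from_newick(truth.topologies["boc"])))
    return {"n_seeds": n_seeds,
            "rf_genome": rf_genome, "rf_boc": rf_boc,
            "max_rf_genome": max(rf_genome), "max_rf_boc": max(rf_boc)}


# ---------------------------------------------------------------------------
# 8. recruitment filter boundaries
# ---------------------------------------------------------------------------

def _mk_result(read_id="r", **kw):
    base = dict(read_id=read_id, target_id="t", target_pos=0, strand="+",
                identity=1.0, aligned_fraction=1.0, unique=True,
                low_complexity_frac=0.0, high_complexity_frac=1.0,
                read_len=100)
    base.update(kw)
    return rc.MappingResult(**base)


def filter_boundary_behaviour(seed: int = 0) -> dict:
    """Each of the four thresholds (0.75 / 0.30 / 0.80 / 0.95) must flip a
    boundary-constructed read exactly at its stated inequality, and
    relaxing any threshold must be monotone in surviving count."""
    cases = [
        (dict(low_complexity_frac=0.75), True),
        (dict(low_complexity_frac=0.7501), False),
        (dict(high_complexity_frac=0.30), True),
        (dict(high_complexity_frac=0.2999), False),
        (dict(aligned_fraction=0.80), True),
        (dict(aligned_fraction=0.7999), False),
        (dict(identity=0.95), True),
        (dict(identity=0.9499), False),
    ]
    flips_ok = all(
        bool(rc.apply_filters([_mk_result(**kw)])) is kept
        for kw, kept in cases)
    rng = np.random.default_rng([seed, 61])
    results = [_mk_result(read_id=f"r{i}", target_pos=i,
                          identity=float(rng.uniform(0.9, 1.0)),
                          aligned_fraction=float(rng.uniform(0.7, 1.0)),
                          low_complexity_frac=float(rng.uniform(0, 1)),
                          high_complexity_frac=float(rng.uniform(0, 1)))
               for i in range(300)]
    base = len(rc.apply_filters(results))
    monotone = True
    for kw in (dict(low_max=0.9), dict(high_min=0.1), dict(cov_min=0.6),
               dict(id_min=0.9)):
        if len(rc.apply_filters(results, **kw)) < base:
            monotone = False
    return {"boundary_flips_ok": flips_ok, "relaxation_monotone": monotone}


# ---------------------------------------------------------------------------
# 9. determinism and conservation
# ---------------------------------------------------------------------------

def determinism_and_conservation(seed: int) -> dict:
    """Byte-determinism of every simulation stage under a fixed seed,
    window-count conservation at step = window, exact length-weighted
    ratio normalisation, and input-order invariance of gene clustering."""
    cfg = sg.SimConfig(
        seed=seed, n_chromosomes=3,
        chrom_lengths=[250_000, 650_000, 140_000],
        boc_chrom="chr02", soc_chrom="chr03", snp_rate=0.002)

    def build():
        strains, truth = sg.assemble_population(cfg, (2, 2), seed=seed)
        reads, rtruth = sg.simulate_reads([(strains[0], 1.0)], 2_000,
                                          100, 0.005, seed=seed)
        return strains, truth, reads

    s1, t1, r1 = build()
    s2, t2, r2 = build()
    byte_identical = (
        all(a.chromosomes == b.chromosomes for a, b in zip(s1, s2))
        and all([(g.gene_id, g.start, g.end, g.strand, g.cds_seq)
                 for g in a.genes] ==
                [(g.gene_id, g.start, g.end, g.strand, g.cds_seq)
                 for g in b.genes] for a, b in zip(s1, s2))
        and [(x.read_id, x.seq) for x in r1] == [(x.read_id, x.seq)
                                                 for x in r2]
        and t1.snps == t2.snps and t1.svs == t2.svs)

    rng = np.random.default_rng([seed, 71])
    chrom_len = 400_000
    records = [dv.SnpRecord("chr", int(p), "A", "C", "s")
               for p in rng.integers(0, chrom_len, size=1_500).tolist()]
    windows = dv.window_divergence(records, {"chr": chrom_len},
                                   window=20_000, step=20_000,
                                   aligned_bp=chrom_len)
    conserved = sum(w.n_variants for w in windows) == len(records)
    weighted = sum(w.density * (w.end - w.start) for w in windows)
    normalised = abs(weighted - len(records)) < 1e-6

    cds = []
    for s in s1:
        cds.extend((s.strain_id, g.gene_id, g.cds_seq)
                   for g in s.genes_on(cfg.boc_chrom))
    part1 = sorted(tuple(sorted(c.members)) for c in pg.cluster_genes(cds))
    perm = [cds[i] for i in rng.permutation(len(cds))]
    part2 = sorted(tuple(sorted(c.members)) for c in pg.cluster_genes(perm))
    return {"byte_identical": bool(byte_identical),
            "window_counts_conserved": bool(conserved),
            "ratio_normalisation_exact": bool(normalised),
            "clustering_order_invariant": part1 == part2}
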