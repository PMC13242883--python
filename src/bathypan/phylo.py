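"""Distance-based phylogenomics on shared single-copy gene clusters.

Per-gene p-distances (mismatched over ungapped columns of an affine-gap
global alignment) are combined into a column-weighted concatenated
distance matrix, trees are built with canonical neighbor joining
(deterministic tie-breaks, non-negative branch lengths), and per-branch
gene concordance factors report the percentage of decisive gene trees
containing each internal bipartition. This stands in, at desk scale, for
maximum-likelihood inference on a partitioned supermatrix: the panel
conclusions tested here are topological groupings, which neighbor
joining recovers for additive (and near-additive) distances.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO

import numpy as np
from Bio import Align
from skbio import TreeNode


class DistanceError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise DistanceError("matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T) or np.any(np.diag(self.d) != 0):
            raise DistanceError("matrix must be symmetric with zero diagonal")

    def value(self, a: str, b: str) -> float:
        return float(self.d[self.taxa.index(a), self.taxa.index(b)])


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    return aligner


_ALIGNER = _make_aligner()


def pairwise_alignment_stats(seq_a: str, seq_b: str) -> tuple[float, int]:
    """(p-distance, ungapped column count) from an affine-gap global
    alignment; gap columns are excluded from the distance."""
    if not seq_a or not seq_b:
        raise DistanceError("cannot align an empty sequence")
    if len(seq_a) == len(seq_b):
        # equal-length, low-divergence pairs: the ungapped diagonal is the
        # affine optimum (a mismatch costs less than an indel pair)
        a = np.frombuffer(seq_a.encode("ascii"), np.uint8)
        b = np.frombuffer(seq_b.encode("ascii"), np.uint8)
        mism = int((a != b).sum())
        if mism / len(seq_a) <= 0.15:
            return mism / len(seq_a), len(seq_a)
    aln = _ALIGNER.align(seq_a, seq_b)[0]
    counts = aln.counts()
    ungapped = counts.identities + counts.mismatches
    if ungapped == 0:
        raise DistanceError("alignment has no ungapped columns")
    return counts.mismatches / ungapped, ungapped


def pairwise_gene_distance(seq_a: str, seq_b: str,
                           jukes_cantor: bool = False) -> float:
    """p-distance between two gene sequences; optional Jukes-Cantor
    correction -3/4 ln(1 - 4p/3) (off by default)."""
    p, _ = pairwise_alignment_stats(seq_a, seq_b)
    if jukes_cantor:
        if p >= 0.75:
            raise DistanceError("p-distance too large for Jukes-Cantor")
        return -0.75 * np.log1p(-4.0 * p / 3.0)
    return p


def shared_single_copy_clusters(clusters, strains: list[str],
                                seq_lookup: dict[tuple[str, str], str],
                                max_clusters: int | None = None,
                                ) -> dict[str, dict[str, str]]:
    """Select clusters present exactly once in every strain and resolve
    member sequences, the input expected by ``concat_distance_matrix``.
    ``seq_lookup`` maps (strain_id, gene_id) to the CDS sequence."""
    want = sorted(strains)
    out: dict[str, dict[str, str]] = {}
    for cl in clusters:
        members = sorted(cl.members)
        if sorted(m[0] for m in members) != want:
            continue
        out[cl.cluster_id] = {s: seq_lookup[(s, g)] for s, g in members}
        if max_clusters is not None and len(out) >= max_clusters:
            break
    return out


def concat_distance_matrix(clusters: dict[str, dict[str, str]],
                           jukes_cantor: bool = False) -> DistanceMatrix:
    """Column-weighted mean of per-gene distances over shared single-copy
    clusters: d(i,j) = sum_g w_g p_g(i,j) / sum_g w_g with w_g the
    ungapped column count. Every cluster must cover every strain once."""
    if not clusters:
        raise DistanceError("no clusters supplied")
    taxa = sorted({s for seqs in clusters.values() for s in seqs})
    for cid, seqs in clusters.items():
        missing = set(taxa) - set(seqs)
        if missing:
            raise DistanceError(f"cluster {cid} missing strains {sorted(missing)}")
    n = len(taxa)
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for seqs in clusters.values():
        for i in range(n):
            for j in range(i + 1, n):
                p, w = pairwise_alignment_stats(seqs[taxa[i]], seqs[taxa[j]])
                if jukes_cantor:
                    p = float(-0.75 * np.log1p(-4.0 * min(p, 0.70) / 3.0))
                num[i, j] += w * p
                den[i, j] += w
    d = np.zeros((n, n))
    mask = den > 0
    d[mask] = num[mask] / den[mask]
    d = d + d.T
    return DistanceMatrix(taxa, d)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(matrix: DistanceMatrix) -> TreeNode:
    """Canonical neighbor joining.

    Ties in the Q criterion break toward the lexicographically smallest
    taxon pair; negative branch lengths are clamped to zero with the
    deficit moved to the sibling branch. Returns an unrooted tree
    (trifurcating root) as a scikit-bio TreeNode.
    """
    n = len(matrix.taxa)
    if n < 3:
        raise DistanceError("neighbor joining needs at least 3 taxa")
    nodes: dict[str, TreeNode] = {t: TreeNode(name=t) for t in matrix.taxa}
    labels = sorted(matrix.taxa)
    d: dict[tuple[str, str], float] = {}
    for i, a in enumerate(matrix.taxa):
        for j, b in enumerate(matrix.taxa):
            if a != b:
                d[(a, b)] = float(matrix.d[i, j])

    counter = 0
    while len(labels) > 3:
        m = len(labels)
        r = {a: sum(d[(a, b)] for b in labels if b != a) for a in labels}
        best = None
        for ai in range(m):
            for bi in range(ai + 1, m):
                a, b = labels[ai], labels[bi]
                q = (m - 2) * d[(a, b)] - r[a] - r[b]
                if best is None or q < best[0] - 1e-12:
                    best = (q, a, b)
        _q, a, b = best
        dab = d[(a, b)]
        la = 0.5 * dab + (r[a] - r[b]) / (2 * (m - 2))
        lb = dab - la
        if la < 0:
            lb, la = dab, 0.0
        if lb < 0:
            la, lb = dab, 0.0
        parent = TreeNode(name=f"_nj{counter}")
        counter += 1
        ca, cb = nodes.pop(a), nodes.pop(b)
        ca.length = max(la, 0.0)
        cb.length = max(lb, 0.0)
        parent.extend([ca, cb])
        u = parent.name
        for c in labels:
            if c in (a, b):
                continue
            duc = 0.5 * (d[(a, c)] + d[(b, c)] - dab)
            d[(u, c)] = d[(c, u)] = max(duc, 0.0)
        labels = sorted([c for c in labels if c not in (a, b)] + [u])
        nodes[u] = parent

    a, b, c = labels
    la = 0.5 * (d[(a, b)] + d[(a, c)] - d[(b, c)])
    lb = 0.5 * (d[(a, b)] + d[(b, c)] - d[(a, c)])
    lc = 0.5 * (d[(a, c)] + d[(b, c)] - d[(a, b)])
    root = TreeNode(name="root")
    for lbl, ln in ((a, la), (b, lb), (c, lc)):
        child = nodes.pop(lbl)
        child.length = max(ln, 0.0)
        root.append(child)
    return root


def to_newick(tree: TreeNode) -> str:
    return str(tree).strip()


def from_newick(s: str) -> TreeNode:
    return TreeNode.read(StringIO(s))


def robinson_foulds(tree_a: TreeNode, tree_b: TreeNode) -> int:
    """Symmetric bipartition difference between two unrooted trees."""
    ba = _bipartitions(tree_a)
    bb = _bipartitions(tree_b)
    return len(ba ^ bb)


def _bipartitions(tree: TreeNode, leaf_set: frozenset | None = None):
    """Non-trivial bipartitions as canonical frozensets (smaller side,
    ties by sorted tuple)."""
    leaves = leaf_set or frozenset(t.name for t in tree.tips())
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(leaves - side) < 2:
            continue
        other = leaves - side
        canon = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
        out.add(canon)
    return out


# ---------------------------------------------------------------------------
# gene concordance factors
# ---------------------------------------------------------------------------

def gene_concordance(gene_trees: list[TreeNode],
                     reference_tree: TreeNode) -> dict[frozenset, float | None]:
    """Per-branch gene concordance factor.

    For each internal branch of the reference tree (keyed by the
    canonical smaller side of its bipartition over the full leaf set),
    gCF = 100 x (# gene trees whose restriction to shared leaves contains
    the branch's restricted bipartition) / (# decisive gene trees). A
    gene tree is decisive when both restricted sides retain >= 2 leaves.
    Branches with no decisive gene tree map to None, not 0.
    """
    ref_leaves = frozenset(t.name for t in reference_tree.tips())
    gene_info = []
    for gt in gene_trees:
        gl = frozenset(t.name for t in gt.tips())
        gene_info.append((gl, _bipartitions(gt)))
    out: dict[frozenset, float | None] = {}
    for node in reference_tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = ref_leaves - side
        if len(side) < 2 or len(other) < 2:
            continue
        canon = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
        decisive = concordant = 0
        for gl, bips in gene_info:
            s = side & gl
            o = other & gl
            if len(s) < 2 or len(o) < 2:
                continue
            decisive += 1
            gcanon = min(s, o, key=lambda x: (len(x), tuple(sorted(x))))
            # bipartitions of the gene tree restricted to shared leaves
            restricted = {frozenset(bp & gl) for bp in bips}
            restricted = {min(bp, gl - bp,
                              key=lambda x: (len(x), tuple(sorted(x))))
                          for bp in restricted
                          if len(bp & gl) >= 2 and len(gl - bp) >= 2}
            if gcanon in restricted:
                concordant += 1
        out[canon] = 100.0 * concordant / decisive if decisive else None
    return out


def annotate_gcf(tree: TreeNode, gcf: dict[frozenset, float | None]) -> TreeNode:
    """Write gCF values into internal node names for Newick display."""
    leaves = frozenset(t.name for t in tree.tips())
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        canon = min(side, leaves - side,
                    key=lambda s: (len(s), tuple(sorted(s))))
        val = gcf.get(canon)
        node.name = "NA" if val is None else f"{val:.1f}"
    return tree
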