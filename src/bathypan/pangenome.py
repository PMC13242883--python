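"""Homologous gene clustering and pangenome occupancy.

CDS are clustered at 80% global identity and 80% mutual coverage with a
deterministic, representative-based greedy scheme (CD-HIT-EST-like
semantics, canonical length-descending order instead of tool-internal
order), turned into a strains x clusters presence/absence matrix, and
classified into core (>90% of strains), rare (<10%) and shell occupancy
classes. Strain relationships by gene content are summarised with
average-linkage hierarchical clustering on Jaccard distances.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform


class IntegrityError(ValueError):
    pass


@dataclass
class GeneCluster:
    cluster_id: str
    representative: tuple[str, str]  # (strain_id, gene_id)
    rep_seq: str = field(repr=False, default="")
    members: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class PresenceMatrix:
    """Binary occupancy with per-cluster category labels."""

    matrix: pd.DataFrame  # strains x clusters, uint8
    categories: dict[str, str] = field(default_factory=dict)

    @property
    def strains(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def clusters(self) -> list[str]:
        return list(self.matrix.columns)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _alignment_stats(a: str, b: str, k: int = -1):
    """(identity over aligned columns, coverage_a, coverage_b) from a
    global alignment; None when the edit distance exceeds ``k``."""
    res = edlib.align(a, b, mode="NW", task="path", k=k)
    if res["editDistance"] < 0:
        return None
    matches = x = 0
    for n, op in re.findall(r"(\d+)([=XID])", res["cigar"]):
        if op == "=":
            matches += int(n)
        elif op == "X":
            x += int(n)
    aligned = matches + x
    ident = matches / aligned if aligned else 0.0
    return ident, aligned / len(a), aligned / len(b)


def _edit_bound(la: int, lb: int, min_identity: float,
                min_coverage: float) -> int:
    """Largest edit distance an alignment passing the identity and
    coverage thresholds can have.

    For a global alignment, gaps I = la - aligned and D = lb - aligned,
    so the edit distance X + I + D is at most
    (1 - min_identity) * aligned + la + lb - 2 * aligned, maximised at
    the smallest admissible aligned span min_coverage * max(la, lb).
    A pair whose optimal edit distance exceeds this bound cannot pass."""
    aligned_min = min_coverage * max(la, lb)
    return int(la + lb - (1.0 + min_identity) * aligned_min)


def matches_cluster(seq: str, rep: str, min_identity: float,
                    min_coverage: float, bounded: bool = True) -> bool:
    """True when the global alignment of seq vs rep reaches the identity
    threshold over aligned columns and covers both sequences."""
    # cheap length screen: mutual coverage bounds the length ratio
    la, lb = len(seq), len(rep)
    if min(la, lb) < min_coverage * max(la, lb):
        return False
    k = _edit_bound(la, lb, min_identity, min_coverage) if bounded else -1
    stats = _alignment_stats(seq, rep, k=k)
    if stats is None:
        return False
    ident, cov_a, cov_b = stats
    return (ident >= min_identity and cov_a >= min_coverage
            and cov_b >= min_coverage)


def _kmer_set(seq: str, k: int) -> set:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def cluster_genes(
    cds_collection: list[tuple[str, str, str]],
    min_identity: float = 0.80,
    min_coverage: float = 0.80,
    use_prefilter: bool = True,
) -> list[GeneCluster]:
    """Deterministic greedy incremental clustering of CDS.

    ``cds_collection`` rows are (strain_id, gene_id, sequence). Genes are
    visited in canonical order (length descending, then strain and gene
    id); each joins the first existing cluster whose representative it
    matches at global identity >= ``min_identity`` with alignment
    coverage >= ``min_coverage`` of BOTH sequences, else founds a new
    cluster.

    The prefilter is a length screen plus a k-bounded edit-distance
    computation whose bound is derived from the thresholds themselves
    (see ``_edit_bound``), so skipped pairs provably cannot match and the
    partition is identical with the prefilter on or off.
    """
    for strain, gid, seq in cds_collection:
        if not seq:
            raise ValueError(f"empty CDS for {strain}:{gid}")
    ordered = sorted(cds_collection,
                     key=lambda r: (-len(r[2]), r[0], r[1]))
    clusters: list[GeneCluster] = []
    for strain, gid, seq in ordered:
        placed = False
        for cl in clusters:
            if matches_cluster(seq, cl.rep_seq, min_identity, min_coverage,
                               bounded=use_prefilter):
                cl.members.append((strain, gid))
                placed = True
                break
        if not placed:
            clusters.append(GeneCluster(f"clu{len(clusters):05d}",
                                        (strain, gid), seq, [(strain, gid)]))
    return clusters


# ---------------------------------------------------------------------------
# occupancy
# ---------------------------------------------------------------------------

def build_presence_matrix(clusters: list[GeneCluster],
                          strains: list[str]) -> PresenceMatrix:
    """occupancy[s, c] = 1 iff strain s has at least one member of c."""
    known = set(strains)
    data = np.zeros((len(strains), len(clusters)), dtype=np.uint8)
    sidx = {s: i for i, s in enumerate(strains)}
    for j, cl in enumerate(clusters):
        for strain, _gid in cl.members:
            if strain not in known:
                raise IntegrityError(f"unknown strain {strain} in {cl.cluster_id}")
            data[sidx[strain], j] = 1
    df = pd.DataFrame(data, index=list(strains),
                      columns=[c.cluster_id for c in clusters])
    return PresenceMatrix(df)


def classify_occupancy(matrix: PresenceMatrix,
                       core_threshold: float = 0.90,
                       rare_threshold: float = 0.10) -> dict[str, str]:
    """core iff presence fraction strictly exceeds ``core_threshold``,
    rare iff strictly below ``rare_threshold``, else shell."""
    if not (0 < rare_threshold < core_threshold < 1):
        raise ValueError("thresholds must satisfy 0 < rare < core < 1")
    n = len(matrix.strains)
    cats = {}
    frac = matrix.matrix.sum(axis=0) / n
    for cid, f in frac.items():
        if f > core_threshold:
            cats[cid] = "core"
        elif f < rare_threshold:
            cats[cid] = "rare"
        else:
            cats[cid] = "shell"
    matrix.categories = cats
    return cats


# ---------------------------------------------------------------------------
# strain dendrogram
# ---------------------------------------------------------------------------

@dataclass
class Dendrogram:
    linkage: np.ndarray
    leaf_order: list[str]
    newick: str
    strains: list[str]

    def first_split(self) -> tuple[set, set]:
        """Leaf sets of the two subtrees under the root join."""
        tree = hierarchy.to_tree(self.linkage)
        left = {self.strains[i] for i in _tree_leaves(tree.left)}
        right = {self.strains[i] for i in _tree_leaves(tree.right)}
        return left, right


def _tree_leaves(node):
    if node.is_leaf():
        return [node.id]
    return _tree_leaves(node.left) + _tree_leaves(node.right)


def jaccard_distances(matrix: PresenceMatrix) -> np.ndarray:
    """Pairwise 1 - |intersection|/|union| over occupancy rows; two
    all-zero rows are at distance 0."""
    m = matrix.matrix.to_numpy(dtype=np.int64)
    inter = m @ m.T
    sizes = m.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        d = 1.0 - np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    np.fill_diagonal(d, 0.0)
    return d


def strain_dendrogram(matrix: PresenceMatrix) -> Dendrogram:
    """Average-linkage hierarchical clustering on Jaccard distances of
    occupancy rows. Strains are canonically sorted before linkage so ties
    break deterministically by strain id."""
    if len(matrix.strains) < 2:
        raise ValueError("need at least two strains")
    order = sorted(matrix.strains)
    df = matrix.matrix.loc[order]
    pm = PresenceMatrix(df)
    d = jaccard_distances(pm)
    z = hierarchy.linkage(squareform(d, checks=False), method="average")
    leaves = [order[i] for i in hierarchy.leaves_list(z)]
    tree = hierarchy.to_tree(z)

    def nwk(node):
        if node.is_leaf():
            return order[node.id]
        return f"({nwk(node.left)},{nwk(node.right)}):{node.dist:.6g}"

    newick = nwk(tree).rsplit(":", 1)[0] + ";"
    return Dendrogram(z, leaves, newick, order)
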