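"""Phylogenetic beta diversity: OTU tree, UniFrac, PCoA, UPGMA dendrogram.

The OTU tree is neighbor-joining over pairwise alignment distances
(1 - identity) between OTU representative sequences, with negative branch
lengths clamped to zero and midpoint rooting. UniFrac is computed by branch
traversal: for every branch, the fraction of each sample's reads descending
from it; weighted UniFrac sums branch length times the absolute difference
of those fractions (normalized, by default, so the metric ranges from 0 for
identical communities to 1 for maximally distinct ones), unweighted UniFrac
is unique-over-union branch length on presence/absence. Ordination is
classical PCoA via Gower double-centering.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO

import edlib
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .search import cigar_columns


def alignment_distance(a: str, b: str) -> float:
    """1 - global alignment identity (gap columns count as differences)."""
    res = edlib.align(a, b, mode="NW", task="path")
    cols = cigar_columns(res["cigar"])
    return res["editDistance"] / cols


def representative_distance_matrix(named_seqs: list[tuple[str, str]],
                                   ) -> DistanceMatrix:
    ids = [name for name, _ in named_seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate leaf ids")
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = alignment_distance(named_seqs[i][1],
                                                   named_seqs[j][1])
    return DistanceMatrix(d, ids)


def build_tree(named_seqs: list[tuple[str, str]]) -> TreeNode:
    """Neighbor-joining tree over representatives, midpoint rooted."""
    if len(named_seqs) < 2:
        raise ValueError("need at least 2 representatives to build a tree")
    dm = representative_distance_matrix(named_seqs)
    tree = nj(dm, neg_as_zero=True)
    if len(named_seqs) > 2 and tree.get_max_distance()[0] > 0:
        tree = tree.root_at_midpoint()
    for node in tree.traverse():
        if node.length is None or node.length < 0:
            node.length = 0.0
    return tree


def _branch_table(tree: TreeNode, leaf_order: list[str],
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(branch lengths, branch x leaf membership, root-to-leaf depths)."""
    leaf_pos = {name: i for i, name in enumerate(leaf_order)}
    tree_leaves = {t.name for t in tree.tips()}
    missing = set(leaf_order) - tree_leaves
    if missing:
        raise ValueError(f"leaves missing from tree: {sorted(missing)}")
    lengths: list[float] = []
    members: list[np.ndarray] = []
    below: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            mask = np.zeros(len(leaf_order), dtype=bool)
            if node.name in leaf_pos:
                mask[leaf_pos[node.name]] = True
            below[id(node)] = mask
        else:
            mask = np.zeros(len(leaf_order), dtype=bool)
            for child in node.children:
                mask |= below[id(child)]
            below[id(node)] = mask
        if not node.is_root():
            lengths.append(node.length or 0.0)
            members.append(mask)
    depths = np.zeros(len(leaf_order))
    for tip in tree.tips():
        if tip.name in leaf_pos:
            depths[leaf_pos[tip.name]] = tip.accumulate_to_ancestor(tree)
    return np.array(lengths), np.array(members), depths


def weighted_unifrac(tree: TreeNode, counts_a, counts_b, taxa: list[str],
                     normalized: bool = True) -> float:
    """Branch-traversal weighted UniFrac between two samples."""
    l, m, depths = _branch_table(tree, list(taxa))
    pa = np.asarray(counts_a, dtype=float)
    pb = np.asarray(counts_b, dtype=float)
    if pa.sum() > 0:
        pa = pa / pa.sum()
    if pb.sum() > 0:
        pb = pb / pb.sum()
    raw = float(np.sum(l * np.abs(m @ pa - m @ pb)))
    if not normalized:
        return raw
    denom = float(np.sum(depths * (pa + pb)))
    return raw / denom if denom > 0 else 0.0


def unweighted_unifrac(tree: TreeNode, counts_a, counts_b,
                       taxa: list[str]) -> float:
    """Unique-over-shared branch length on presence/absence."""
    l, m, _ = _branch_table(tree, list(taxa))
    ia = m @ (np.asarray(counts_a, dtype=float) > 0)
    ib = m @ (np.asarray(counts_b, dtype=float) > 0)
    ia, ib = ia > 0, ib > 0
    union = float(np.sum(l * (ia | ib)))
    if union == 0:
        return 0.0
    return float(np.sum(l * (ia ^ ib))) / union


def unifrac_matrix(tree: TreeNode, otu_counts: pd.DataFrame,
                   metric: str = "weighted", normalized: bool = True,
                   ) -> DistanceMatrix:
    """All-pairs UniFrac over the samples (columns) of an OTU count table."""
    if metric not in ("weighted", "unweighted"):
        raise ValueError("metric must be 'weighted' or 'unweighted'")
    taxa = list(otu_counts.index)
    l, m, depths = _branch_table(tree, taxa)
    p = otu_counts.to_numpy(dtype=float)
    col_sums = p.sum(axis=0)
    p = np.divide(p, col_sums, where=col_sums > 0, out=np.zeros_like(p))
    bp = m @ p  # branch x sample descending proportions
    samples = list(otu_counts.columns)
    n = len(samples)
    d = np.zeros((n, n))
    if metric == "weighted":
        leaf_terms = depths[:, None] * p
        for i in range(n):
            for j in range(i + 1, n):
                raw = float(np.sum(l * np.abs(bp[:, i] - bp[:, j])))
                if normalized:
                    denom = float(leaf_terms[:, i].sum()
                                  + leaf_terms[:, j].sum())
                    raw = raw / denom if denom > 0 else 0.0
                d[i, j] = d[j, i] = raw
    else:
        pres = bp > 0
        for i in range(n):
            for j in range(i + 1, n):
                union = float(np.sum(l * (pres[:, i] | pres[:, j])))
                uniq = float(np.sum(l * (pres[:, i] ^ pres[:, j])))
                d[i, j] = d[j, i] = uniq / union if union > 0 else 0.0
    return DistanceMatrix(d, samples)


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray  # all eigenvalues, descending
    proportion_explained: np.ndarray  # per reported axis, over positive sum


def pcoa(dm: DistanceMatrix | np.ndarray, axes: int = 3,
         ids: list[str] | None = None) -> PCoAResult:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Gower double-centering ``B = -1/2 J D^2 J`` followed by an
    eigendecomposition; coordinates are eigenvectors scaled by the square
    root of their (positive) eigenvalues. Negative eigenvalues are reported
    but excluded from the variance fractions. Eigenvector signs follow the
    convention that the largest-magnitude loading on each axis is positive.
    """
    if isinstance(dm, DistanceMatrix):
        ids = list(dm.ids)
        d = dm.data
    else:
        d = np.asarray(dm, dtype=float)
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have a zero diagonal")
        ids = ids or [f"s{i}" for i in range(len(d))]
    n = len(d)
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    w, v = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    pos_sum = w[w > 0].sum()
    n_axes = min(axes, int((w > 1e-12).sum()))
    coords = np.zeros((n, n_axes))
    explained = np.zeros(n_axes)
    for i in range(n_axes):
        vec = v[:, i] * np.sqrt(w[i])
        if np.abs(vec).max() > 0 and vec[np.argmax(np.abs(vec))] < 0:
            vec = -vec
        coords[:, i] = vec
        explained[i] = w[i] / pos_sum if pos_sum > 0 else 0.0
    coordinates = pd.DataFrame(
        coords, index=pd.Index(ids, name="sample_id"),
        columns=[f"PC{i + 1}" for i in range(n_axes)])
    return PCoAResult(coordinates, w, explained)


def upgma_dendrogram(dm: DistanceMatrix) -> tuple[str, np.ndarray]:
    """Average-linkage dendrogram; returns (newick, scipy linkage matrix).

    Branch lengths are ultrametric: each node sits at half the merge
    distance, children hang at the height difference.
    """
    ids = list(dm.ids)
    z = hierarchy.linkage(squareform(dm.data, checks=False), method="average")
    root = hierarchy.to_tree(z)

    def newick(node, parent_height: float) -> str:
        height = node.dist / 2.0
        length = parent_height - height
        if node.is_leaf():
            return f"{ids[node.id]}:{length:.6g}"
        left = newick(node.left, height)
        right = newick(node.right, height)
        return f"({left},{right}):{length:.6g}"

    height = root.dist / 2.0
    tree = f"({newick(root.left, height)},{newick(root.right, height)});"
    return tree, z


def distance_long_table(dm: DistanceMatrix, groups: pd.Series) -> pd.DataFrame:
    """All sample pairs with their distance and group labels (for the
    within/between-group distance comparisons)."""
    ids = list(dm.ids)
    rows = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            gi, gj = groups[ids[i]], groups[ids[j]]
            contrast = "-".join(sorted((gi, gj)))
            rows.append((ids[i], ids[j], gi, gj, contrast,
                         "within" if gi == gj else "between",
                         dm.data[i, j]))
    return pd.DataFrame(rows, columns=[
        "sample_a", "sample_b", "group_a", "group_b", "contrast", "kind",
        "distance"])


def tree_to_newick(tree: TreeNode) -> str:
    buf = StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()
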