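"""Host phylogeny handling: Newick I/O, Grafen ultrametrization, pruning,
and the Brownian-motion species correlation matrix.

Supertrees assembled from taxonomy lack meaningful branch lengths, so the
standard recipe is: set every branch to one, then make the tree ultrametric
with Grafen's method (node height proportional to a power ``rho`` of the
number of descendant tips minus one, root scaled to depth 1).  Under a
Brownian trait model on an ultrametric depth-``d`` tree the between-species
correlation is the shared root-to-MRCA path length divided by ``d``.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd


class TreeError(ValueError):
    pass


@dataclass(frozen=True)
class CorrMatrix:
    """Species-by-species correlation matrix with a fixed label order."""

    labels: tuple[str, ...]
    matrix: np.ndarray  # (m, m), unit diagonal, PSD

    def __post_init__(self):
        m = self.matrix
        if m.shape != (len(self.labels), len(self.labels)):
            raise TreeError("matrix shape does not match labels")
        if not np.allclose(m, m.T, atol=1e-12):
            raise TreeError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-12):
            raise TreeError("correlation matrix must have unit diagonal")
        if np.linalg.eigvalsh(m).min() < -1e-10:
            raise TreeError("correlation matrix is not positive semi-definite")

    def submatrix(self, labels) -> "CorrMatrix":
        labels = tuple(sorted(labels))
        missing = set(labels) - set(self.labels)
        if missing:
            raise TreeError(f"labels not in matrix: {sorted(missing)}")
        idx = [self.labels.index(x) for x in labels]
        return CorrMatrix(labels, self.matrix[np.ix_(idx, idx)].copy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def read_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string; lengths stay absent (None) where not given."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"could not parse Newick: {exc}") from exc
    labels = tip_labels(tree)
    dup = {x for x in labels if labels.count(x) > 1}
    if dup:
        raise TreeError(f"duplicate tip labels: {sorted(dup)}")
    return tree


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def set_unit_branch_lengths(tree: dendropy.Tree) -> dendropy.Tree:
    tree = tree.clone(depth=1)
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node:
            edge.length = 1.0
    tree.seed_node.edge.length = None
    return tree


def grafen_transform(tree: dendropy.Tree, rho: float = 1.0) -> dendropy.Tree:
    """Make a tree ultrametric with unit depth using Grafen's node heights.

    Each internal node is placed at height ``((t - 1) / (T - 1)) ** rho``
    where ``t`` is its number of descendant tips and ``T`` the total; tips sit
    at height 0.  Idempotent: re-applying yields identical branch lengths.
    """
    if rho <= 0:
        raise TreeError("rho must be > 0")
    tree = tree.clone(depth=1)
    n_total = len(tree.leaf_nodes())
    if n_total < 2:
        raise TreeError("Grafen transform needs at least two tips")
    heights: dict[int, float] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._n_tips = 1
            heights[id(node)] = 0.0
        else:
            node._n_tips = sum(ch._n_tips for ch in node.child_nodes())
            heights[id(node)] = ((node._n_tips - 1) / (n_total - 1)) ** rho
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            node.edge.length = None
        else:
            node.edge.length = heights[id(node.parent_node)] - heights[id(node)]
    return tree


def tree_depth(tree: dendropy.Tree) -> float:
    """Maximum root-to-tip path length (missing lengths treated as errors)."""
    depths = _tip_depths(tree)
    return max(depths.values())


def _tip_depths(tree: dendropy.Tree) -> dict[str, float]:
    depths: dict[str, float] = {}
    dist: dict[int, float] = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        if node.edge.length is None:
            raise TreeError(
                "tree has missing branch lengths; apply grafen_transform first"
            )
        dist[id(node)] = dist[id(node.parent_node)] + node.edge.length
        if node.is_leaf():
            depths[node.taxon.label] = dist[id(node)]
    return depths


def is_ultrametric(tree: dendropy.Tree, rel_tol: float = 1e-6) -> bool:
    depths = list(_tip_depths(tree).values())
    d = max(depths)
    return d > 0 and (d - min(depths)) <= rel_tol * d


def prune(tree: dendropy.Tree, taxa) -> dendropy.Tree:
    """Restrict a tree to ``taxa``, summing lengths across removed degree-2
    nodes so tip-to-tip path lengths are preserved."""
    taxa = set(taxa)
    unknown = taxa - set(tip_labels(tree))
    if unknown:
        raise TreeError(f"taxa not in tree: {sorted(unknown)}")
    if len(taxa) < 2:
        raise TreeError("pruning needs at least two taxa")
    tree = tree.clone(depth=1)
    tree.retain_taxa_with_labels(sorted(taxa))
    return tree


def brownian_correlation(tree: dendropy.Tree) -> CorrMatrix:
    """Brownian-motion correlation matrix of an ultrametric tree.

    ``A[i, j]`` is the root-to-MRCA path length shared by tips ``i`` and
    ``j``, divided by the tree depth; the diagonal is exactly 1.  Labels are
    sorted lexicographically.
    """
    depths = _tip_depths(tree)
    d = max(depths.values())
    if d <= 0:
        raise TreeError("tree depth must be positive")
    if (d - min(depths.values())) > 1e-6 * d:
        raise TreeError("tree is not ultrametric; apply grafen_transform first")

    labels = sorted(depths)
    index = {lab: i for i, lab in enumerate(labels)}
    m = len(labels)
    A = np.zeros((m, m))

    # Shared path from root to MRCA = depth(MRCA); accumulate per internal node.
    node_depth: dict[int, float] = {id(tree.seed_node): 0.0}
    tips_below: dict[int, list[int]] = {}
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            node_depth[id(node)] = (
                node_depth[id(node.parent_node)] + node.edge.length
            )
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            tips_below[id(node)] = [index[node.taxon.label]]
        else:
            children = [tips_below[id(ch)] for ch in node.child_nodes()]
            h = node_depth[id(node)]
            for a in range(len(children)):
                for b in range(a + 1, len(children)):
                    for i in children[a]:
                        A[i, children[b]] = h
                        A[np.asarray(children[b]), i] = h
            tips_below[id(node)] = [i for sub in children for i in sub]
    A /= d
    np.fill_diagonal(A, 1.0)
    return CorrMatrix(tuple(labels), A)
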