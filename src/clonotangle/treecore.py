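"""Dendrogram data model, hierarchical clustering engines, and Newick I/O.

Every phylogeny builder in this package emits a :class:`Dendrogram`: a rooted
binary tree whose internal nodes carry a *height* (the dissimilarity at which
the two child clusters were merged) and whose child ordering induces a
left-to-right leaf sequence.  The leaf sequence is what the tanglegram
entanglement statistic operates on, so child order is a first-class, mutable
property of the tree.

Height conventions
------------------
* UPGMA: node height = average-linkage merge distance / 2 (the classical
  ultrametric convention, so cophenetic distance = 2 x LCA height recovers
  the merge distance).
* ``hclust`` with average / complete / ward.D linkage: node height = the raw
  merge criterion value, matching R's ``hclust`` heights.  Consequently an
  average-linkage ``hclust`` tree has heights exactly twice the UPGMA heights
  for the same input.

Tie-breaking in all linkage engines is deterministic: among pairs attaining
the minimal criterion, the pair whose (sorted) representative labels are
lexicographically smallest is merged, and each cluster is represented by its
lexicographically smallest leaf label.  This removes the input-order
dependence of R's hclust and makes every tree reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterator

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Node",
    "Dendrogram",
    "DistanceMatrix",
    "NewickParseError",
    "upgma",
    "hclust",
    "cophenetic",
    "read_newick",
    "write_newick",
]

HEIGHT_TOL = 1e-9


class NewickParseError(ValueError):
    """Malformed Newick input; ``offset`` is the 1-based character position."""

    def __init__(self, message: str, offset: int | None = None):
        super().__init__(message)
        self.offset = offset


# ---------------------------------------------------------------------------
# Tree model
# ---------------------------------------------------------------------------

class Node:
    """A dendrogram node: a labelled leaf at height 0, or an internal node
    with exactly two children and a non-negative merge height."""

    __slots__ = ("height", "children", "label", "support")

    def __init__(self, height: float = 0.0,
                 children: list["Node"] | None = None,
                 label: str | None = None,
                 support: float | None = None):
        self.height = float(height)
        self.children = children
        self.label = label
        self.support = support

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def leaves(self) -> Iterator["Node"]:
        if self.is_leaf:
            yield self
        else:
            for c in self.children:
                yield from c.leaves()

    def copy(self) -> "Node":
        if self.is_leaf:
            return Node(self.height, None, self.label, self.support)
        return Node(self.height, [c.copy() for c in self.children],
                    self.label, self.support)

    def swap(self) -> None:
        """Reverse child order; reverses the contiguous leaf block below."""
        if self.is_leaf:
            raise ValueError("cannot swap children of a leaf")
        self.children = self.children[::-1]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        if self.is_leaf:
            return f"Leaf({self.label!r})"
        return f"Node(h={self.height:.4g}, n={sum(1 for _ in self.leaves())})"


@dataclass
class Dendrogram:
    """Rooted binary tree with node heights and an ordered leaf sequence."""

    root: Node

    def __post_init__(self) -> None:
        self.validate()

    # -- structure -------------------------------------------------------
    def validate(self) -> None:
        labels: list[str] = []
        for node in self.iter_nodes():
            if node.is_leaf:
                if node.label is None:
                    raise ValueError("leaf without a label")
                labels.append(node.label)
            else:
                if len(node.children) != 2:
                    raise ValueError(
                        f"internal node with {len(node.children)} children; "
                        "dendrograms are strictly binary")
                if node.height < -HEIGHT_TOL:
                    raise ValueError(f"negative node height {node.height}")
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate leaf labels: {dup}")

    def iter_nodes(self) -> Iterator[Node]:
        """Pre-order traversal."""
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            if not node.is_leaf:
                stack.extend(reversed(node.children))

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.iter_nodes() if not n.is_leaf]

    @property
    def leaf_order(self) -> list[str]:
        return [leaf.label for leaf in self.root.leaves()]

    @property
    def labels(self) -> set[str]:
        return set(self.leaf_order)

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self.root.leaves())

    def copy(self) -> "Dendrogram":
        return Dendrogram(self.root.copy())

    # -- analysis --------------------------------------------------------
    def is_ultrametric(self, tol: float = HEIGHT_TOL) -> bool:
        """True if parent height >= max child height everywhere."""
        for node in self.iter_nodes():
            if node.is_leaf:
                continue
            if node.height < max(c.height for c in node.children) - tol:
                return False
        return True

    def cut(self, k: int) -> dict[str, int]:
        """Cut into ``k`` clusters by undoing the ``k - 1`` highest merges.

        Returns a label -> cluster-id mapping (ids are arbitrary but
        deterministic).  Ties in height are resolved by preferring the merge
        closer to the root (pre-order position), which reproduces the usual
        'cut the tallest fusions' reading of a dendrogram cut.
        """
        n = self.n_leaves
        if not 1 <= k <= n:
            raise ValueError(f"k={k} outside [1, {n}]")
        # Order internal nodes by height descending, pre-order rank ascending.
        order = {id(node): i for i, node in enumerate(self.iter_nodes())}
        internals = sorted(self.internal_nodes(),
                           key=lambda nd: (-nd.height, order[id(nd)]))
        cut_set = {id(nd) for nd in internals[: k - 1]}
        assignment: dict[str, int] = {}
        next_id = 0

        def assign(node: Node, cluster: int | None) -> None:
            nonlocal next_id
            if cluster is None and id(node) not in cut_set:
                cluster = next_id
                next_id += 1
            if node.is_leaf:
                assignment[node.label] = cluster if cluster is not None else -1
            else:
                for c in node.children:
                    assign(c, cluster)

        assign(self.root, None)
        return assignment


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with labelled rows/columns."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError(f"matrix shape {self.d.shape} != ({n}, {n})")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels in distance matrix")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("non-finite distance entries")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        if (self.d < -1e-12).any():
            raise ValueError("negative distances")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.d[i, j])

    # -- TSV round trip (square, labelled header row and column) --------
    def to_tsv(self, path_or_buf) -> None:
        pd.DataFrame(self.d, index=self.labels, columns=self.labels).to_csv(
            path_or_buf, sep="\t")

    @classmethod
    def from_tsv(cls, path_or_buf) -> "DistanceMatrix":
        df = pd.read_csv(path_or_buf, sep="\t", index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError("row and column labels differ")
        return cls(list(map(str, df.index)), df.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# Agglomerative engines
# ---------------------------------------------------------------------------

# Lance-Williams coefficients: given clusters i, j merging into ij and an
# outside cluster k, d(ij, k) = ai*d(i,k) + aj*d(j,k) + b*d(i,j)
#                                + g*|d(i,k) - d(j,k)|.

def _lw_average(ni, nj, nk):
    return ni / (ni + nj), nj / (ni + nj), 0.0, 0.0


def _lw_complete(ni, nj, nk):
    return 0.5, 0.5, 0.0, 0.5


def _lw_ward(ni, nj, nk):
    t = ni + nj + nk
    return (ni + nk) / t, (nj + nk) / t, -nk / t, 0.0


_LINKAGES: dict[str, Callable] = {
    "average": _lw_average,
    "complete": _lw_complete,
    "ward": _lw_ward,
    "ward.D": _lw_ward,
}


def _agglomerate(dm: DistanceMatrix, linkage: str,
                 height_scale: float) -> Dendrogram:
    n = len(dm.labels)
    if n < 2:
        raise ValueError("need at least 2 labels to cluster")
    lw = _LINKAGES[linkage]

    # Each active cluster is keyed by its lexicographically smallest leaf
    # label; that key also breaks ties among equal-criterion pairs.
    nodes: dict[str, Node] = {
        lab: Node(0.0, None, lab) for lab in dm.labels}
    sizes: dict[str, int] = {lab: 1 for lab in dm.labels}
    dist: dict[frozenset, float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[frozenset((dm.labels[i], dm.labels[j]))] = dm.d[i, j]

    while len(nodes) > 1:
        best: tuple[float, str, str] | None = None
        for key, val in dist.items():
            a, b = sorted(key)
            cand = (val, a, b)
            if best is None or cand < best:
                best = cand
        val, a, b = best
        # Children ordered by representative label: deterministic leaf order.
        merged = Node(val * height_scale, [nodes[a], nodes[b]])
        ni, nj = sizes[a], sizes[b]
        del nodes[a], nodes[b]
        for k in list(nodes):
            ai, aj, beta, gamma = lw(ni, nj, sizes[k])
            dik = dist.pop(frozenset((a, k)))
            djk = dist.pop(frozenset((b, k)))
            dist[frozenset((a, k))] = (
                ai * dik + aj * djk + beta * val + gamma * abs(dik - djk))
        del dist[frozenset((a, b))]
        nodes[a] = merged  # a < b, so the merged key stays the min label
        sizes[a] = ni + nj
        del sizes[b]

    return Dendrogram(next(iter(nodes.values())))


def upgma(dm: DistanceMatrix) -> Dendrogram:
    """Average-linkage agglomeration with ultrametric heights (d / 2).

    At every step the pair of clusters with the minimal size-weighted mean
    pairwise distance is merged at height = that distance / 2; ties go to the
    lexicographically smallest label pair.  The output satisfies the
    ultrametric three-point condition.
    """
    return _agglomerate(dm, "average", 0.5)


def hclust(dm: DistanceMatrix, linkage: str = "average") -> Dendrogram:
    """Agglomerative clustering with R-style raw-criterion heights.

    ``linkage`` is one of ``ward`` (R's ward.D: the Ward Lance-Williams
    recurrence applied to the dissimilarities as given), ``average`` or
    ``complete``.
    """
    if linkage not in _LINKAGES:
        raise ValueError(
            f"unknown linkage {linkage!r}; choose from "
            f"{sorted(set(_LINKAGES) - {'ward.D'})}")
    return _agglomerate(dm, linkage, 1.0)


def cophenetic(t: Dendrogram) -> DistanceMatrix:
    """Tree-induced distances: d(i, j) = 2 x height of the LCA of i and j.

    The factor 2 is the ultrametric convention that makes
    ``cophenetic(upgma(dm))`` reproduce ``dm`` exactly when ``dm`` is itself
    ultrametric; it is applied uniformly to every tree.
    """
    labels = t.leaf_order
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    d = np.zeros((n, n))

    def fill(node: Node) -> list[int]:
        if node.is_leaf:
            return [index[node.label]]
        left = fill(node.children[0])
        right = fill(node.children[1])
        for i in left:
            for j in right:
                d[i, j] = d[j, i] = 2.0 * node.height
        return left + right

    fill(t.root)
    return DistanceMatrix(labels, d)


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def _binarize(children: list[Node]) -> list[Node]:
    """Left-leaning binarization with zero-length internal edges."""
    while len(children) > 2:
        h = max(c.height for c in children[:2])
        children = [Node(h, children[:2])] + children[2:]
    return children


def read_newick(text: str, binarize: bool = False) -> Dendrogram:
    """Parse a Newick string (branch lengths required or implied 0).

    Node heights are reconstructed bottom-up: leaves sit at height 0 and an
    internal node's height is the maximum over children of child height plus
    the child's branch length, which inverts :func:`write_newick` exactly.
    Internal node labels, when numeric, are stored as bootstrap support.
    Non-binary nodes raise unless ``binarize`` is set, in which case they are
    resolved left-leaning with zero-length edges.
    """
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises several tokenizer errors
        offset = getattr(exc, "col_num", None)
        raise NewickParseError(
            f"malformed Newick at offset {offset}: {exc.__class__.__name__}",
            offset=offset) from exc

    def convert(dnode) -> tuple[Node, float]:
        """Returns (node, edge_top) where edge_top = node height + the
        length of the edge above it."""
        kids = dnode.child_nodes()
        bl = dnode.edge.length if dnode.edge.length is not None else 0.0
        if not kids:
            label = dnode.taxon.label if dnode.taxon else dnode.label
            if label is None:
                raise NewickParseError("unlabelled leaf")
            return Node(0.0, None, str(label)), bl
        pairs = [convert(k) for k in kids]
        if len(pairs) != 2:
            if not binarize:
                raise NewickParseError(
                    f"non-binary node with {len(pairs)} children "
                    "(pass binarize=True to resolve)")
            while len(pairs) > 2:  # left-leaning, zero-length joins
                top = max(t for _, t in pairs[:2])
                pairs = [(Node(top, [n for n, _ in pairs[:2]]), top)] \
                    + pairs[2:]
        height = max(t for _, t in pairs)
        support = None
        if dnode.label is not None:
            try:
                support = float(dnode.label)
            except ValueError:
                pass
        return Node(height, [n for n, _ in pairs], support=support), \
            height + bl

    root, _ = convert(tree.seed_node)
    if root.is_leaf:
        raise NewickParseError("single-leaf tree is not a dendrogram")
    return Dendrogram(root)


def write_newick(t: Dendrogram, include_support: bool = False) -> str:
    """Serialize with branch lengths = parent height - child height.

    ``write_newick(read_newick(x))`` preserves topology, heights (1e-9) and
    leaf order.  With ``include_support``, internal node labels carry the
    bootstrap proportion.
    """

    def fmt(node: Node, parent_height: float) -> str:
        bl = parent_height - node.height
        if node.is_leaf:
            return f"{node.label}:{bl:.10g}"
        inner = ",".join(fmt(c, node.height) for c in node.children)
        sup = ""
        if include_support and node.support is not None:
            sup = f"{node.support:.10g}"
        return f"({inner}){sup}:{bl:.10g}"

    root = t.root
    inner = ",".join(fmt(c, root.height) for c in root.children)
    sup = ""
    if include_support and root.support is not None:
        sup = f"{root.support:.10g}"
    return f"({inner}){sup};"
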