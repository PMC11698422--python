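"""Shared fixtures and independent oracles.

The linkage oracles here deliberately recompute cluster criteria from
scratch every round (O(n^3), numpy-matrix based) so that they share no code
path with the dict-based Lance-Williams engines they check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from clonotangle.treecore import Dendrogram, DistanceMatrix, upgma


def random_distance_matrix(n: int, seed: int,
                           labels: list[str] | None = None
                           ) -> DistanceMatrix:
    rng = np.random.default_rng(seed)
    d = rng.random((n, n))
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels or [f"t{i}" for i in range(n)], d)


def random_tree(n: int, seed: int) -> Dendrogram:
    return upgma(random_distance_matrix(n, seed))


def merge_table(t: Dendrogram) -> list[tuple[frozenset, float]]:
    """(leaf set, height) per internal node, sorted — a tree fingerprint."""
    out = []

    def walk(node) -> frozenset:
        if node.is_leaf:
            return frozenset([node.label])
        below = frozenset().union(*(walk(c) for c in node.children))
        out.append((below, node.height))
        return below

    walk(t.root)
    return sorted(out, key=lambda x: (sorted(x[0]), x[1]))


def naive_linkage_trace(dm: DistanceMatrix, linkage: str,
                        height_scale: float = 1.0
                        ) -> list[tuple[frozenset, float]]:
    """Brute-force agglomeration scanning all pairs each round.

    For ``average`` the criterion is recomputed from the original matrix
    (mean over all cross-cluster leaf pairs); ``complete`` likewise (max);
    ``ward`` applies the ward.D Lance-Williams recurrence on a dense matrix.
    Ties break on the lexicographically smallest sorted pair of
    representative labels (min leaf label per cluster).
    """
    labels = list(dm.labels)
    base = {a: {b: dm[(a, b)] for b in labels} for a in labels}
    clusters: list[frozenset] = [frozenset([l]) for l in labels]
    merges: list[tuple[frozenset, float]] = []

    if linkage == "ward":
        cur = {frozenset([a]): {frozenset([b]): base[a][b]
                                for b in labels if b != a}
               for a in labels}

    def criterion(ci: frozenset, cj: frozenset) -> float:
        if linkage == "average":
            return float(np.mean([base[a][b] for a in ci for b in cj]))
        if linkage == "complete":
            return float(np.max([base[a][b] for a in ci for b in cj]))
        return cur[ci][cj]

    while len(clusters) > 1:
        best = None
        for ci, cj in itertools.combinations(clusters, 2):
            key = tuple(sorted((min(ci), min(cj))))
            cand = (criterion(ci, cj), key, ci, cj)
            if best is None or cand[:2] < best[:2]:
                best = cand
        val, _, ci, cj = best
        merged = ci | cj
        if linkage == "ward":
            dij = cur[ci][cj]
            new_row = {}
            for ck in clusters:
                if ck in (ci, cj):
                    continue
                ni, nj, nk = len(ci), len(cj), len(ck)
                t = ni + nj + nk
                new_row[ck] = ((ni + nk) / t * cur[ci][ck]
                               + (nj + nk) / t * cur[cj][ck]
                               - nk / t * dij)
            for ck, v in new_row.items():
                cur[ck][merged] = v
            cur[merged] = new_row
        clusters = [c for c in clusters if c not in (ci, cj)] + [merged]
        merges.append((merged, val * height_scale))
    return sorted(merges, key=lambda x: (sorted(x[0]), x[1]))


def all_rotations(t: Dendrogram):
    """Every child-order assignment of a tree (2^internal copies)."""
    k = len(t.internal_nodes())
    for bits in itertools.product((0, 1), repeat=k):
        tt = t.copy()
        for b, node in zip(bits, tt.internal_nodes()):
            if b:
                node.swap()
        yield tt


@pytest.fixture
def three_leaf_dm() -> DistanceMatrix:
    return DistanceMatrix(
        ["A", "B", "C"],
        np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float))
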