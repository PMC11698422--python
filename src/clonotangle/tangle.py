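"""Tanglegram comparison: entanglement, untangling, and rendering.

Entanglement quantifies how crossed the connector lines of a tanglegram are.
For the labels shared by both trees, each label gets a rank in each tree's
left-to-right leaf order (restricted to the shared set); the statistic is

    entanglement = sum_i |r_i - s_i|^L  /  sum_i |i - (n + 1 - i)|^L

i.e. the rank-displacement sum normalized by its value for a full reversal,
so 0 means the two leaf orders agree and 1 means one is the exact reversal
of the other.  ``L`` (default 1.5) is the norm exponent; larger values
penalize long connectors more.

Untangling rotates internal nodes (swapping child order, which exchanges
the two child leaf blocks) without changing topology.
``untangle_step1side`` optimizes one tree against a fixed partner exactly;
``untangle_step2side`` finds the joint optimum for small trees and
alternates sides otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .treecore import Dendrogram, Node

__all__ = [
    "Tanglegram",
    "entanglement",
    "untangle_step1side",
    "untangle_step2side",
    "render_tanglegram",
]

DEFAULT_L = 1.5
CONVERGE_TOL = 1e-12


def _shared_ranks(left: Dendrogram, right: Dendrogram
                  ) -> tuple[list[str], np.ndarray, np.ndarray]:
    lo, ro = left.leaf_order, right.leaf_order
    if len(set(lo)) != len(lo) or len(set(ro)) != len(ro):
        raise ValueError("duplicate leaf labels")
    shared = set(lo) & set(ro)
    if not shared:
        raise ValueError("trees share no leaf labels")
    llab = [x for x in lo if x in shared]
    rrank = {x: i + 1 for i, x in enumerate(x for x in ro if x in shared)}
    r = np.arange(1, len(llab) + 1, dtype=float)
    s = np.array([rrank[x] for x in llab], dtype=float)
    return llab, r, s


def entanglement(left: Dendrogram, right: Dendrogram,
                 L: float = DEFAULT_L) -> float:
    """Normalized rank-displacement entanglement in [0, 1].

    Requires >= 2 shared labels.  0 for identical leaf orders; 1 when the
    restricted orders are exact reversals of each other.
    """
    if L <= 0:
        raise ValueError("norm exponent L must be positive")
    _, r, s = _shared_ranks(left, right)
    n = len(r)
    if n < 2:
        raise ValueError("need at least 2 shared labels")
    raw = float(np.sum(np.abs(r - s) ** L))
    rev = n + 1 - r
    denom = float(np.sum(np.abs(r - rev) ** L))
    if denom == 0.0:
        return 0.0
    return raw / denom


@dataclass
class Tanglegram:
    """A pair of dendrograms under comparison."""

    left: Dendrogram
    right: Dendrogram
    L: float = DEFAULT_L

    def __post_init__(self) -> None:
        self.shared_labels = self.left.labels & self.right.labels
        if not self.shared_labels:
            raise ValueError("trees share no leaf labels")

    @property
    def entanglement(self) -> float:
        return entanglement(self.left, self.right, self.L)

    def untangled(self, max_rounds: int = 25) -> "Tanglegram":
        l2, r2, _ = untangle_step2side(self.left, self.right, self.L,
                                       max_rounds=max_rounds)
        return Tanglegram(l2, r2, self.L)


def untangle_step1side(fixed: Dendrogram, movable: Dendrogram,
                       L: float = DEFAULT_L) -> Dendrogram:
    """Rotate ``movable``'s internal nodes to minimize entanglement.

    One-sided untangling is solved exactly: because a subtree's (shared)
    leaves always occupy a contiguous block of ranks, the minimal
    rank-displacement sum decomposes over nodes given the block offset, so a
    depth-first dynamic program over (node, offset) finds, at every node,
    the child order minimizing whole-tree entanglement against ``fixed``.
    Ties keep the incoming child order, so an already-optimal tree is
    returned unchanged; the result's entanglement never exceeds the
    input's.
    """
    if L <= 0:
        raise ValueError("norm exponent L must be positive")
    out = movable.copy()
    shared = fixed.labels & out.labels
    if not shared:
        raise ValueError("trees share no leaf labels")
    fixed_rank = {lab: i + 1 for i, lab in enumerate(
        x for x in fixed.leaf_order if x in shared)}

    nshared: dict[int, int] = {}

    def count(node: Node) -> int:
        if node.is_leaf:
            k = 1 if node.label in shared else 0
        else:
            k = sum(count(c) for c in node.children)
        nshared[id(node)] = k
        return k

    count(out.root)
    memo: dict[tuple[int, int], tuple[float, bool]] = {}

    def cost(node: Node, offset: int) -> float:
        """Min displacement sum when the node's shared leaves take ranks
        offset+1 .. offset+nshared; records the best flip decision."""
        if node.is_leaf:
            if node.label not in shared:
                return 0.0
            return abs((offset + 1) - fixed_rank[node.label]) ** L
        key = (id(node), offset)
        if key in memo:
            return memo[key][0]
        a, b = node.children
        ka = nshared[id(a)]
        keep = cost(a, offset) + cost(b, offset + ka)
        kb = nshared[id(b)]
        flip = cost(b, offset) + cost(a, offset + kb)
        best = (keep, False) if keep <= flip else (flip, True)
        memo[key] = best
        return best[0]

    cost(out.root, 0)

    def apply(node: Node, offset: int) -> None:
        if node.is_leaf:
            return
        _, flipped = memo[(id(node), offset)]
        if flipped:
            node.swap()
        a, b = node.children
        apply(a, offset)
        apply(b, offset + nshared[id(a)])

    apply(out.root, 0)
    return out


EXACT_2SIDE_LIMIT = 10  # enumerate <= 2**10 rotations of the smaller side


def untangle_step2side(left: Dendrogram, right: Dendrogram,
                       L: float = DEFAULT_L, max_rounds: int = 25
                       ) -> tuple[Dendrogram, Dendrogram, int]:
    """Two-sided untangling; returns (left', right', rounds).

    When the smaller tree has at most ``EXACT_2SIDE_LIMIT`` internal nodes
    the joint optimum is found exactly: every rotation assignment of that
    side is enumerated and the other side is solved by the exact one-sided
    dynamic program.  Larger pairs alternate one-sided untangling until no
    round improves (``max_rounds`` caps alternation to rule out rotation
    cycling).  Either way the final entanglement is <= the initial one.
    """
    import itertools

    n_l = len(left.internal_nodes())
    n_r = len(right.internal_nodes())
    if min(n_l, n_r) <= EXACT_2SIDE_LIMIT:
        enum_left = n_l <= n_r
        base = (left if enum_left else right).copy()
        nodes = base.internal_nodes()
        best: tuple[float, Dendrogram, Dendrogram] | None = None
        for bits in itertools.product((0, 1), repeat=len(nodes)):
            cand = base.copy()
            for b, node in zip(bits, cand.internal_nodes()):
                if b:
                    node.swap()
            if enum_left:
                other = untangle_step1side(cand, right, L)
                e = entanglement(cand, other, L)
                pair = (e, cand, other)
            else:
                other = untangle_step1side(cand, left, L)
                e = entanglement(other, cand, L)
                pair = (e, other, cand)
            if best is None or pair[0] < best[0] - CONVERGE_TOL:
                best = pair
            if best[0] <= CONVERGE_TOL:
                break
        return best[1], best[2], 1

    cur_l, cur_r = left.copy(), right.copy()
    prev = entanglement(cur_l, cur_r, L)
    rounds = 0
    for rounds in range(1, max_rounds + 1):
        cur_r = untangle_step1side(cur_l, cur_r, L)
        cur_l = untangle_step1side(cur_r, cur_l, L)
        now = entanglement(cur_l, cur_r, L)
        if now > prev + CONVERGE_TOL:  # must never happen
            raise AssertionError("untangling increased entanglement")
        if now > prev - CONVERGE_TOL:
            break
        prev = now
    return cur_l, cur_r, rounds


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _leaf_positions(t: Dendrogram) -> dict[str, float]:
    order = t.leaf_order
    n = len(order)
    return {lab: n - 1 - i for i, lab in enumerate(order)}


def _draw_dendrogram(ax, t: Dendrogram, side: str, span: float) -> None:
    """Draw with leaves at x=0 (left tree) or x=0 mirrored (right tree)."""
    ypos = _leaf_positions(t)
    hmax = max(t.root.height, 1e-12)

    def xcoord(h: float) -> float:
        frac = h / hmax
        return -frac * span if side == "left" else frac * span

    def layout(node: Node) -> float:
        if node.is_leaf:
            return ypos[node.label]
        ys = [layout(c) for c in node.children]
        x = xcoord(node.height)
        for c, y in zip(node.children, ys):
            ax.plot([x, xcoord(c.height)], [y, y], color="0.2", lw=1.0)
        ax.plot([x, x], [min(ys), max(ys)], color="0.2", lw=1.0)
        return float(np.mean(ys))

    layout(t.root)


def render_tanglegram(tg: Tanglegram, path: str,
                      groups: dict[str, str] | None = None) -> None:
    """Render back-to-back dendrograms with straight inter-leaf connectors.

    ``groups`` maps label -> group name; connectors and labels are coloured
    per group.  Labels present in only one tree are drawn without a
    connector.  The entanglement value is printed in the figure margin.
    Output format follows the file extension (SVG recommended).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    plt.rcParams["svg.fonttype"] = "none"  # keep labels as text elements

    lpos = _leaf_positions(tg.left)
    rpos = _leaf_positions(tg.right)
    nmax = max(len(lpos), len(rpos))
    fig, ax = plt.subplots(figsize=(8, max(2.5, 0.28 * nmax)))

    span = 1.0
    gap = 1.2
    # left tree occupies x in [-span-gap, -gap]; right in [gap, span+gap]
    # connectors run across [-gap, gap]
    group_names = sorted(set((groups or {}).values()))
    cmap = plt.get_cmap("tab10")
    colour_of = {g: cmap(i % 10) for i, g in enumerate(group_names)}

    def colour(lab: str):
        if groups and lab in groups:
            return colour_of[groups[lab]]
        return "0.3"

    # trees
    ax_l = ax.inset_axes([0.0, 0.0, 0.32, 1.0])
    ax_r = ax.inset_axes([0.68, 0.0, 0.32, 1.0])
    for sub in (ax_l, ax_r):
        sub.set_axis_off()
    _draw_dendrogram(ax_l, tg.left, "left", span)
    _draw_dendrogram(ax_r, tg.right, "right", span)
    ax_l.set_xlim(-span * 1.05, 0.35)
    ax_r.set_xlim(-0.35, span * 1.05)
    ylim = (-0.6, nmax - 0.4)
    ax_l.set_ylim(*ylim)
    ax_r.set_ylim(*ylim)
    ax.set_xlim(0, 1)
    ax.set_ylim(*ylim)
    ax.set_axis_off()

    for lab, y in lpos.items():
        ax_l.text(0.05, y, lab, ha="left", va="center", fontsize=7,
                  color=colour(lab))
    for lab, y in rpos.items():
        ax_r.text(-0.05, y, lab, ha="right", va="center", fontsize=7,
                  color=colour(lab))
    for lab in sorted(tg.shared_labels):
        ax.plot([0.34, 0.66], [lpos[lab], rpos[lab]],
                color=colour(lab), lw=1.0, alpha=0.8,
                gid=f"connector-{lab}")

    ax.set_title(f"entanglement (L={tg.L:g}) = {tg.entanglement:.3f}",
                 fontsize=9)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
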