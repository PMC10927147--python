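"""Neighbor-Joining trees from K2P distance matrices.

Classical NJ (Saitou & Nei agglomeration on the Q criterion): at each step the
pair minimising

    Q(i, j) = (m - 2) d(i, j) - r_i - r_j,      r_i = sum_k d(i, k)

is joined.  Negative estimated branch lengths — a normal by-product of noisy
distances — are clamped to zero with the deficit transferred to the sister
edge, preserving the path length between the joined taxa.  Ties are broken by
the lowest index pair so output is deterministic.

The resulting tree is unrooted with leaves labelled by specimen id;
:func:`collapse_by` condenses monophyletic species or MOTU groups to single
labelled leaves for genus-level views.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .distances import DistanceMatrix
from .io_model import BarcodeAuditError

__all__ = ["NJTree", "build_nj", "collapse_by"]


@dataclass
class NJTree:
    """Unrooted tree: adjacency map node -> {neighbour: branch length}."""

    adjacency: dict[int, dict[int, float]]
    leaf_labels: dict[int, str]
    #: labels found non-monophyletic by :func:`collapse_by`
    flagged: list[str] = field(default_factory=list)

    def leaves(self) -> list[int]:
        return sorted(self.leaf_labels)

    def _side_leaves(self, node: int, parent: int) -> frozenset[str]:
        out: set[str] = set()
        stack = [(node, parent)]
        while stack:
            cur, par = stack.pop()
            if cur in self.leaf_labels:
                out.add(self.leaf_labels[cur])
            for nbr in self.adjacency[cur]:
                if nbr != par:
                    stack.append((nbr, cur))
        return frozenset(out)

    def splits(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions (as the smaller-side canonical form)."""
        all_leaves = frozenset(self.leaf_labels.values())
        out: set[frozenset[str]] = set()
        for a in self.adjacency:
            for b in self.adjacency[a]:
                if a < b:
                    side = self._side_leaves(a, b)
                    if 1 < len(side) < len(all_leaves) - 1:
                        out.add(min(side, all_leaves - side, key=sorted))
        return out

    def path_length(self, label_a: str, label_b: str) -> float:
        """Sum of branch lengths on the path between two leaves."""
        inv = {lab: node for node, lab in self.leaf_labels.items()}
        start, goal = inv[label_a], inv[label_b]
        stack = [(start, None, 0.0)]
        while stack:
            cur, par, dist = stack.pop()
            if cur == goal:
                return dist
            for nbr, length in self.adjacency[cur].items():
                if nbr != par:
                    stack.append((nbr, cur, dist + length))
        raise BarcodeAuditError("leaves not connected")  # pragma: no cover


def build_nj(dm: DistanceMatrix, subset: list[str] | None = None) -> NJTree:
    """Neighbor-Joining tree for a distance matrix (or a subset of its ids)."""
    sub = dm.submatrix(subset) if subset is not None else dm
    n = len(sub)
    if n < 2:
        raise BarcodeAuditError("NJ requires >= 2 taxa")
    bad = [
        (sub.ids[i], sub.ids[j])
        for i in range(n)
        for j in range(i + 1, n)
        if np.isnan(sub.d[i, j])
    ]
    if bad:
        raise BarcodeAuditError(
            f"saturated/undefined distances in NJ input: {bad[:3]}"
        )

    adjacency: dict[int, dict[int, float]] = {}
    leaf_labels: dict[int, str] = {}

    def connect(a: int, b: int, length: float) -> None:
        adjacency.setdefault(a, {})[b] = length
        adjacency.setdefault(b, {})[a] = length

    if n == 2:
        # Two taxa: split the single distance symmetrically across a
        # degree-2 junction so both leaves carry half the distance.
        centre = 2
        leaf_labels[0], leaf_labels[1] = sub.ids[0], sub.ids[1]
        half = sub.d[0, 1] / 2.0
        connect(0, centre, half)
        connect(1, centre, half)
        return NJTree(adjacency, leaf_labels)

    D = sub.d.copy()
    active = list(range(n))  # positions into D
    node_of = {i: i for i in range(n)}  # position -> tree node id
    for i, sid in enumerate(sub.ids):
        leaf_labels[i] = sid
    next_node = n

    while len(active) > 3:
        m = len(active)
        Dm = D[np.ix_(active, active)]
        r = Dm.sum(axis=1)
        Q = (m - 2) * Dm - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        dij = Dm[ai, aj]
        vi = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        vj = dij - vi
        # clamp negatives, moving the deficit to the sister edge
        if vi < 0:
            vj += vi
            vi = 0.0
        if vj < 0:
            vi += vj
            vj = 0.0
        vi, vj = max(vi, 0.0), max(vj, 0.0)
        new = next_node
        next_node += 1
        connect(node_of[active[ai]], new, vi)
        connect(node_of[active[aj]], new, vj)
        # distances from the new node to the remaining taxa
        pi, pj = active[ai], active[aj]
        rest = [p for k, p in enumerate(active) if k not in (ai, aj)]
        new_d = 0.5 * (D[pi, rest] + D[pj, rest] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        pn = D.shape[0] - 1
        D[pn, rest] = new_d
        D[rest, pn] = new_d
        node_of[pn] = new
        active = rest + [pn]

    # final three taxa join a central node
    pa, pb, pc = active
    dab, dac, dbc = D[pa, pb], D[pa, pc], D[pb, pc]
    va = 0.5 * (dab + dac - dbc)
    vb = 0.5 * (dab + dbc - dac)
    vc = 0.5 * (dac + dbc - dab)
    centre = next_node
    for p, v in ((pa, va), (pb, vb), (pc, vc)):
        connect(node_of[p], centre, max(v, 0.0))
    return NJTree(adjacency, leaf_labels)


def collapse_by(
    tree: NJTree, label_map: Mapping[str, str], mode: str = "species"
) -> NJTree:
    """Collapse monophyletic same-label leaf sets to single labelled leaves.

    ``label_map`` maps leaf labels (specimen ids) to display groups (species
    or MOTU labels); every leaf must be covered.  A group whose leaves form a
    clade is replaced by one leaf ``"<label> (n=k)"`` carrying the separating
    edge's length; non-monophyletic groups are left expanded and recorded in
    ``flagged``.  Groups of a single leaf are left untouched.
    """
    if mode not in ("species", "motu"):
        raise BarcodeAuditError(f"unknown collapse mode {mode!r}")
    uncovered = [lab for lab in tree.leaf_labels.values() if lab not in label_map]
    if uncovered:
        raise BarcodeAuditError(f"label_map does not cover leaves: {uncovered[:5]}")

    adjacency = {a: dict(nbrs) for a, nbrs in tree.adjacency.items()}
    leaf_labels = dict(tree.leaf_labels)
    flagged: list[str] = []
    work = NJTree(adjacency, leaf_labels)

    groups: dict[str, set[str]] = {}
    for leaf, group in ((lab, label_map[lab]) for lab in leaf_labels.values()):
        groups.setdefault(group, set()).add(leaf)

    for group in sorted(groups):
        members = groups[group]
        if len(members) < 2:
            continue
        # find an edge separating exactly this leaf set
        edge = None
        for a in list(work.adjacency):
            for b in work.adjacency[a]:
                if work._side_leaves(a, b) == members:
                    edge = (a, b)
                    break
            if edge:
                break
        if edge is None:
            flagged.append(group)
            continue
        inner, outer = edge
        length = work.adjacency[inner][outer]
        # drop the subtree on the inner side
        to_drop = set()
        stack = [(inner, outer)]
        while stack:
            cur, par = stack.pop()
            to_drop.add(cur)
            for nbr in work.adjacency[cur]:
                if nbr != par:
                    stack.append((nbr, cur))
        for node in to_drop:
            work.adjacency.pop(node)
            work.leaf_labels.pop(node, None)
            work.adjacency[outer].pop(node, None)
        new = max(max(work.adjacency, default=0), max(to_drop)) + 1
        work.adjacency[new] = {outer: length}
        work.adjacency[outer][new] = length
        work.leaf_labels[new] = f"{group} (n={len(members)})"
    work.flagged = flagged
    return work
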