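"""Independent reference implementations used to check the package.

Everything here is deliberately naive — pure-Python loops, exhaustive
enumeration, closed forms — and shares no code with the package internals it
validates.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}


def py_k2p(seq_a: str, seq_b: str):
    """Direct closed-form K2P evaluation with pairwise deletion."""
    sites = ts = tv = 0
    for x, y in zip(seq_a, seq_b):
        if x not in "ACGT" or y not in "ACGT":
            continue
        sites += 1
        if x == y:
            continue
        same_class = (x in PURINES) == (y in PURINES)
        if same_class:
            ts += 1
        else:
            tv += 1
    if sites == 0:
        return None, 0
    P, Q = ts / sites, tv / sites
    if 1 - 2 * P - Q <= 0 or 1 - 2 * Q <= 0:
        return "saturated", sites
    return -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q), sites


def brute_force_summaries(ids, d, species_of):
    """Per-species mean/max intra and min-NN by exhaustive pair enumeration."""
    out = {}
    for sp in sorted(set(species_of.values())):
        members = [i for i, sid in enumerate(ids) if species_of[sid] == sp]
        intra = []
        for i, j in itertools.combinations(members, 2):
            if not math.isnan(d[i][j]):
                intra.append(d[i][j])
        best = math.inf
        best_species = None
        for i in members:
            for j in range(len(ids)):
                if species_of[ids[j]] == sp or math.isnan(d[i][j]):
                    continue
                if d[i][j] < best or (
                    d[i][j] == best and species_of[ids[j]] < best_species
                ):
                    best = d[i][j]
                    best_species = species_of[ids[j]]
        out[sp] = {
            "n": len(members),
            "mean_intra": sum(intra) / len(intra) if intra else None,
            "max_intra": max(intra) if intra else None,
            "min_nn": best,
            "nn_species": best_species,
        }
    return out


def union_find_cluster(ids, d, t):
    """Single-linkage clusters at threshold t via naive union-find.

    Returns a set partition as frozensets of ids; nan distances never join.
    """
    parent = {sid: sid for sid in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in itertools.combinations(range(len(ids)), 2):
        if not math.isnan(d[i][j]) and d[i][j] <= t:
            parent[find(ids[i])] = find(ids[j])
    groups = {}
    for sid in ids:
        groups.setdefault(find(sid), set()).add(sid)
    return {frozenset(g) for g in groups.values()}


def partition_as_sets(assignment):
    groups = {}
    for sid, label in assignment.items():
        groups.setdefault(label, set()).add(sid)
    return {frozenset(g) for g in groups.values()}


def classify_oracle(assignment, species_of):
    """Exhaustive unique/share/split classification of one partition."""
    out = {}
    labels_by_species = {}
    species_by_label = {}
    for sid, label in assignment.items():
        sp = species_of[sid]
        labels_by_species.setdefault(sp, set()).add(label)
        species_by_label.setdefault(label, set()).add(sp)
    for sp, labels in labels_by_species.items():
        shares = any(len(species_by_label[lab]) > 1 for lab in labels)
        out[sp] = {"n_motus": len(labels), "shares": shares, "split": len(labels) >= 2}
    return out


def agreement_oracle(assign_x, assign_y, species_of, domain):
    """Per-species agreement between two partitions (set-based definition)."""

    def signature(assignment, sp):
        groups = {}
        for sid in domain:
            if species_of[sid] == sp:
                groups.setdefault(assignment[sid], set()).add(sid)
        cooccur = []
        for label in groups:
            for sid in domain:
                if assignment[sid] == label and species_of[sid] != sp:
                    cooccur.append(species_of[sid])
        return (
            frozenset(frozenset(g) for g in groups.values()),
            tuple(sorted(cooccur)),
        )

    return {
        sp: signature(assign_x, sp) == signature(assign_y, sp)
        for sp in sorted({species_of[sid] for sid in domain})
    }


# --------------------------------------------------------------------------
# unrooted binary trees for NJ checks


def random_additive_tree(n_leaves, rng, low=0.01, high=0.2):
    """Random unrooted binary tree with random edge lengths.

    Returns (edges, labels) with edges as {(u, v): length}; leaves are
    0..n_leaves-1 labelled "T0".."T<n-1>", internal nodes numbered upward.
    """
    edges = {}
    next_node = n_leaves

    def add_edge(a, b, w):
        edges[(min(a, b), max(a, b))] = w

    centre = next_node
    next_node += 1
    for leaf in range(3):
        add_edge(leaf, centre, float(rng.uniform(low, high)))
    for leaf in range(3, n_leaves):
        (u, v), w = list(edges.items())[rng.integers(len(edges))]
        del edges[(u, v)]
        mid = next_node
        next_node += 1
        split = float(rng.uniform(0.25, 0.75))
        add_edge(u, mid, w * split)
        add_edge(v, mid, w * (1 - split))
        add_edge(leaf, mid, float(rng.uniform(low, high)))
    labels = {i: f"T{i}" for i in range(n_leaves)}
    return edges, labels


def tree_distance_matrix(edges, labels):
    """Leaf-to-leaf path-length matrix of an edge-weighted tree."""
    adj = {}
    for (u, v), w in edges.items():
        adj.setdefault(u, {})[v] = w
        adj.setdefault(v, {})[u] = w
    leaves = sorted(labels)
    n = len(leaves)
    D = np.zeros((n, n))
    for i, start in enumerate(leaves):
        dist = {start: 0.0}
        stack = [start]
        while stack:
            cur = stack.pop()
            for nbr, w in adj[cur].items():
                if nbr not in dist:
                    dist[nbr] = dist[cur] + w
                    stack.append(nbr)
        for j, goal in enumerate(leaves):
            D[i, j] = dist[goal]
    return D, [labels[i] for i in leaves]


def tree_splits(edges, labels):
    """Non-trivial bipartitions of the leaf set, canonical smaller side."""
    adj = {}
    for (u, v), w in edges.items():
        adj.setdefault(u, {})[v] = w
        adj.setdefault(v, {})[u] = w
    all_leaves = frozenset(labels.values())
    out = set()
    for (u, v) in edges:
        side = set()
        stack = [(u, v)]
        while stack:
            cur, par = stack.pop()
            if cur in labels:
                side.add(labels[cur])
            for nbr in adj[cur]:
                if nbr != par:
                    stack.append((nbr, cur))
        side = frozenset(side)
        if 1 < len(side) < len(all_leaves) - 1:
            out.add(min(side, all_leaves - side, key=sorted))
    return out


def enumerate_topologies(n_leaves):
    """All unrooted binary topologies on leaves 0..n-1 (as edge sets)."""
    if n_leaves < 3:
        raise ValueError("need >= 3 leaves")
    base = [frozenset({(0, n_leaves), (1, n_leaves), (2, n_leaves)})]
    next_internal = n_leaves + 1
    trees = base
    for leaf in range(3, n_leaves):
        new_trees = []
        for edge_set in trees:
            for (u, v) in edge_set:
                mid = next_internal
                others = edge_set - {(u, v)}
                new = others | {(u, mid), (v, mid), (leaf, mid)}
                new_trees.append(frozenset(new))
        next_internal += 1
        trees = new_trees
    return trees


def fit_edge_lengths(edge_set, n_leaves, D):
    """Least-squares edge lengths for a topology; returns (lengths, rss)."""
    edges = sorted(edge_set)
    adj = {}
    for (u, v) in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    pairs = list(itertools.combinations(range(n_leaves), 2))
    A = np.zeros((len(pairs), len(edges)))
    for row, (a, b) in enumerate(pairs):
        # path from a to b
        stack = [(a, None, [])]
        while stack:
            cur, par, path = stack.pop()
            if cur == b:
                for e in path:
                    A[row, edges.index(e)] = 1.0
                break
            for nbr in adj[cur]:
                if nbr != par:
                    key = (min(cur, nbr), max(cur, nbr))
                    stack.append((nbr, cur, path + [key]))
    y = np.array([D[a, b] for a, b in pairs])
    lengths, *_ = np.linalg.lstsq(A, y, rcond=None)
    rss = float(np.sum((A @ lengths - y) ** 2))
    return dict(zip(edges, lengths)), rss
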