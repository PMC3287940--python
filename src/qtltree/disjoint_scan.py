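"""Maximum score over disjoint node sets.

The gene-level statistic S_j is the maximum, over sets of at most j
pairwise *disjoint* nodes (no node an ancestor of another — an antichain),
of the summed node scores f(z).  A post-order dynamic program computes all
of S_1..S_k in one pass: for node v and budget m,

    best(v, m) = max( score(v)                        # select v, close subtree
                      max_{m0+m1=m} best(c0, m0) + best(c1, m1) )

with best(., 0) = 0 and the empty selection allowed, so a branch never
contributes a forced negative score and S_j is non-decreasing in j.
Complexity is O(#nodes * k^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ScanStatistics:
    """S_1..S_k for one gene with, per budget, one maximizing antichain."""

    gene: str
    k: int
    S: np.ndarray                     # length k, S[j-1] = S_j
    best_sets: list[tuple[int, ...]]  # best_sets[j-1] achieves S_j

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)


# candidate = (value, size, ids); maximize value, then prefer fewer nodes,
# then the lexicographically smallest id sequence — deterministic reports.
_EMPTY = (0.0, 0, ())


def _better(a, b):
    if a[0] != b[0]:
        return a if a[0] > b[0] else b
    return a if (a[1], a[2]) < (b[1], b[2]) else b


def _scores_array(tree, scores) -> np.ndarray:
    if isinstance(scores, dict):
        return np.array([float(scores[v.node_id]) for v in tree.nodes])
    arr = np.asarray(scores, dtype=float)
    if arr.shape != (tree.n_nodes,):
        raise ValueError("scores must cover every node")
    return arr


def best_disjoint(tree, scores, k: int) -> ScanStatistics:
    """Exact S_1..S_k by dynamic programming, with maximizing antichains.

    ``scores`` is a dict node_id -> score or an array indexed by node id.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    sc = _scores_array(tree, scores)

    best: dict[int, list[tuple]] = {}
    for nid in tree.postorder():
        v = tree.nodes[nid]
        row = [_EMPTY] * (k + 1)
        own = (sc[nid], 1, (nid,))
        if v.is_leaf:
            for m in range(1, k + 1):
                row[m] = _better(_EMPTY, own)
        else:
            b0, b1 = best[v.child0], best[v.child1]
            for m in range(1, k + 1):
                cand = own
                for m0 in range(0, m + 1):
                    l, r = b0[m0], b1[m - m0]
                    cand = _better(cand, (l[0] + r[0], l[1] + r[1],
                                          tuple(sorted(l[2] + r[2]))))
                row[m] = cand
        best[nid] = row
        if not v.is_leaf:
            del best[v.child0], best[v.child1]

    root = best[tree.root_id]
    return ScanStatistics(gene=tree.gene, k=k,
                          S=np.array([root[m][0] for m in range(1, k + 1)]),
                          best_sets=[root[m][2] for m in range(1, k + 1)])


def brute_force_disjoint(tree, scores, k: int, max_nodes: int = 30) -> ScanStatistics:
    """Independent oracle: enumerate every antichain of size <= k.

    Guarded to small trees; used to validate the dynamic program.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if tree.n_nodes > max_nodes:
        raise ValueError(f"tree too large for enumeration ({tree.n_nodes} > {max_nodes} nodes)")
    sc = _scores_array(tree, scores)

    # incompatibility: ancestors and descendants of each node
    parent = tree.parents()
    incompatible = [set() for _ in range(tree.n_nodes)]
    for nid in range(tree.n_nodes):
        a = parent[nid]
        while a != -1:
            incompatible[nid].add(int(a))
            incompatible[int(a)].add(nid)
            a = parent[a]

    best = [_EMPTY] * (k + 1)  # best antichain of size exactly m

    def rec(start: int, chosen: tuple[int, ...], value: float, blocked: set[int]) -> None:
        m = len(chosen)
        best[m] = _better(best[m], (value, m, chosen))
        if m == k:
            return
        for nid in range(start, tree.n_nodes):
            if nid in blocked:
                continue
            rec(nid + 1, chosen + (nid,), value + sc[nid], blocked | incompatible[nid])

    rec(0, (), 0.0, set())

    S, sets, running = [], [], _EMPTY
    for m in range(1, k + 1):
        running = _better(running, best[m])
        S.append(running[0])
        sets.append(running[2])
    return ScanStatistics(gene=tree.gene, k=k, S=np.array(S), best_sets=sets)
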