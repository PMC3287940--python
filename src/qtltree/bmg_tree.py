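"""Lexical genotype trees.

A gene's binary multilocus genotypes (BMGs) are clustered by processing the
gene's variant sites in a fixed order.  All individuals start at the root;
whenever the individuals at a node differ at the current site the node is
split, 0-carriers on one branch and 1-carriers on the other.  Leaves end up
in one-to-one correspondence with the distinct observed BMGs, and two BMGs
that first differ at site t separate exactly when t is processed, so
genotypes one mutation apart always cluster.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .genotype_io import BMGMatrix


@dataclass
class TreeNode:
    node_id: int
    members: np.ndarray               # sorted individual indices
    split_site: int | None = None     # index into site_order at which this node splits
    child0: int | None = None         # 0-carriers branch
    child1: int | None = None         # 1-carriers branch

    @property
    def is_leaf(self) -> bool:
        return self.child0 is None

    @property
    def n(self) -> int:
        return len(self.members)


@dataclass
class GenotypeTree:
    """Binary tree over a gene's BMGs; node ids follow construction order."""

    gene: str
    nodes: list[TreeNode]
    site_order: np.ndarray            # permutation of the gene's site indices
    site_ids: list[str]
    codes: np.ndarray | None = None   # (n_individuals, n_sites) bits; patterns derive from it
    root_id: int = 0

    @property
    def n_individuals(self) -> int:
        return self.nodes[self.root_id].n

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def leaves(self) -> list[TreeNode]:
        return [v for v in self.nodes if v.is_leaf]

    def pattern(self, node_id: int) -> str:
        """Partial BMG at a node, in processing order: '#' where members differ."""
        v = self.nodes[node_id]
        bits = self.codes[v.members][:, self.site_order]
        out = []
        for s in range(bits.shape[1]):
            col = bits[:, s]
            out.append(str(col[0]) if (col == col[0]).all() else "#")
        return "".join(out)

    def postorder(self) -> list[int]:
        order, stack = [], [(self.root_id, False)]
        while stack:
            nid, done = stack.pop()
            if done:
                order.append(nid)
                continue
            stack.append((nid, True))
            v = self.nodes[nid]
            if not v.is_leaf:
                stack.append((v.child1, False))
                stack.append((v.child0, False))
        return order

    def leaf_assignment(self) -> np.ndarray:
        """Leaf node id for every individual."""
        out = np.empty(self.n_individuals, dtype=np.int64)
        for v in self.leaves():
            out[v.members] = v.node_id
        return out

    def parents(self) -> np.ndarray:
        par = np.full(self.n_nodes, -1, dtype=np.int64)
        for v in self.nodes:
            if not v.is_leaf:
                par[v.child0] = v.node_id
                par[v.child1] = v.node_id
        return par

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeTree):
            return NotImplemented
        if (self.gene != other.gene or self.root_id != other.root_id
                or self.site_ids != other.site_ids
                or not np.array_equal(self.site_order, other.site_order)
                or self.n_nodes != other.n_nodes):
            return False
        for a, b in zip(self.nodes, other.nodes):
            if (a.node_id != b.node_id or a.split_site != b.split_site
                    or a.child0 != b.child0 or a.child1 != b.child1
                    or not np.array_equal(a.members, b.members)):
                return False
        return True


def build_tree(b: BMGMatrix, site_order=None) -> GenotypeTree:
    """Build the lexical genotype tree for one gene.

    ``site_order`` is a permutation of the gene's site indices (default:
    storage order, i.e. genomic position).  At each site in turn, every
    current leaf whose members vary at the site is split, 0-carriers to
    ``child0`` and 1-carriers to ``child1``; node ids are assigned in
    construction (breadth-first) order.
    """
    if b.n_individuals == 0:
        raise ValueError("empty BMGMatrix")
    m = b.n_sites
    if site_order is None:
        site_order = np.arange(m)
    site_order = np.asarray(site_order, dtype=np.int64)
    if sorted(site_order.tolist()) != list(range(m)):
        raise ValueError("site_order must be a permutation of the gene's sites")

    codes = b.codes
    nodes = [TreeNode(0, np.arange(b.n_individuals))]
    frontier = [0]
    for t, s in enumerate(site_order):
        nxt = []
        for nid in frontier:
            v = nodes[nid]
            bits = codes[v.members, s]
            if bits.min() == bits.max():
                nxt.append(nid)
                continue
            c0 = TreeNode(len(nodes), v.members[bits == 0])
            nodes.append(c0)
            c1 = TreeNode(len(nodes), v.members[bits == 1])
            nodes.append(c1)
            v.split_site, v.child0, v.child1 = t, c0.node_id, c1.node_id
            nxt.extend((c0.node_id, c1.node_id))
        frontier = nxt

    return GenotypeTree(gene=b.gene, nodes=nodes, site_order=site_order,
                        site_ids=list(b.site_ids), codes=codes)


def ordering_by_frequency(b: BMGMatrix, rarest_first: bool = True) -> np.ndarray:
    """Alternative site processing order: by carrier frequency (stable ties)."""
    freq = b.codes.mean(axis=0)
    key = freq if rarest_first else -freq
    return np.argsort(key, kind="stable")


def to_json(t: GenotypeTree) -> str:
    """Serialize a tree losslessly.

    Schema: ``{gene, site_order, site_ids, nodes: [{id, pattern, n, members,
    split_site, child0, child1}]}``.
    """
    payload = {
        "gene": t.gene,
        "site_order": t.site_order.tolist(),
        "site_ids": t.site_ids,
        "nodes": [
            {
                "id": v.node_id,
                "pattern": t.pattern(v.node_id),
                "n": v.n,
                "members": v.members.tolist(),
                "split_site": v.split_site,
                "child0": v.child0,
                "child1": v.child1,
            }
            for v in t.nodes
        ],
    }
    return json.dumps(payload, indent=1)


def tree_from_json(text: str) -> GenotypeTree:
    """Inverse of :func:`to_json`; codes are rebuilt from leaf patterns."""
    payload = json.loads(text)
    nodes = [
        TreeNode(d["id"], np.asarray(d["members"], dtype=np.int64),
                 d["split_site"], d["child0"], d["child1"])
        for d in payload["nodes"]
    ]
    site_order = np.asarray(payload["site_order"], dtype=np.int64)
    n_ind = max((int(m) for d in payload["nodes"] for m in d["members"]), default=-1) + 1
    codes = np.zeros((n_ind, len(site_order)), dtype=np.uint8)
    inv = np.argsort(site_order)  # processing position of each storage site
    for d in payload["nodes"]:
        if d["child0"] is None:
            bits = np.array([int(c) for c in d["pattern"]], dtype=np.uint8)
            codes[np.asarray(d["members"], dtype=np.int64)] = bits[inv]
    return GenotypeTree(gene=payload["gene"], nodes=nodes, site_order=site_order,
                        site_ids=list(payload["site_ids"]), codes=codes)


def to_dot(t: GenotypeTree, annotations=None, highlights=None) -> str:
    """Render the tree in DOT.

    ``annotations`` maps node id -> value shown in the label (e.g. z);
    ``highlights`` maps node id -> fill colour name.
    """
    lines = ["digraph genotype_tree {", "  node [shape=box];"]
    for v in t.nodes:
        label = f"{t.pattern(v.node_id)}\\nn={v.n}"
        if annotations is not None and v.node_id in annotations:
            label += f"\\n{annotations[v.node_id]:.3g}"
        style = ""
        if highlights is not None and v.node_id in highlights:
            style = f', style=filled, fillcolor="{highlights[v.node_id]}"'
        lines.append(f'  n{v.node_id} [label="{label}"{style}];')
    for v in t.nodes:
        if not v.is_leaf:
            lines.append(f'  n{v.node_id} -> n{v.child0} [label="0"];')
            lines.append(f'  n{v.node_id} -> n{v.child1} [label="1"];')
    lines.append("}")
    return "\n".join(lines)


def export_tree(t: GenotypeTree, format: str, annotations=None) -> str:
    """Export a tree as ``"DOT"`` or ``"JSON"`` text."""
    fmt = format.upper()
    if fmt == "DOT":
        return to_dot(t, annotations=annotations)
    if fmt == "JSON":
        return to_json(t)
    raise ValueError(f"unknown export format {format!r} (use DOT or JSON)")
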