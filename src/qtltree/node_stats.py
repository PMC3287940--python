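"""Per-node partial test statistics.

Each tree node i with members j = 1..n_i gets the z score

    z_i = sqrt(n_i) * (x_bar_i - x_bar) / s,

where x_bar_i is the mean trait value over the node's members and x_bar, s
are the mean and sample (n-1) standard deviation of the trait over *all*
individuals.  Both x_bar and s depend only on the trait multiset, so they
are invariant under permutation relabelling and are computed once.  A score
transform f turns z into the non-negative quantity the scan maximizes;
the default f(z) = z^2 is sensitive in both directions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

F_SPECS = ("square", "abs", "positive_part")


@dataclass
class TraitVector:
    """A trait with its precomputed overall mean and sample sd."""

    values: np.ndarray
    mean: float
    sd: float

    @classmethod
    def from_values(cls, values) -> "TraitVector":
        values = np.asarray(values, dtype=float)
        if values.ndim != 1 or len(values) < 2:
            raise ValueError("trait must be a 1-d vector of length >= 2")
        if not np.all(np.isfinite(values)):
            raise ValueError("trait contains non-finite values")
        sd = float(values.std(ddof=1))
        if sd == 0.0:
            raise ValueError("degenerate trait: zero variance")
        return cls(values=values, mean=float(values.mean()), sd=sd)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class NodeStat:
    node_id: int
    n: int
    node_mean: float
    z: float
    score: float


def node_z(members, trait: TraitVector) -> float:
    """z score of one node's trait mean against the overall mean."""
    members = np.asarray(members)
    if len(members) == 0:
        raise ValueError("node has no members")
    n_i = len(members)
    return float(np.sqrt(n_i) * (trait.values[members].mean() - trait.mean) / trait.sd)


def transform_scores(z, f_spec: str = "square"):
    """Apply the score transform f to z values (scalar or array)."""
    z = np.asarray(z, dtype=float)
    if f_spec == "square":
        out = z ** 2
    elif f_spec == "abs":
        out = np.abs(z)
    elif f_spec == "positive_part":
        out = np.maximum(z, 0.0) ** 2
    else:
        raise ValueError(f"unknown f_spec {f_spec!r} (use one of {F_SPECS})")
    return out if out.ndim else float(out)


def compute_node_stats(tree, trait: TraitVector, f_spec: str = "square") -> list[NodeStat]:
    """Score every node of a tree.

    Node trait sums are aggregated bottom-up (leaf sums added into parents),
    so a re-scoring under a permuted trait costs time linear in the number
    of nodes — the property the permutation engine relies on.
    """
    if len(trait) != tree.n_individuals:
        raise ValueError(f"trait length {len(trait)} != {tree.n_individuals} individuals")
    sums = np.zeros(tree.n_nodes)
    for nid in tree.postorder():
        v = tree.nodes[nid]
        if v.is_leaf:
            sums[nid] = trait.values[v.members].sum()
        else:
            sums[nid] = sums[v.child0] + sums[v.child1]
    out = []
    for v in tree.nodes:
        mean_i = sums[v.node_id] / v.n
        z = np.sqrt(v.n) * (mean_i - trait.mean) / trait.sd
        out.append(NodeStat(v.node_id, v.n, float(mean_i), float(z),
                            float(transform_scores(z, f_spec))))
    return out
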