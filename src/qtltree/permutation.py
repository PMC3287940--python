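"""Significance by within-population permutation, and the per-gene scan.

The null distribution of S_k is not available analytically, so p-values are
estimated by randomly relabelling trait values *within* each population
stratum.  This preserves every population's trait mean and standard
deviation exactly across replicates, which protects the test against simple
between-population trait differences; a plain (unstratified) shuffle would
destroy them and inflate type-I error in structured samples.

The genotype tree is fixed under the null, so each replicate only re-scores
nodes.  Replicates are processed in vectorized batches: per-leaf trait sums
come from one matrix product, internal sums from child additions in
post-order, and the disjoint-node dynamic program runs on whole batches at
once.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bmg_tree import GenotypeTree, build_tree
from .disjoint_scan import ScanStatistics, best_disjoint
from .genotype_io import GenotypeMatrix, PhenotypeTable, recode_to_bmg
from .node_stats import TraitVector, transform_scores

log = logging.getLogger(__name__)


@dataclass
class PermutationResult:
    gene: str
    n_reps: int
    observed: ScanStatistics
    p_values: np.ndarray  # p_1..p_k, add-one estimator
    seed: int | None
    degenerate: bool = False


class TreeScorer:
    """Batch re-scoring of a fixed tree under many trait relabellings."""

    def __init__(self, tree: GenotypeTree):
        self.tree = tree
        self.n_nodes = tree.n_nodes
        self.n_ind = tree.n_individuals
        leaves = tree.leaves()
        self.leaf_ids = np.array([v.node_id for v in leaves], dtype=np.int64)
        # individuals x leaves membership for the leaf-sum matrix product
        self.membership = np.zeros((self.n_ind, len(leaves)))
        for col, v in enumerate(leaves):
            self.membership[v.members, col] = 1.0
        self.n_i = np.array([v.n for v in tree.nodes], dtype=np.int64)
        self.postorder = tree.postorder()
        self.internal = [(nid, tree.nodes[nid].child0, tree.nodes[nid].child1)
                         for nid in self.postorder if not tree.nodes[nid].is_leaf]
        self.children = {nid: (c0, c1) for nid, c0, c1 in self.internal}

    def node_sums(self, traits: np.ndarray) -> np.ndarray:
        """(R, n_individuals) traits -> (R, n_nodes) member trait sums."""
        sums = np.empty((traits.shape[0], self.n_nodes))
        sums[:, self.leaf_ids] = traits @ self.membership
        for nid, c0, c1 in self.internal:
            sums[:, nid] = sums[:, c0] + sums[:, c1]
        return sums

    def node_z(self, traits: np.ndarray, mean: float, sd: float) -> np.ndarray:
        """z at every node for every replicate: (sum - n*mean)/(sd*sqrt(n))."""
        sums = self.node_sums(traits)
        return (sums - self.n_i * mean) / (sd * np.sqrt(self.n_i))

    def scan(self, traits: np.ndarray, mean: float, sd: float, k: int,
             f_spec: str = "square") -> np.ndarray:
        """S_1..S_k for each replicate trait vector; returns (R, k)."""
        scores = transform_scores(self.node_z(traits, mean, sd), f_spec)
        R = scores.shape[0]
        best = np.zeros((self.n_nodes, k + 1, R))
        for nid in self.postorder:
            own = scores[:, nid]
            if nid not in self.children:
                best[nid, 1:, :] = np.maximum(own, 0.0)
            else:
                c0, c1 = self.children[nid]
                b0, b1 = best[c0], best[c1]
                for m in range(1, k + 1):
                    cc = b0[m] + b1[0]
                    for m0 in range(0, m):
                        np.maximum(cc, b0[m0] + b1[m - m0], out=cc)
                    best[nid, m] = np.maximum(cc, own)
        return best[self.tree.root_id, 1:, :].T


def stratified_permutation(trait, strata, rng: np.random.Generator) -> np.ndarray:
    """Relabel trait values uniformly at random within each stratum.

    The multiset of values inside every stratum is preserved exactly; no
    value crosses a stratum boundary.  Singleton strata are fixed points.
    """
    values = np.asarray(trait, dtype=float)
    strata = np.asarray(strata)
    if len(strata) != len(values):
        raise ValueError("strata labels must match trait length")
    out = values.copy()
    singletons = 0
    for lab in pd.unique(strata):
        idx = np.flatnonzero(strata == lab)
        if len(idx) == 1:
            singletons += 1
            continue
        out[idx] = values[idx][rng.permutation(len(idx))]
    if singletons:
        log.debug("%d singleton strata left fixed", singletons)
    return out


def _strata_indices(strata, n: int) -> list[np.ndarray]:
    if strata is None:
        return [np.arange(n)]
    strata = np.asarray(strata)
    if len(strata) != n:
        raise ValueError("strata labels must match trait length")
    return [np.flatnonzero(strata == lab) for lab in pd.unique(strata)]


def _permuted_batch(values: np.ndarray, groups: list[np.ndarray], R: int,
                    rng: np.random.Generator) -> np.ndarray:
    out = np.tile(values, (R, 1))
    for idx in groups:
        if len(idx) < 2:
            continue
        order = np.argsort(rng.random((R, len(idx))), axis=1)
        out[:, idx] = values[idx][order]
    return out


def permutation_test(tree: GenotypeTree, trait, strata=None, k: int = 10,
                     f_spec: str = "square", n_reps: int = 999,
                     seed: int | None = None, rng: np.random.Generator | None = None,
                     batch_size: int = 2000) -> PermutationResult:
    """Permutation p-values for S_1..S_k on one gene's tree.

    The tree is built once from the genotypes; every replicate re-scores its
    nodes under a within-stratum relabelling of the trait.  p_j uses the
    add-one estimator (1 + #{S_j* >= S_j}) / (n_reps + 1), so p is never 0
    and its minimum is 1/(n_reps + 1).  Deterministic given ``seed``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    tv = trait if isinstance(trait, TraitVector) else TraitVector.from_values(trait)
    if len(tv) != tree.n_individuals:
        raise ValueError("trait length does not match tree individuals")
    if rng is None:
        rng = np.random.default_rng(seed)

    scorer = TreeScorer(tree)
    s_obs = scorer.scan(tv.values[None, :], tv.mean, tv.sd, k, f_spec)[0]

    groups = _strata_indices(strata, len(tv))
    exceed = np.zeros(k, dtype=np.int64)
    done = 0
    while done < n_reps:
        R = min(batch_size, n_reps - done)
        perms = _permuted_batch(tv.values, groups, R, rng)
        s_rep = scorer.scan(perms, tv.mean, tv.sd, k, f_spec)
        exceed += (s_rep >= s_obs).sum(axis=0)
        done += R
    p = (1.0 + exceed) / (n_reps + 1.0)

    # exact antichains for reporting (same S up to fp round-off)
    z = scorer.node_z(tv.values[None, :], tv.mean, tv.sd)[0]
    observed = best_disjoint(tree, transform_scores(z, f_spec), k)
    observed.S = s_obs
    return PermutationResult(gene=tree.gene, n_reps=n_reps, observed=observed,
                             p_values=p, seed=seed)


def gene_seed(master_seed: int, gene: str) -> np.random.SeedSequence:
    """Deterministic per-gene RNG substream from the master seed."""
    digest = int.from_bytes(hashlib.sha256(gene.encode()).digest()[:4], "big")
    return np.random.SeedSequence([int(master_seed), digest])


def _degenerate_row(gene, n_sites, k, seed):
    return {"gene": gene, "n_sites": n_sites, "n_leaves": 1,
            **{f"S_{j}": 0.0 for j in range(1, k + 1)},
            **{f"p_{j}": 1.0 for j in range(1, k + 1)},
            "best_set": "", "degenerate": True, "seed": seed}


def _scan_one(g: GenotypeMatrix, gene: str, values, strata, k, f_spec, n_reps,
              master_seed, polarize, missing_policy):
    bmg = recode_to_bmg(g, gene, polarize=polarize, missing_policy=missing_policy)
    if bmg.distinct_codes() < 2:
        return _degenerate_row(gene, bmg.n_sites, k, master_seed)
    tree = build_tree(bmg)
    rng = np.random.default_rng(gene_seed(master_seed, gene))
    res = permutation_test(tree, values, strata=strata, k=k, f_spec=f_spec,
                           n_reps=n_reps, rng=rng)
    row = {"gene": gene, "n_sites": bmg.n_sites, "n_leaves": len(tree.leaves())}
    for j in range(1, k + 1):
        row[f"S_{j}"] = float(res.observed.S[j - 1])
    for j in range(1, k + 1):
        row[f"p_{j}"] = float(res.p_values[j - 1])
    row["best_set"] = ";".join(str(i) for i in res.observed.best_sets[k - 1])
    row["degenerate"] = False
    row["seed"] = master_seed
    return row


def scan_genes(g: GenotypeMatrix, phenotypes: PhenotypeTable | None, trait_name=None,
               trait=None, strata="population", k: int = 10, f_spec: str = "square",
               n_reps: int = 999, seed: int = 0, genes=None, polarize: bool = False,
               missing_policy: str = "as_common", n_jobs: int = 1) -> pd.DataFrame:
    """Run the permutation scan over every gene.

    Trait and strata come from ``phenotypes`` (aligned to the genotype
    matrix) unless given directly as arrays; ``strata=None`` disables
    stratification.  Per-gene RNG substreams derive from ``seed`` and the
    gene label, so results are independent of gene evaluation order and of
    ``n_jobs``.  Genes whose BMGs show no variation are flagged degenerate
    with S = 0 and p = 1.
    """
    if trait is None:
        if phenotypes is None or trait_name is None:
            raise ValueError("provide either a trait array or phenotypes + trait_name")
        phenotypes = phenotypes.aligned_to(g)
        trait = phenotypes.trait(trait_name)
    values = np.asarray(trait, dtype=float)
    if isinstance(strata, str):
        if strata == "population":
            strata_vals = (phenotypes.population if phenotypes is not None
                           else g.individual_population)
        else:
            strata_vals = phenotypes.data[strata].to_numpy(dtype=object)
    else:
        strata_vals = strata

    gene_list = list(genes) if genes is not None else g.genes()
    if not gene_list:
        raise ValueError("no genes to scan")

    if n_jobs != 1:
        from joblib import Parallel, delayed
        rows = Parallel(n_jobs=n_jobs)(
            delayed(_scan_one)(g, gene, values, strata_vals, k, f_spec, n_reps,
                               seed, polarize, missing_policy)
            for gene in gene_list)
    else:
        rows = [_scan_one(g, gene, values, strata_vals, k, f_spec, n_reps,
                          seed, polarize, missing_policy)
                for gene in gene_list]
    n_degen = sum(r["degenerate"] for r in rows)
    if n_degen:
        log.info("%d of %d genes degenerate (no BMG variation)", n_degen, len(rows))
    return pd.DataFrame(rows)


def bonferroni_threshold(alpha: float, n_genes: int) -> float:
    """Per-gene significance threshold alpha / n_genes."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    return alpha / n_genes


def write_scan_tsv(df: pd.DataFrame, path, seed: int, header_extra: str = "") -> None:
    """Write the scan table with a provenance header (version, seed)."""
    from . import __version__
    with open(path, "w") as fh:
        fh.write(f"# qtltree {__version__} seed={seed}")
        if header_extra:
            fh.write(f" {header_extra}")
        fh.write("\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")
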