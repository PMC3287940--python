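"""Structured-population genotype/phenotype simulator with known truth.

Generates mini-exome-like datasets for calibration, power and confound
studies: several populations, many rare variants per gene, covariate
effects on the trait, optional causal genes acting through carrier
indicators, and an optional heterozygosity-trait confound.

Population structure follows the Balding-Nichols construction: each site
draws an ancestral frequency p from a rare-skewed Beta spectrum, and each
population's frequency from Beta(p(1-F)/F, (1-p)(1-F)/F), so F controls
the between-population allele-frequency spread.  Diploid genotypes are
Binomial(2, population frequency).

The confound emulates a genotype-calling artifact of uneven sequencing
coverage: each individual has a heterozygote dropout rate d_i, and a true
heterozygote is observed as homozygous-reference with probability d_i.
Individuals with low dropout therefore show more variants genome-wide, the
observed heterozygosity axis becomes a leading principal component of the
allele counts, and a trait term proportional to standardized observed
heterozygosity plants a trait-heterozygosity correlation that within
population permutation cannot remove — but PC residualization can.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, PhenotypeTable

log = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """Study design for one simulated dataset.

    Defaults emulate a mini-exome sample of unrelated individuals drawn
    from seven populations (~700 individuals, ~7 rare variants per gene),
    with a modest age effect on the trait and no genetic or heterozygosity
    signal unless requested.
    """

    n_populations: int = 7
    n_per_population: int = 100
    n_genes: int = 100
    sites_per_gene: int = 7
    fst: float = 0.05                 # Balding-Nichols F
    spectrum_a: float = 0.5           # Beta shape of the ancestral frequency
    spectrum_b: float = 8.0           #   spectrum (rare-variant skew)
    maf_floor: float = 0.001
    n_causal_genes: int = 0
    causal_sites_per_gene: int = 4
    beta: float = 0.5                 # per-variant carrier effect, trait-sd units
    age_mean: float = 45.0
    age_sd: float = 12.0
    age_pop_sd: float = 5.0           # between-population spread of mean age
    sex_p: float = 0.5
    smoke_p: float = 0.25
    age_beta: float = 0.02            # trait slope per year of (Age - age_mean)
    sex_beta: float = 0.0
    smoke_beta: float = 0.25
    population_shift: tuple | None = None  # explicit per-population trait shifts
    gamma_het: float = 0.0            # trait loading on standardized observed het
    het_dropout_max: float = 0.0      # d_i ~ Uniform(0, max)
    noise_sd: float = 1.0
    trait_name: str = "Q1"
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_populations, self.n_per_population, self.n_genes,
               self.sites_per_gene) < 1:
            raise ValueError("all counts must be positive")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("fst must be in [0, 1)")
        for p in (self.sex_p, self.smoke_p, self.het_dropout_max):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.population_shift is not None and \
                len(self.population_shift) != self.n_populations:
            raise ValueError("population_shift length must equal n_populations")
        if self.n_causal_genes > self.n_genes:
            raise ValueError("more causal genes than genes")


@dataclass
class SimTruth:
    causal_effects: dict            # gene -> {site_id: beta}
    het_trait_correlation: float    # realized Pearson r(trait, observed het)
    population_shift: list


@dataclass
class SimulatedDataset:
    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable
    truth: SimTruth


def _gene_genotypes(rng, cfg, n_per_pop) -> np.ndarray:
    """Draw one gene's true diploid counts under Balding-Nichols."""
    S = cfg.sites_per_gene
    p = np.clip(rng.beta(cfg.spectrum_a, cfg.spectrum_b, size=S), cfg.maf_floor, 0.5)
    blocks = []
    for _ in range(cfg.n_populations):
        if cfg.fst > 0:
            a = p * (1 - cfg.fst) / cfg.fst
            b = (1 - p) * (1 - cfg.fst) / cfg.fst
            pk = np.clip(rng.beta(a, b), 0.0, 1.0)
        else:
            pk = p
        blocks.append(rng.binomial(2, pk, size=(n_per_pop, S)))
    return np.concatenate(blocks, axis=0).astype(np.int8)


def simulate(config: SimulationConfig, seed: int | None = None) -> SimulatedDataset:
    """Generate one dataset; deterministic given the seed.

    A causal gene whose chosen sites have no true carrier is regenerated
    (bounded retries, logged) so configured effects are always realizable.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n_populations * cfg.n_per_population
    pops = np.repeat([f"pop{k + 1}" for k in range(cfg.n_populations)],
                     cfg.n_per_population).astype(object)
    individual_ids = [f"IND{i + 1:05d}" for i in range(n)]
    gene_labels = [f"GENE{j + 1:04d}" for j in range(cfg.n_genes)]

    causal_genes = sorted(rng.choice(cfg.n_genes, size=cfg.n_causal_genes,
                                     replace=False).tolist())
    causal_set = set(causal_genes)

    true_counts = np.empty((n, cfg.n_genes * cfg.sites_per_gene), dtype=np.int8)
    causal_effects: dict[str, dict[str, float]] = {}
    genetic = np.zeros(n)
    for j in range(cfg.n_genes):
        gt = _gene_genotypes(rng, cfg, cfg.n_per_population)
        if j in causal_set:
            n_c = min(cfg.causal_sites_per_gene, cfg.sites_per_gene)
            for attempt in range(20):
                sites = np.sort(rng.choice(cfg.sites_per_gene, size=n_c, replace=False))
                if (gt[:, sites] > 0).any():
                    break
                log.info("gene %s monomorphic at causal sites; regenerating (attempt %d)",
                         gene_labels[j], attempt + 1)
                gt = _gene_genotypes(rng, cfg, cfg.n_per_population)
            else:
                raise RuntimeError(f"could not realize carriers for causal gene {gene_labels[j]}")
            effects = {}
            for s in sites:
                carrier = (gt[:, s] > 0).astype(float)
                genetic += cfg.beta * carrier
                effects[f"{gene_labels[j]}_s{s + 1}"] = cfg.beta
            causal_effects[gene_labels[j]] = effects
        true_counts[:, j * cfg.sites_per_gene:(j + 1) * cfg.sites_per_gene] = gt

    # coverage-like heterozygote dropout
    observed = true_counts.copy()
    if cfg.het_dropout_max > 0:
        d = rng.uniform(0.0, cfg.het_dropout_max, size=n)
        drop = (true_counts == 1) & (rng.random(true_counts.shape) < d[:, None])
        observed[drop] = 0

    het_obs = (observed == 1).mean(axis=1)
    het_std = (het_obs - het_obs.mean())
    sd = het_std.std(ddof=1)
    het_std = het_std / sd if sd > 0 else het_std * 0.0

    age_mu = cfg.age_mean + rng.normal(0.0, cfg.age_pop_sd, size=cfg.n_populations)
    age = rng.normal(np.repeat(age_mu, cfg.n_per_population), cfg.age_sd)
    sex = rng.binomial(1, cfg.sex_p, size=n)
    smoke = rng.binomial(1, cfg.smoke_p, size=n)
    shift = (np.zeros(cfg.n_populations) if cfg.population_shift is None
             else np.asarray(cfg.population_shift, dtype=float))
    trait = (cfg.age_beta * (age - cfg.age_mean) + cfg.sex_beta * sex
             + cfg.smoke_beta * smoke + np.repeat(shift, cfg.n_per_population)
             + genetic + cfg.gamma_het * het_std
             + rng.normal(0.0, cfg.noise_sd, size=n))

    site_ids = [f"{g}_s{s + 1}" for g in gene_labels for s in range(cfg.sites_per_gene)]
    positions = np.concatenate([
        (j + 1) * 100_000 + 100 * np.arange(1, cfg.sites_per_gene + 1)
        for j in range(cfg.n_genes)])
    site_genes = np.repeat(gene_labels, cfg.sites_per_gene).astype(object)

    gmat = GenotypeMatrix(counts=observed, site_ids=site_ids, site_positions=positions,
                          site_genes=site_genes, individual_ids=individual_ids,
                          individual_population=pops)
    pheno = PhenotypeTable(pd.DataFrame({
        "population": pops, cfg.trait_name: trait,
        "Age": age, "Sex": sex, "Smoke": smoke,
    }, index=pd.Index(individual_ids, name="id")))
    r = float(np.corrcoef(trait, het_obs)[0, 1]) if het_obs.std() > 0 else 0.0
    truth = SimTruth(causal_effects=causal_effects, het_trait_correlation=r,
                     population_shift=list(np.asarray(shift, dtype=float)))
    return SimulatedDataset(genotypes=gmat, phenotypes=pheno, truth=truth)


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write the genotype matrix as a minimal VCF v4.2 (GT field only)."""
    code = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.individual_ids) + "\n")
        for s in range(g.n_sites):
            gts = "\t".join(code[int(c)] for c in g.counts[:, s])
            fh.write(f"1\t{g.site_positions[s]}\t{g.site_ids[s]}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


def write_dataset(d: SimulatedDataset, out_dir) -> dict[str, str]:
    """Emit VCF + gene map TSV + phenotype TSV + truth JSON; returns paths."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "vcf": os.path.join(out_dir, "genotypes.vcf"),
        "gene_map": os.path.join(out_dir, "genes.tsv"),
        "phenotypes": os.path.join(out_dir, "phenotypes.tsv"),
        "truth": os.path.join(out_dir, "truth.json"),
    }
    g = d.genotypes
    write_vcf(g, paths["vcf"])
    pd.DataFrame({"gene": g.site_genes, "site_id": g.site_ids}).to_csv(
        paths["gene_map"], sep="\t", index=False)
    d.phenotypes.data.to_csv(paths["phenotypes"], sep="\t", index_label="id",
                             float_format="%.10g")
    with open(paths["truth"], "w") as fh:
        json.dump({
            "causal_genes": sorted(d.truth.causal_effects),
            "causal_effects": d.truth.causal_effects,
            "het_trait_correlation": d.truth.het_trait_correlation,
            "population_shift": d.truth.population_shift,
        }, fh, indent=1)
    return paths
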