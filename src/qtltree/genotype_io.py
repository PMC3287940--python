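"""Genotype and phenotype input, and collapsing to binary multilocus genotypes.

The scan operates on *binary multilocus genotypes* (BMGs): within a gene each
individual's diploid allele counts (0/1/2 copies of the non-common allele) are
collapsed site-by-site to a single bit — 0 if the individual is homozygous for
the common allele, 1 otherwise.  Carriers of one or two copies of a rare
variant are thereby pooled, which suits rare-variant analysis where homozygous
carriers are essentially absent and phasing is unreliable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: sentinel for a missing (no-call) genotype in a GenotypeMatrix
MISSING = -1


@dataclass
class GenotypeMatrix:
    """Individuals x sites matrix of alternate-allele counts with metadata.

    ``counts[i, s]`` is the number of non-reference alleles (0, 1 or 2)
    carried by individual ``i`` at site ``s``; ``MISSING`` (-1) marks a
    no-call.  Sites carry a gene label and a 1-based genomic position; within
    a gene, sites are ordered by strictly increasing position.
    """

    counts: np.ndarray
    site_ids: list[str]
    site_positions: np.ndarray
    site_genes: np.ndarray
    individual_ids: list[str]
    individual_population: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int8)
        self.site_positions = np.asarray(self.site_positions, dtype=np.int64)
        self.site_genes = np.asarray(self.site_genes, dtype=object)
        self.individual_population = np.asarray(self.individual_population, dtype=object)
        n, m = self.counts.shape
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length does not match genotype rows")
        if not (len(self.site_ids) == len(self.site_positions) == len(self.site_genes) == m):
            raise ValueError("site metadata length does not match genotype columns")
        if len(set(self.individual_ids)) != n:
            raise ValueError("individual ids are not unique")
        if any(p is None or str(p) == "" for p in self.individual_population):
            raise ValueError("population labels must be non-empty")
        bad = ~np.isin(self.counts, (0, 1, 2, MISSING))
        if bad.any():
            i, s = np.argwhere(bad)[0]
            raise ValueError(
                f"allele count out of range at individual {self.individual_ids[i]!r}, "
                f"site {self.site_ids[s]!r}: {self.counts[i, s]}"
            )
        for gene in self.genes():
            pos = self.site_positions[self.sites_for(gene)]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"site positions within gene {gene!r} not strictly increasing")

    @property
    def n_individuals(self) -> int:
        return self.counts.shape[0]

    @property
    def n_sites(self) -> int:
        return self.counts.shape[1]

    def genes(self) -> list[str]:
        """Gene labels in first-appearance order."""
        seen: dict[str, None] = {}
        for g in self.site_genes:
            seen.setdefault(g, None)
        return list(seen)

    def sites_for(self, gene: str) -> np.ndarray:
        """Column indices belonging to ``gene``."""
        return np.flatnonzero(self.site_genes == gene)


@dataclass
class BMGMatrix:
    """Per-gene binary multilocus genotypes: one bit per variant site."""

    gene: str
    codes: np.ndarray  # (n_individuals, n_gene_sites) uint8
    site_ids: list[str]

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.uint8)
        if not np.isin(self.codes, (0, 1)).all():
            raise ValueError("BMG codes must be 0/1")
        if self.codes.shape[1] != len(self.site_ids):
            raise ValueError("codes width does not match site_ids")

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.codes.shape[1]

    def distinct_codes(self) -> int:
        return len({row.tobytes() for row in self.codes})


@dataclass
class PhenotypeTable:
    """Traits, covariates and population labels keyed by individual id.

    ``data`` is indexed by individual id and must carry a ``population``
    column; remaining columns are traits and covariates (Age, Sex, Smoke, PC
    loadings, ...).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if "population" not in self.data.columns:
            raise ValueError("phenotype table must have a 'population' column")
        if not self.data.index.is_unique:
            raise ValueError("individual ids are not unique")

    @property
    def individual_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def population(self) -> np.ndarray:
        return self.data["population"].to_numpy(dtype=object)

    def trait(self, name: str) -> np.ndarray:
        v = self.data[name].to_numpy(dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError(f"trait {name!r} contains non-finite values")
        return v

    def aligned_to(self, g: GenotypeMatrix) -> "PhenotypeTable":
        """Explicit join: reorder rows to the genotype matrix's individuals.

        Rows without genotypes are dropped (count logged); genotyped
        individuals missing from the table raise.
        """
        missing = [i for i in g.individual_ids if i not in self.data.index]
        if missing:
            raise ValueError(f"{len(missing)} genotyped individuals missing from phenotype table "
                             f"(first: {missing[0]!r})")
        extra = len(self.data.index.difference(g.individual_ids))
        if extra:
            log.info("dropping %d phenotype rows without genotypes", extra)
        return PhenotypeTable(self.data.loc[g.individual_ids])


def load_gene_map(path) -> pd.DataFrame:
    """Load a gene map TSV.

    Two layouts are accepted: site lists with columns ``gene, site_id`` and
    BED-like intervals with columns ``gene, chrom, start, end`` (1-based,
    inclusive).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = set(df.columns)
    if {"gene", "site_id"} <= cols:
        return df[["gene", "site_id"]]
    if {"gene", "chrom", "start", "end"} <= cols:
        out = df[["gene", "chrom", "start", "end"]].copy()
        out["start"] = out["start"].astype(int)
        out["end"] = out["end"].astype(int)
        return out
    raise ValueError("gene map needs columns (gene, site_id) or (gene, chrom, start, end)")


def _gene_for_sites(gene_map: pd.DataFrame, site_ids, chroms, positions) -> np.ndarray:
    """Resolve the gene label (or None) for each site from a loaded gene map."""
    genes = np.full(len(site_ids), None, dtype=object)
    if "site_id" in gene_map.columns:
        lookup = dict(zip(gene_map["site_id"], gene_map["gene"]))
        for j, (sid, chrom, pos) in enumerate(zip(site_ids, chroms, positions)):
            genes[j] = lookup.get(sid, lookup.get(f"{chrom}:{pos}"))
    else:
        by_chrom: dict[str, list[tuple[int, int, str]]] = {}
        for _, row in gene_map.iterrows():
            by_chrom.setdefault(str(row["chrom"]), []).append(
                (int(row["start"]), int(row["end"]), row["gene"]))
        for j, (chrom, pos) in enumerate(zip(chroms, positions)):
            for start, end, gene in by_chrom.get(str(chrom), ()):
                if start <= pos <= end:
                    genes[j] = gene
                    break
    return genes


def read_vcf(path, gene_map) -> GenotypeMatrix:
    """Read diploid genotypes from a VCF into a GenotypeMatrix.

    Any non-reference allele counts as alternate, so a 1/2 genotype at a
    multi-allelic site yields allele count 2.  Sites not assigned to a gene
    by ``gene_map`` are dropped (count logged).
    """
    from cyvcf2 import VCF

    if not isinstance(gene_map, pd.DataFrame):
        gene_map = load_gene_map(gene_map)

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad files
        raise ValueError(f"malformed VCF {path}: {exc}") from exc
    individual_ids = list(vcf.samples)

    rows, site_ids, chroms, positions = [], [], [], []
    for variant in vcf:
        gts = variant.genotypes  # [[a0, a1, phased], ...]
        counts = np.empty(len(individual_ids), dtype=np.int8)
        for i, gt in enumerate(gts):
            a = [x for x in gt[:-1]]
            if not a or a[0] < 0:
                counts[i] = MISSING
            else:
                counts[i] = sum(1 for x in a if x > 0)
        rows.append(counts)
        sid = variant.ID if variant.ID not in (None, ".") else f"{variant.CHROM}:{variant.POS}"
        site_ids.append(sid)
        chroms.append(variant.CHROM)
        positions.append(variant.POS)
    if not rows:
        raise ValueError(f"no variant records in {path}")

    genes = _gene_for_sites(gene_map, site_ids, chroms, positions)
    keep = np.flatnonzero([g is not None for g in genes])
    dropped = len(site_ids) - len(keep)
    if dropped:
        log.info("dropping %d sites not mapped to any gene", dropped)
    if len(keep) == 0:
        raise ValueError("no sites mapped to any gene")

    counts = np.stack(rows, axis=1)[:, keep]
    site_ids = [site_ids[j] for j in keep]
    positions = np.asarray(positions)[keep]
    genes = genes[keep]

    # order sites by (gene first-appearance, position) so per-gene positions increase
    gene_rank = {g: r for r, g in enumerate(dict.fromkeys(genes))}
    order = np.lexsort((positions, [gene_rank[g] for g in genes]))
    log.info("read %d individuals x %d mapped sites from %s",
             counts.shape[0], len(keep), path)
    return GenotypeMatrix(
        counts=counts[:, order],
        site_ids=[site_ids[j] for j in order],
        site_positions=positions[order],
        site_genes=genes[order],
        individual_ids=individual_ids,
        individual_population=np.array(["all"] * len(individual_ids), dtype=object),
    )


def read_genotype_tsv(path, gene_map=None, populations=None) -> GenotypeMatrix:
    """Read a TSV allele-count matrix: header of site ids, one row per individual.

    First column holds individual ids; entries are 0/1/2 or NA.  Without a
    gene map all sites form a single gene in column order.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed genotype TSV {path}: {exc}") from exc
    if df.isnull().all(axis=None):
        raise ValueError(f"empty genotype TSV {path}")

    site_ids = [str(c) for c in df.columns]
    counts = np.full(df.shape, MISSING, dtype=np.int8)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            v = str(raw).strip()
            if v in ("NA", "nan", "", "."):
                continue
            if v not in ("0", "1", "2"):
                raise ValueError(f"invalid allele count {raw!r} at row {i + 2} column {col!r}")
            counts[i, j] = int(v)

    if gene_map is not None:
        if not isinstance(gene_map, pd.DataFrame):
            gene_map = load_gene_map(gene_map)
        genes = _gene_for_sites(gene_map, site_ids, [""] * len(site_ids), [0] * len(site_ids))
        keep = np.flatnonzero([g is not None for g in genes])
        if len(keep) == 0:
            raise ValueError("no sites mapped to any gene")
        if len(keep) < len(site_ids):
            log.info("dropping %d unmapped sites", len(site_ids) - len(keep))
        counts = counts[:, keep]
        site_ids = [site_ids[j] for j in keep]
        genes = genes[keep]
    else:
        genes = np.array(["gene1"] * len(site_ids), dtype=object)

    individual_ids = [str(i) for i in df.index]
    if populations is None:
        populations = ["all"] * len(individual_ids)
    log.info("read %d individuals x %d sites from %s", counts.shape[0], counts.shape[1], path)

    # positions: per-gene column order (1, 2, ...) — the TSV carries no coordinates
    positions = np.zeros(len(site_ids), dtype=np.int64)
    counters: dict[str, int] = {}
    for j, g in enumerate(genes):
        counters[g] = counters.get(g, 0) + 1
        positions[j] = counters[g]
    return GenotypeMatrix(counts, site_ids, positions, genes, individual_ids,
                          np.asarray(populations, dtype=object))


def read_phenotype_tsv(path) -> PhenotypeTable:
    """Read a phenotype TSV with columns id, population, traits/covariates."""
    df = pd.read_csv(path, sep="\t")
    if "id" not in df.columns:
        raise ValueError("phenotype TSV must have an 'id' column")
    df = df.set_index("id")
    df.index = df.index.astype(str)
    return PhenotypeTable(df)


def recode_to_bmg(g: GenotypeMatrix, gene: str, polarize: bool = False,
                  missing_policy: str = "as_common") -> BMGMatrix:
    """Collapse a gene's allele counts to binary multilocus genotypes.

    A bit is 0 iff the individual is homozygous for the common allele at the
    site, else 1.  By default the reference allele is taken as common; with
    ``polarize=True`` the sample-major allele is (ties keep the reference).

    missing_policy:
        ``as_common`` — missing genotypes code as 0 (count logged);
        ``error`` — raise, naming the first offending site and individual.
    """
    if missing_policy not in ("as_common", "error"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    sites = g.sites_for(gene)
    if len(sites) == 0:
        raise ValueError(f"gene {gene!r} has no sites")
    sub = g.counts[:, sites]

    miss = sub == MISSING
    if miss.any():
        if missing_policy == "error":
            i, s = np.argwhere(miss)[0]
            raise ValueError(
                f"missing genotype for individual {g.individual_ids[i]!r} at site "
                f"{g.site_ids[sites[s]]!r} (gene {gene!r})")
        log.info("gene %s: %d missing genotypes coded as common", gene, int(miss.sum()))

    if polarize:
        codes = np.zeros_like(sub, dtype=np.uint8)
        for s in range(sub.shape[1]):
            col = sub[:, s]
            ok = col != MISSING
            alt_count = int(col[ok].sum())
            # alternate allele is "common" only on a strict majority of alleles
            if alt_count > ok.sum():  # > 2*n_ok/2
                codes[:, s] = np.where(ok, col != 2, 0)
            else:
                codes[:, s] = np.where(ok, col != 0, 0)
    else:
        codes = ((sub != 0) & ~miss).astype(np.uint8)

    return BMGMatrix(gene=gene, codes=codes, site_ids=[g.site_ids[j] for j in sites])
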