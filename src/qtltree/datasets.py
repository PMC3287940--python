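"""Small built-in example data.

A classic four-site worked example: 100 individuals whose diploid allele
counts collapse to six distinct binary multilocus genotype codes.  Where a
code groups several allele-count genotypes (e.g. 0-0-1-0 and 0-0-2-0 both
code to 0-0-1-0), one individual is placed on each non-canonical row and
the remainder on the canonical one — the recoding and the resulting tree
are invariant to that choice.
"""

from __future__ import annotations

import numpy as np

from .genotype_io import GenotypeMatrix

# (allele-count genotype, count); totals per code: 45, 15, 17, 6, 13, 4 = 100
EXAMPLE_ALLELE_COUNTS = [
    ((0, 0, 0, 0), 45),
    ((0, 0, 0, 1), 15),
    ((0, 0, 1, 0), 16),
    ((0, 0, 2, 0), 1),
    ((0, 0, 1, 1), 3),
    ((0, 0, 1, 2), 1),
    ((0, 0, 2, 1), 1),
    ((0, 0, 2, 2), 1),
    ((0, 1, 0, 0), 12),
    ((0, 2, 0, 0), 1),
    ((1, 0, 0, 0), 4),
]

#: the six distinct BMG codes and their expected multiplicities
EXAMPLE_CODE_COUNTS = {
    (0, 0, 0, 0): 45,
    (0, 0, 0, 1): 15,
    (0, 0, 1, 0): 17,
    (0, 0, 1, 1): 6,
    (0, 1, 0, 0): 13,
    (1, 0, 0, 0): 4,
}


def example_genotypes(gene: str = "GENE1") -> GenotypeMatrix:
    """The 100-individual, four-site worked example as a GenotypeMatrix."""
    rows = []
    for genotype, count in EXAMPLE_ALLELE_COUNTS:
        rows.extend([genotype] * count)
    counts = np.asarray(rows, dtype=np.int8)
    n = counts.shape[0]
    return GenotypeMatrix(
        counts=counts,
        site_ids=[f"{gene}_s{j}" for j in range(1, 5)],
        site_positions=np.array([101, 205, 309, 412]),
        site_genes=np.array([gene] * 4, dtype=object),
        individual_ids=[f"S{i + 1:03d}" for i in range(n)],
        individual_population=np.array(["all"] * n, dtype=object),
    )
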