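"""Derived (residual) phenotypes, PC loadings and heterozygosity.

Raw quantitative traits can correlate with sample-level structure — between
population differences, covariates such as age, or technical variation in
per-individual heterozygosity — and those correlations masquerade as gene
level association.  The remedy implemented here regresses the trait on
candidate covariates (Age, Sex, Smoke, optionally principal-component
loadings of the allele-count matrix), selects terms by backwards stepwise
elimination under BIC, and uses the standardized residuals as the phenotype
for the scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .genotype_io import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass
class DerivedPhenotype:
    """A standardized-residual phenotype and the model that produced it."""

    name: str
    base_trait: str
    retained_terms: list[str]
    coefficients: dict[str, float]
    residual_sd: float          # sigma-hat of the fitted linear model
    values: np.ndarray          # standardized residuals, mean 0 / sd 1
    bic_trace: list[tuple[str, float]] = field(default_factory=list)


def individual_heterozygosity(g: GenotypeMatrix) -> np.ndarray:
    """Fraction of an individual's non-missing sites that are heterozygous.

    Individuals with every genotype missing get NaN (logged).
    """
    het = (g.counts == 1).sum(axis=1).astype(float)
    called = (g.counts != MISSING).sum(axis=1).astype(float)
    out = np.full(g.n_individuals, np.nan)
    ok = called > 0
    out[ok] = het[ok] / called[ok]
    if (~ok).any():
        log.warning("%d individuals with all genotypes missing; heterozygosity NaN",
                    int((~ok).sum()))
    return out


def pc_loadings(g: GenotypeMatrix, n_components: int = 6):
    """Principal-component scores of individuals from the allele-count matrix.

    Columns are mean-centered (missing entries imputed to the site mean
    first).  Returns ``(scores, variance_fractions)`` with component signs
    fixed so each score vector's largest-magnitude coordinate is positive.
    """
    from sklearn.decomposition import PCA

    if g.n_individuals < n_components:
        raise ValueError("need at least n_components individuals")
    X = g.counts.astype(float)
    miss = g.counts == MISSING
    if miss.any():
        col_mean = np.where(miss, np.nan, X).astype(float)
        col_mean = np.nanmean(col_mean, axis=0)
        X[miss] = np.take(col_mean, np.where(miss)[1])
    if np.allclose(X, X[0]):
        raise ValueError("degenerate genotype matrix: no variation for PCA")
    pca = PCA(n_components=n_components, random_state=0)
    scores = pca.fit_transform(X)
    for c in range(scores.shape[1]):
        j = int(np.argmax(np.abs(scores[:, c])))
        if scores[j, c] < 0:
            scores[:, c] = -scores[:, c]
    return scores, pca.explained_variance_ratio_.copy()


def _standardize(r: np.ndarray) -> np.ndarray:
    return (r - r.mean()) / r.std(ddof=1)


def _drop_aliased(X: pd.DataFrame) -> pd.DataFrame:
    """Drop constant or linearly dependent candidate columns (logged)."""
    keep: list[str] = []
    for col in X.columns:
        v = X[col].to_numpy(dtype=float)
        if np.ptp(v) == 0:
            log.info("dropping constant candidate %r", col)
            continue
        trial = X[keep + [col]].to_numpy(dtype=float)
        if np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), trial])) < len(keep) + 2:
            log.info("dropping aliased candidate %r", col)
            continue
        keep.append(col)
    return X[keep]


def _fit(y: np.ndarray, X: pd.DataFrame, terms: list[str]):
    design = sm.add_constant(X[terms].astype(float), has_constant="add")
    return sm.OLS(y, design).fit()


def residualize(trait, candidates: pd.DataFrame, name: str = "derived",
                base_trait: str = "trait") -> DerivedPhenotype:
    """Backwards stepwise BIC selection, then standardized residuals.

    Starting from the full linear model (intercept + all candidates), the
    single term whose removal most decreases BIC is dropped, repeatedly,
    until no removal decreases it; ties are broken by dropping the term with
    the smallest absolute t statistic.  The intercept is always kept.
    """
    y = np.asarray(trait, dtype=float)
    if len(y) != len(candidates):
        raise ValueError("trait and candidate table lengths differ")
    if len(y) <= candidates.shape[1] + 1:
        raise ValueError("insufficient data: need n > #candidates + 1")
    X = _drop_aliased(candidates.copy())

    terms = list(X.columns)
    fit = _fit(y, X, terms)
    trace = [("<full>", float(fit.bic))]
    while terms:
        options = []
        for t in terms:
            reduced = [u for u in terms if u != t]
            bic = float(_fit(y, X, reduced).bic)
            options.append((bic, abs(float(fit.tvalues[t])), t))
        options.sort()  # lowest BIC first; ties -> smallest |t| dropped
        best_bic, _, drop = options[0]
        if best_bic >= float(fit.bic):
            break
        terms = [u for u in terms if u != drop]
        fit = _fit(y, X, terms)
        trace.append((f"-{drop}", float(fit.bic)))

    resid = np.asarray(y - fit.fittedvalues, dtype=float)
    sigma = float(np.sqrt(fit.scale))
    coefs = {k: float(v) for k, v in fit.params.items()}
    return DerivedPhenotype(name=name, base_trait=base_trait, retained_terms=terms,
                            coefficients=coefs, residual_sd=sigma,
                            values=_standardize(resid), bic_trace=trace)


def refit_selected(model: DerivedPhenotype, trait, candidates: pd.DataFrame,
                   name: str | None = None) -> DerivedPhenotype:
    """Re-estimate an already-selected model on new data (no re-selection).

    Coefficients are refit to the replicate; residuals are standardized.
    With zero retained terms this reduces to standardizing the trait.
    """
    missing = [t for t in model.retained_terms if t not in candidates.columns]
    if missing:
        raise ValueError(f"replicate table lacks retained terms: {missing}")
    y = np.asarray(trait, dtype=float)
    if model.retained_terms:
        fit = _fit(y, candidates, model.retained_terms)
        resid = np.asarray(y - fit.fittedvalues, dtype=float)
        sigma = float(np.sqrt(fit.scale))
        coefs = {k: float(v) for k, v in fit.params.items()}
    else:
        resid, sigma, coefs = y - y.mean(), float(y.std(ddof=1)), {}
    return DerivedPhenotype(name=name or model.name, base_trait=model.base_trait,
                            retained_terms=list(model.retained_terms),
                            coefficients=coefs, residual_sd=sigma,
                            values=_standardize(resid))
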