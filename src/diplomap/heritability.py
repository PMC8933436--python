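"""Heritability estimation and additive/dominance/epistatic decomposition.

Broad-sense heritability is estimated from replicate concordance as the
between-genotype sum of squares over the total sum of squares, averaged
over repeated random subsamples of genotypes.  Note that this SS ratio is
upward-biased under the null: with G genotypes of 2 replicates each and no
genetic variance its expectation is (G-1)/(2G-1), i.e. about one half.

The additive/dominance/epistatic decomposition uses genomic relationship
matrices: A from column-centered 3S dosage, D from the centered
heterozygosity indicator (both scaled to unit mean diagonal), and
E = A o A (Hadamard square, the additive-by-additive kernel).  Variance
components are estimated by Haseman-Elston-style method of moments:
regression of off-diagonal phenotypic cross-products on the corresponding
kernel entries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._rng import substream
from .panels import DiploidPanel

__all__ = [
    "HeritabilityEstimate",
    "broad_sense",
    "ade_decomposition",
    "relationship_matrices",
]


@dataclass
class HeritabilityEstimate:
    """Mean and standard error of a heritability (or variance-fraction) estimate."""

    estimate: float
    se: float
    components: dict = field(default_factory=dict)  # name -> (mean, se)
    n_subsample: int = 0
    n_repeats: int = 0


def broad_sense(
    replicate_fitness: np.ndarray,
    diploid_ids: np.ndarray,
    n_sub: int = 2500,
    n_rep: int = 1000,
    seed: int = 0,
) -> HeritabilityEstimate:
    """Broad-sense heritability from replicate (pre-averaged) fitnesses.

    For each of ``n_rep`` random subsamples of ``n_sub`` genotypes, computes
    the one-way decomposition H2 = SS_between / SS_total over the subsample's
    replicate-level fitness values; reports the mean and SD/sqrt(n_rep).
    Only genotypes with at least two replicates participate.
    """
    y = np.asarray(replicate_fitness, dtype=np.float64)
    dip = np.asarray(diploid_ids)
    uniq, codes = np.unique(dip, return_inverse=True)
    counts = np.bincount(codes)
    eligible = np.flatnonzero(counts[codes] >= 2)
    elig_geno = np.unique(codes[eligible])
    if elig_geno.size < n_sub:
        warnings.warn(
            f"only {elig_geno.size} genotypes with >=2 replicates; using all"
        )
        n_sub = elig_geno.size
    rng = substream(seed, "broad_sense")

    order = np.argsort(codes[eligible], kind="stable")
    rows_sorted = eligible[order]
    codes_sorted = codes[rows_sorted]
    starts = np.searchsorted(codes_sorted, elig_geno)
    ends = np.searchsorted(codes_sorted, elig_geno, side="right")

    h2 = np.empty(n_rep)
    for r in range(n_rep):
        pick = rng.choice(elig_geno.size, size=n_sub, replace=False)
        rows = np.concatenate(
            [rows_sorted[starts[g]:ends[g]] for g in pick]
        )
        g = codes[rows]
        yy = y[rows]
        _, gcodes = np.unique(g, return_inverse=True)
        n_g = np.bincount(gcodes)
        mean_g = np.bincount(gcodes, weights=yy) / n_g
        grand = yy.mean()
        ss_between = float(np.sum(n_g * (mean_g - grand) ** 2))
        ss_total = float(np.sum((yy - grand) ** 2))
        h2[r] = ss_between / ss_total if ss_total > 0 else np.nan
    return HeritabilityEstimate(
        float(np.nanmean(h2)),
        float(np.nanstd(h2, ddof=1) / np.sqrt(n_rep)) if n_rep > 1 else 0.0,
        {},
        n_sub,
        n_rep,
    )


def broad_sense_components(
    replicate_fitness: np.ndarray, diploid_ids: np.ndarray
) -> tuple[float, float]:
    """Variance components from expected mean squares (one-way random effects).

    Returns (genetic variance, residual variance) via the classic ANOVA
    estimator sigma_g^2 = (MSB - MSW) / k0 with k0 the effective replicate
    number.  Unlike the raw SS ratio, H2 = sigma_g^2 / (sigma_g^2 +
    sigma_e^2) is unbiased for the underlying variance ratio, so this is
    the estimator to use when the target is the true heritability rather
    than the replicate-concordance statistic.
    """
    y = np.asarray(replicate_fitness, dtype=np.float64)
    _, codes = np.unique(np.asarray(diploid_ids), return_inverse=True)
    counts = np.bincount(codes)
    keep = counts[codes] >= 2
    y, codes = y[keep], codes[keep]
    _, codes = np.unique(codes, return_inverse=True)
    counts = np.bincount(codes).astype(float)
    G = counts.size
    n = y.size
    mean_g = np.bincount(codes, weights=y) / counts
    grand = y.mean()
    ssb = float(np.sum(counts * (mean_g - grand) ** 2))
    ssw = float(np.sum((y - mean_g[codes]) ** 2))
    msb = ssb / (G - 1)
    msw = ssw / (n - G)
    k0 = (n - np.sum(counts**2) / n) / (G - 1)
    sigma_g = max((msb - msw) / k0, 0.0)
    return sigma_g, msw


def relationship_matrices(panel: DiploidPanel, idx: np.ndarray | None = None):
    """Additive, dominance, and additive-by-additive relationship matrices.

    A = W W' / c_A with W the column-centered dosage matrix and c_A chosen
    so that mean(diag(A)) = 1; D likewise from the centered heterozygosity
    indicator; E = A o A.  Monomorphic columns contribute nothing.
    """
    G = panel.genotypes if idx is None else panel.genotypes[idx]
    X = G.astype(np.float64)
    W = X - X.mean(axis=0)
    A = W @ W.T
    cA = np.trace(A) / A.shape[0]
    if cA <= 0:
        raise ValueError("additive kernel is degenerate (all markers monomorphic)")
    A /= cA
    H = (X == 1).astype(np.float64)
    Hc = H - H.mean(axis=0)
    D = Hc @ Hc.T
    cD = np.trace(D) / D.shape[0]
    D = D / cD if cD > 0 else None
    E = A * A
    return A, D, E


def ade_decomposition(
    phenotype: np.ndarray,
    panel: DiploidPanel,
    n_sub: int = 2500,
    n_rep: int = 10,
    seed: int = 0,
) -> HeritabilityEstimate:
    """Method-of-moments additive/dominance/epistatic variance fractions.

    For each subsample, regresses the off-diagonal phenotypic cross-products
    (of the centered phenotype) on the off-diagonal entries of (A, D, E)
    plus an intercept; the coefficients estimate the variance components,
    which are divided by the total phenotypic variance to give fractions.
    A degenerate kernel (e.g. no heterozygotes) is dropped with a warning.
    """
    y = np.asarray(phenotype, dtype=np.float64)
    if y.size != panel.n_diploids:
        raise ValueError("phenotype length must match panel")
    rng = substream(seed, "ade")
    n = y.size
    n_sub = min(n_sub, n)

    names_all = ["additive", "dominance", "epistatic"]
    ests = {k: [] for k in names_all}
    for _ in range(n_rep):
        idx = rng.choice(n, size=n_sub, replace=False) if n_sub < n else np.arange(n)
        A, D, E = relationship_matrices(panel, idx)
        yy = y[idx] - y[idx].mean()
        var_tot = float(np.var(yy, ddof=1))
        iu = np.triu_indices(n_sub, k=1)
        prod = (yy[:, None] * yy[None, :])[iu]
        cols = [np.ones(prod.size), A[iu], E[iu]]
        names = ["additive", "epistatic"]
        if D is not None and np.ptp(D[iu]) > 1e-12:
            cols.insert(2, D[iu])
            names = ["additive", "dominance", "epistatic"]
        else:
            warnings.warn("dominance kernel degenerate; dropped from the regression")
        Xmat = np.column_stack(cols)
        beta, *_ = np.linalg.lstsq(Xmat, prod, rcond=None)
        for k, b in zip(names, beta[1:]):
            ests[k].append(b / var_tot)
        for k in set(names_all) - set(names):
            ests[k].append(np.nan)

    comps = {}
    for k in names_all:
        v = np.asarray(ests[k], dtype=np.float64)
        if np.all(np.isnan(v)):
            continue
        comps[k] = (
            float(np.nanmean(v)),
            float(np.nanstd(v, ddof=1) / np.sqrt(n_rep)) if n_rep > 1 else 0.0,
        )
    total = sum(m for m, _ in comps.values())
    return HeritabilityEstimate(float(total), 0.0, comps, n_sub, n_rep)
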