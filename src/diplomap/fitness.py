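"""Lineage fitness estimation from barcode count trajectories.

Each double-barcode lineage's frequency trajectory follows

    f_i(t+1) = f_i(t) * exp((s_i - sbar(t)) * dg)

where s_i is its per-generation relative fitness and sbar(t) the
abundance-weighted population mean fitness.  Read counts at timepoint t are
modelled as Poisson with mean depth(t) * f_i(t), which reduces each lineage
fit to a two-parameter Poisson regression of counts on generations with an
offset absorbing the depth and the cumulative mean-fitness trajectory.  The
estimator alternates lineage fits with updates of sbar(t) until the mean
trajectory converges, then reports fitnesses relative to the initial
population mean (the dynamics identify s only up to an additive constant,
so the gauge is fixed at sbar(0) = 0).

Replicate quality control follows three rules: lineages whose maximum
log-likelihood score falls more than 1.5 IQR below the first quartile are
dropped; among >= 3 replicates of a diploid, any replicate more than 0.5
fitness units from the median of the others is dropped; when exactly two
replicates disagree by more than 0.5 both are dropped; diploids left with a
single replicate are omitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .counts import CountTable

__all__ = [
    "FitnessTable",
    "estimate_fitness",
    "filter_replicates",
    "aggregate_and_normalize",
    "quantile_normalize",
]


@dataclass
class FitnessTable:
    """Per-lineage fitness estimates and the per-diploid aggregated phenotype.

    ``lineages`` has one row per estimated lineage with columns
    (diploid, replicate, s, score, kept).  ``phenotypes`` (set by
    :func:`aggregate_and_normalize`) has one row per surviving diploid with
    columns (diploid, n_replicates, mean_s, qnorm_s).
    """

    lineages: pd.DataFrame
    generations_per_cycle: float
    converged: bool = True
    phenotypes: pd.DataFrame = field(default=None)

    def kept(self) -> pd.DataFrame:
        return self.lineages[self.lineages["kept"]]

    def to_tsv(self, path) -> None:
        self.lineages.to_csv(path, sep="\t", index=False)


def _poisson_fit(counts, gens, offsets, n_newton=30):
    """Vectorized per-lineage Poisson regression: log mu = b0 + b1*g + offset.

    Returns (b0, b1, loglik).  ``counts`` is (L, T); ``offsets`` is (L, T) or (T,).
    """
    counts = np.asarray(counts, dtype=np.float64)
    L, T = counts.shape
    off = np.broadcast_to(offsets, (L, T))
    g = np.broadcast_to(gens, (L, T))
    tot = counts.sum(axis=1)
    b0 = np.log(np.maximum(tot, 0.5)) - np.log(np.exp(off).sum(axis=1))
    b1 = np.zeros(L)
    for _ in range(n_newton):
        eta = np.clip(b0[:, None] + b1[:, None] * g + off, -60, 60)
        lam = np.exp(eta)
        r = counts - lam
        g0 = r.sum(axis=1)
        g1 = (r * g).sum(axis=1)
        h00 = lam.sum(axis=1)
        h01 = (lam * g).sum(axis=1)
        h11 = (lam * g * g).sum(axis=1)
        det = h00 * h11 - h01 * h01
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        d0 = (h11 * g0 - h01 * g1) / det
        d1 = (h00 * g1 - h01 * g0) / det
        step = np.maximum(1.0, np.maximum(np.abs(d0), np.abs(d1 * g.max())) / 2.0)
        b0 += d0 / step
        b1 += d1 / step
        if max(np.abs(d0).max(initial=0), np.abs(d1).max(initial=0)) < 1e-12:
            break
    eta = np.clip(b0[:, None] + b1[:, None] * g + off, -60, 60)
    lam = np.exp(eta)
    ll = (counts * eta - lam - gammaln(counts + 1.0)).sum(axis=1)
    return b0, b1, ll


def estimate_fitness(
    table: CountTable,
    generations_per_cycle: float | None = None,
    max_iter: int = 50,
    tol: float = 1e-6,
) -> FitnessTable:
    """Estimate per-generation relative fitness for every valid lineage.

    Iterates (i) per-lineage Poisson fits of the count trajectory given the
    current mean-fitness trajectory and (ii) the update
    sbar(t) = sum_i f_i(t) s_i using the observed frequencies, until the
    relative change of the summed trajectory is below ``tol`` (or
    ``max_iter`` sweeps, with a warning).  All-zero lineages are excluded
    with a warning.
    """
    gens = table.generations
    if generations_per_cycle is None:
        steps = np.diff(gens)
        generations_per_cycle = float(steps[0])
    counts = table.working_counts()
    use = table.valid.copy()
    zero = counts.sum(axis=1) == 0
    if np.any(use & zero):
        warnings.warn(f"excluding {int((use & zero).sum())} all-zero lineages")
        use &= ~zero
    if use.sum() < 2:
        raise ValueError("need at least two lineages with counts")
    C = counts[use]
    depth = C.sum(axis=0)
    freq = C / np.maximum(depth, 1e-12)

    T = gens.size
    sbar = np.zeros(T)  # mean fitness at the start of each interval
    prev_sum = np.inf
    converged = False
    for _ in range(max_iter):
        # cumulative mean-fitness generations up to each timepoint
        cum = np.concatenate([[0.0], np.cumsum(sbar[:-1] * np.diff(gens))])
        offsets = np.log(np.maximum(depth, 1e-12)) - cum
        _, s_hat, ll = _poisson_fit(C, gens, offsets)
        # the dynamics identify s only up to a constant; fix the gauge at
        # sbar(0) = 0 so the iteration cannot drift along that direction
        s_hat = s_hat - float(freq[:, 0] @ s_hat)
        sbar = freq.T @ s_hat
        cur = float(np.abs(sbar).sum())
        if abs(cur - prev_sum) <= tol * max(cur, 1.0):
            converged = True
            break
        prev_sum = cur
    if not converged:
        warnings.warn("mean-fitness iteration did not converge; using last iterate")

    # gauge: fitness relative to the initial population mean
    s_hat = s_hat - float(freq[:, 0] @ s_hat)

    lineages = pd.DataFrame(
        {
            "lineage": table.lineage_ids[use],
            "diploid": table.diploid[use],
            "replicate": table.replicate[use],
            "s": s_hat,
            "score": ll,
            "kept": True,
        }
    )
    return FitnessTable(lineages, generations_per_cycle, converged)


def filter_replicates(fit: FitnessTable, max_diff: float = 0.5) -> FitnessTable:
    """Apply the likelihood-score and replicate-concordance filters.

    See the module docstring for the three rules.  Filtering only changes
    membership (the ``kept`` flag); surviving values are untouched.
    """
    df = fit.lineages.copy()
    kept = df["kept"].to_numpy().copy()

    score = df["score"].to_numpy()
    q1, q3 = np.percentile(score[kept], [25, 75])
    kept &= score >= q1 - 1.5 * (q3 - q1)

    s = df["s"].to_numpy()
    dip = df["diploid"].to_numpy()
    for d in np.unique(dip):
        rows = np.flatnonzero((dip == d) & kept)
        if rows.size >= 3:
            drop = []
            for r in rows:
                others = np.setdiff1d(rows, [r])
                if abs(s[r] - np.median(s[others])) > max_diff:
                    drop.append(r)
            kept[drop] = False
            rows = np.flatnonzero((dip == d) & kept)
        if rows.size == 2 and abs(s[rows[0]] - s[rows[1]]) > max_diff:
            kept[rows] = False
            rows = np.array([], dtype=int)
        if rows.size == 1:
            kept[rows] = False

    df["kept"] = kept
    return FitnessTable(df, fit.generations_per_cycle, fit.converged, fit.phenotypes)


def quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Map values rank-wise onto standard-normal quantiles.

    Uses the offset quantile (rank - 0.5) / n with average ranks for ties,
    so tied inputs receive equal outputs and ranks are preserved.
    """
    values = np.asarray(values, dtype=np.float64)
    ranks = stats.rankdata(values, method="average")
    return stats.norm.ppf((ranks - 0.5) / values.size)


def aggregate_and_normalize(fit: FitnessTable) -> FitnessTable:
    """Average kept replicates per diploid and quantile-normalize the means."""
    kept = fit.kept()
    grp = kept.groupby("diploid")["s"]
    means = grp.mean()
    n = grp.size()
    pheno = pd.DataFrame(
        {
            "diploid": means.index.to_numpy(),
            "n_replicates": n.to_numpy(),
            "mean_s": means.to_numpy(),
            "qnorm_s": quantile_normalize(means.to_numpy()),
        }
    )
    return FitnessTable(fit.lineages, fit.generations_per_cycle, fit.converged, pheno)
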