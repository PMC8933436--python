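"""Family-level genome scans for one-locus effects.

Within a family (all diploids sharing one MATa haploid parent) every marker
segregates at most two genotype classes, because the MATa allele is fixed.
A fixed-effects linear model of phenotype on the locus (categorical, given
any already-detected covariate loci) is therefore a two-group comparison,
and the locus term's partial F test with one numerator degree of freedom
is computed in closed form for all markers at once.

Significance thresholds come from permutations that shuffle phenotypes
within families and record the genome-wide minimum p value; the 5th
percentile of the minima (linear interpolation between order statistics)
is the family-wise 5% threshold.  Detected peaks carry 3-LOD-drop
confidence intervals, detections are consolidated across families by
single-linkage interval overlap, and loci detected more often than a
Poisson model of chance predicts (in 20 kb bins, Bonferroni corrected) are
flagged as enriched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream
from .markers import MarkerMap
from .panels import DiploidPanel

__all__ = [
    "ScanResult",
    "marker_pvalues_2class",
    "family_scan",
    "permutation_threshold",
    "lod_drop_interval",
    "consolidate_across_families",
    "EnrichedLoci",
    "enrichment_test",
]


def _project_out(C: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Residualize the columns of M against the column space of C."""
    Q, _ = np.linalg.qr(C)
    return M - Q @ (Q.T @ M)


def marker_pvalues_2class(
    y: np.ndarray, G: np.ndarray, covariate_idx=()
) -> np.ndarray:
    """p value of the locus term at every marker for a two-class genotype matrix.

    ``G`` holds within-family diploid genotypes; markers with fewer than two
    classes get NaN.  ``covariate_idx`` lists already-detected markers whose
    (two-class) indicators enter the model as covariates.  The returned p is
    the partial F test on 1 numerator df, identical to the classic
    equal-variance two-sample t test when there are no covariates.
    """
    y = np.asarray(y, dtype=np.float64)
    n = y.size
    X = np.asarray(G, dtype=np.float64)
    X = X - X.min(axis=0)  # two classes -> 0/1 indicator
    poly = np.ptp(X, axis=0) > 0

    C_cols = [np.ones(n)]
    for j in covariate_idx:
        C_cols.append(X[:, j])
    C = np.column_stack(C_cols)
    p_c = np.linalg.matrix_rank(C)
    dof = n - p_c - 1
    if dof <= 0:
        raise ValueError("family too small for the requested covariates")

    Xr = _project_out(C, X)
    yr = _project_out(C, y[:, None])[:, 0]
    ssx = (Xr**2).sum(axis=0)
    ssy = float(yr @ yr)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (Xr.T @ yr) ** 2 / np.where(ssx > 0, ssx, np.nan)
        F = num / np.maximum(ssy - num, 1e-300) * dof
    pvals = stats.f.sf(F, 1, dof)
    pvals[~poly | (ssx <= 1e-12)] = np.nan
    return pvals


@dataclass
class ScanResult:
    """Result of one genome scan with forward regression.

    ``pvalues`` is the first-round genome-wide profile; ``profiles`` keeps
    the per-round profiles used for interval computation; ``detections``
    has one row per detected locus with its 3-LOD-drop interval.
    """

    pvalues: np.ndarray
    detections: pd.DataFrame
    threshold: float
    mmap: MarkerMap
    family: int | None = None
    profiles: list = field(default_factory=list)


def _forward_scan(scan_fn, mmap: MarkerMap, threshold: float, max_rounds: int = 20):
    """Generic forward regression over chromosomes.

    ``scan_fn(covariates)`` returns the genome-wide p-value profile given the
    currently known loci.  Each round adds, per chromosome, the most
    significant marker above threshold; rounds repeat until nothing passes.
    Ties break on lowest (chromosome, bp).
    """
    known: list[int] = []
    rows = []
    profiles = []
    first = None
    for rnd in range(1, max_rounds + 1):
        pvals = scan_fn(tuple(known))
        profiles.append(pvals)
        if first is None:
            first = pvals
        added = False
        for c in mmap.chromosomes:
            idx = mmap.chrom_indices(c)
            sub = pvals[idx]
            if np.all(~np.isfinite(sub)):
                continue
            j = int(idx[np.nanargmin(sub)])
            if j in known:
                continue
            if pvals[j] < threshold:
                known.append(j)
                left, right = lod_drop_interval(-np.log10(pvals), j, mmap)
                rows.append(
                    {
                        "marker": j,
                        "chrom": int(mmap.chrom[j]),
                        "bp": int(mmap.bp[j]),
                        "p": float(pvals[j]),
                        "neglog10p": float(-np.log10(pvals[j])),
                        "round": rnd,
                        "ci_left": left,
                        "ci_right": right,
                    }
                )
                added = True
        if not added:
            break
    det = pd.DataFrame(
        rows,
        columns=["marker", "chrom", "bp", "p", "neglog10p", "round", "ci_left", "ci_right"],
    )
    return first, det, profiles


def family_scan(
    phenotype: np.ndarray,
    panel: DiploidPanel,
    family_id: int,
    threshold: float | None = None,
    known_loci=(),
    min_family_size: int = 20,
) -> ScanResult | None:
    """Genome scan with forward regression within one MATa family.

    ``phenotype`` is indexed over the whole panel (NaN entries are skipped).
    Returns None (with a warning) for families smaller than
    ``min_family_size``.  When ``threshold`` is None only the single-round
    profile is computed.
    """
    import warnings

    members = panel.family_members(family_id)
    y = np.asarray(phenotype, dtype=np.float64)[members]
    ok = np.isfinite(y)
    members, y = members[ok], y[ok]
    if members.size < min_family_size:
        warnings.warn(f"family {family_id} has {members.size} members; skipped")
        return None
    G = panel.genotypes[members]

    def scan_fn(covs):
        return marker_pvalues_2class(y, G, tuple(known_loci) + covs)

    if threshold is None:
        pvals = scan_fn(())
        det = pd.DataFrame(
            columns=["marker", "chrom", "bp", "p", "neglog10p", "round", "ci_left", "ci_right"]
        )
        return ScanResult(pvals, det, np.nan, panel.mmap, family_id, [pvals])
    first, det, profiles = _forward_scan(scan_fn, panel.mmap, threshold)
    return ScanResult(first, det, threshold, panel.mmap, family_id, profiles)


def permutation_threshold(
    phenotype: np.ndarray,
    panel: DiploidPanel,
    n_perm: int = 1000,
    n_families: int = 10,
    seed: int = 0,
    families=None,
    quantile: float = 5.0,
) -> float:
    """Family-wise significance threshold from within-family permutations.

    For each permutation the phenotype is shuffled within each of
    ``n_families`` randomly selected families and the genome-wide minimum
    p value (over markers and selected families) is recorded; the
    ``quantile``-th percentile of the minima is returned.
    """
    rng = substream(seed, "perm_threshold")
    all_fams = np.unique(panel.mata_parent)
    if families is None:
        if all_fams.size < n_families:
            raise ValueError("fewer families than n_families")
        families = rng.choice(all_fams, size=n_families, replace=False)

    y = np.asarray(phenotype, dtype=np.float64)
    minima = np.full(n_perm, np.inf)
    for f in families:
        members = panel.family_members(f)
        yf = y[members]
        ok = np.isfinite(yf)
        members, yf = members[ok], yf[ok]
        n = yf.size
        if n < 3:
            continue
        X = panel.genotypes[members].astype(np.float64)
        X = X - X.mean(axis=0)
        norm = np.sqrt((X**2).sum(axis=0))
        poly = norm > 1e-12
        Xs = X[:, poly] / norm[poly]
        # n_perm independent within-family shuffles
        Y = np.empty((n, n_perm))
        for pclm in range(n_perm):
            Y[:, pclm] = rng.permutation(yf)
        Y = Y - Y.mean(axis=0)
        Y /= np.maximum(np.sqrt((Y**2).sum(axis=0)), 1e-300)
        R = Xs.T @ Y  # (m_poly, n_perm) correlations
        R = np.clip(R, -1 + 1e-15, 1 - 1e-15)
        F = (n - 2) * R**2 / (1 - R**2)
        pmat = stats.f.sf(F, 1, n - 2)
        minima = np.minimum(minima, pmat.min(axis=0))
    if not np.all(np.isfinite(minima)):
        raise ValueError("no usable family in the permutation set")
    return float(np.percentile(minima, quantile))


def lod_drop_interval(neglog10p: np.ndarray, peak: int, mmap: MarkerMap, drop: float = 3.0):
    """3-LOD-drop confidence interval around a peak marker.

    Contiguous markers on the peak's chromosome whose -log10 p is within
    ``drop`` of the peak value; returns (left bp, right bp).
    """
    idx = mmap.chrom_indices(mmap.chrom[peak])
    pos = int(np.flatnonzero(idx == peak)[0])
    prof = neglog10p[idx]
    cut = prof[pos] - drop
    left = pos
    while left > 0 and np.isfinite(prof[left - 1]) and prof[left - 1] >= cut:
        left -= 1
    right = pos
    while right < prof.size - 1 and np.isfinite(prof[right + 1]) and prof[right + 1] >= cut:
        right += 1
    return int(mmap.bp[idx[left]]), int(mmap.bp[idx[right]])


def consolidate_across_families(detections: pd.DataFrame) -> pd.DataFrame:
    """Merge per-family detections into distinct loci by interval overlap.

    ``detections`` needs columns (family, chrom, bp, neglog10p, ci_left,
    ci_right).  Overlapping intervals on the same chromosome are merged by
    single linkage; each distinct locus reports its span, the number of
    families detecting it, the total number of detections, and the peak of
    its most significant detection.
    """
    rows = []
    for c, sub in detections.groupby("chrom"):
        sub = sub.sort_values("ci_left")
        cur = None
        group = []
        for _, r in sub.iterrows():
            if cur is None or r["ci_left"] > cur:
                if group:
                    rows.append(_summarize_locus(c, group))
                group = [r]
                cur = r["ci_right"]
            else:
                group.append(r)
                cur = max(cur, r["ci_right"])
        if group:
            rows.append(_summarize_locus(c, group))
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "peak_bp", "n_detections", "n_families",
                 "max_neglog10p"],
    ).sort_values(["chrom", "start"]).reset_index(drop=True)


def _summarize_locus(chrom, group):
    g = pd.DataFrame(group)
    best = g.loc[g["neglog10p"].idxmax()]
    return {
        "chrom": int(chrom),
        "start": int(g["ci_left"].min()),
        "end": int(g["ci_right"].max()),
        "peak_bp": int(best["bp"]),
        "n_detections": int(len(g)),
        "n_families": int(g["family"].nunique()) if "family" in g else int(len(g)),
        "max_neglog10p": float(g["neglog10p"].max()),
    }


@dataclass
class EnrichedLoci:
    """Poisson enrichment of family-level detections in 20 kb genome bins."""

    bins: pd.DataFrame  # chrom, start, end, count
    lam: float
    threshold: int
    alpha_bonferroni: float

    @property
    def enriched(self) -> pd.DataFrame:
        return self.bins[self.bins["count"] > self.threshold]


def poisson_count_threshold(lam: float, cut: float, kmax: int = 100_000) -> int:
    """Smallest k with upper-tail P(X > k) <= cut for X ~ Poisson(lam)."""
    k = 0
    while stats.poisson.sf(k, lam) > cut:
        k += 1
        if k > kmax:
            raise RuntimeError("Poisson threshold search did not terminate")
    return k


def enrichment_test(
    peaks: pd.DataFrame,
    mmap: MarkerMap,
    bin_size: int = 20_000,
    alpha: float = 0.05,
    chrom_lengths: dict | None = None,
) -> EnrichedLoci:
    """Find genome bins with more family-level detections than chance allows.

    Each chromosome is tiled from bp 1 in half-open [start, start + bin_size)
    windows (a final short bin is kept and counted).  Detections are binned
    by peak position.  With lambda = total detections / number of bins, the
    count threshold is the smallest k whose Poisson upper-tail probability
    is at most alpha / number of bins; bins exceeding it are enriched.
    """
    rows = []
    for c in mmap.chromosomes:
        length = (
            chrom_lengths[c] if chrom_lengths is not None else mmap.chrom_length_bp(c)
        )
        starts = np.arange(1, length + 1, bin_size)
        for s in starts:
            rows.append({"chrom": int(c), "start": int(s), "end": int(min(s + bin_size - 1, length))})
    bins = pd.DataFrame(rows)
    counts = np.zeros(len(bins), dtype=np.int64)
    if len(peaks):
        for _, r in peaks.iterrows():
            sel = (
                (bins["chrom"] == r["chrom"])
                & (bins["start"] <= r["bp"])
                & (r["bp"] < bins["start"] + bin_size)
            )
            counts[sel.to_numpy()] += 1
    bins["count"] = counts
    n_bins = len(bins)
    total = int(counts.sum())
    lam = total / n_bins
    if total == 0:
        return EnrichedLoci(bins, 0.0, 0, alpha / n_bins)
    thr = poisson_count_threshold(lam, alpha / n_bins)
    return EnrichedLoci(bins, lam, thr, alpha / n_bins)
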