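"""Scans for dominance, pairwise, and three-locus effects.

Family structure and additive effects are removed first: each diploid's
expected phenotype is the midparent value (the average of its two haploid
parents' mean offspring phenotypes), and the residuals of a regression of
phenotype on midparent value form the non-additive phenotype component used
by every scan here.

Dominance scan: residuals ~ locus with the diploid genotype as a 3-level
categorical variable, with forward regression over chromosomes and a
permutation threshold (5th percentile of genome-wide minimum p values under
shuffled residuals).

Pairwise scan: residuals ~ locus1 + locus2 + locus1:locus2 with all nine
joint genotype classes as independent categories; the interaction term's
sequential F test is computed from per-cell counts and sums, so the whole
marker-pair matrix is obtained from nine matrix products.  The permutation
null draws random marker pairs per permutation.  Hubs (loci with more than
20 interactions) are rescanned by forward regression over partners, and a
three-locus scan on a cM-thinned marker subset tests the full categorical
three-way term with all lower-order terms included.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream
from .markers import MarkerMap, thin_markers
from .panels import DiploidPanel
from .scan_additive import ScanResult, _forward_scan, lod_drop_interval

__all__ = [
    "ResidualPhenotype",
    "midparent_residuals",
    "marker_pvalues_3class",
    "dominance_scan",
    "dominance_permutation_threshold",
    "LocusEffect",
    "effect_and_dominance",
    "InteractionResult",
    "pair_interaction_pvalues",
    "pairwise_scan",
    "pairwise_permutation_threshold",
    "hub_forward_scan",
    "find_hubs",
    "remove_pairs_near_hub",
    "threeway_scan",
    "resolve_hub",
]


# ---------------------------------------------------------------------------
# Midparent residuals
# ---------------------------------------------------------------------------


@dataclass
class ResidualPhenotype:
    """Non-additive phenotype component per diploid.

    ``residuals`` is NaN for diploids excluded by the parental offspring
    threshold or missing phenotypes; ``mask`` marks usable entries.
    """

    residuals: np.ndarray
    midparent: np.ndarray
    mask: np.ndarray

    @property
    def values(self) -> np.ndarray:
        return self.residuals[self.mask]


def midparent_residuals(
    phenotype: np.ndarray, panel: DiploidPanel, min_offspring: int = 20
) -> ResidualPhenotype:
    """Remove additive family structure via midparent regression residuals.

    Each haploid parent's fitness is the mean phenotype of its offspring;
    the midparent value of a diploid is the average of its two parents'
    means; the residuals of phenotype ~ midparent are returned.  Diploids
    with a parent below ``min_offspring`` phenotyped offspring are excluded.
    """
    y = np.asarray(phenotype, dtype=np.float64)
    ok = np.isfinite(y)

    def parent_means(parent_ids):
        n_par = parent_ids.max() + 1
        cnt = np.bincount(parent_ids[ok], minlength=n_par)
        tot = np.bincount(parent_ids[ok], weights=y[ok], minlength=n_par)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(cnt > 0, tot / np.maximum(cnt, 1), np.nan), cnt

    mean_a, cnt_a = parent_means(panel.mata_parent)
    mean_al, cnt_al = parent_means(panel.matalpha_parent)
    mid = 0.5 * (mean_a[panel.mata_parent] + mean_al[panel.matalpha_parent])
    mask = (
        ok
        & (cnt_a[panel.mata_parent] >= min_offspring)
        & (cnt_al[panel.matalpha_parent] >= min_offspring)
        & np.isfinite(mid)
    )
    res = np.full(y.size, np.nan)
    X = np.column_stack([np.ones(mask.sum()), mid[mask]])
    beta, *_ = np.linalg.lstsq(X, y[mask], rcond=None)
    res[mask] = y[mask] - X @ beta
    return ResidualPhenotype(res, mid, mask)


# ---------------------------------------------------------------------------
# Dominance scan
# ---------------------------------------------------------------------------


def _dummies3(G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two dummy columns (het, hom-3S) per marker for categorical coding."""
    return (G == 1).astype(np.float64), (G == 2).astype(np.float64)


def marker_pvalues_3class(
    y: np.ndarray,
    G: np.ndarray,
    covariate_idx=(),
    min_class: int = 50,
) -> np.ndarray:
    """p value of the 3-level categorical locus term at every marker.

    The partial F test has 2 numerator df; markers with any genotype class
    smaller than ``min_class`` get NaN.  Covariate loci enter as categorical
    (two dummies each).  With no covariates this equals one-way ANOVA.
    """
    y = np.asarray(y, dtype=np.float64)
    n = y.size
    H1, H2 = _dummies3(G)
    class_n = np.stack([(G == g).sum(axis=0) for g in (0, 1, 2)])
    eligible = (class_n >= max(min_class, 1)).all(axis=0)

    C_cols = [np.ones(n)]
    for j in covariate_idx:
        C_cols += [H1[:, j], H2[:, j]]
    C = np.column_stack(C_cols)
    Q, _ = np.linalg.qr(C)
    p_c = np.linalg.matrix_rank(C)
    dof = n - p_c - 2
    if dof <= 0:
        raise ValueError("too few diploids for the requested covariates")

    yr = y - Q @ (Q.T @ y)
    ssy = float(yr @ yr)
    X1 = H1 - Q @ (Q.T @ H1)
    X2 = H2 - Q @ (Q.T @ H2)
    # per-marker 2x2 normal equations
    a11 = (X1 * X1).sum(axis=0)
    a22 = (X2 * X2).sum(axis=0)
    a12 = (X1 * X2).sum(axis=0)
    b1 = X1.T @ yr
    b2 = X2.T @ yr
    det = a11 * a22 - a12**2
    with np.errstate(invalid="ignore", divide="ignore"):
        ss_model = np.where(
            det > 1e-12 * np.maximum(a11 * a22, 1e-300),
            (a22 * b1**2 - 2 * a12 * b1 * b2 + a11 * b2**2) / det,
            np.nan,
        )
        F = (ss_model / 2.0) / np.maximum(ssy - ss_model, 1e-300) * dof
    pvals = stats.f.sf(F, 2, dof)
    pvals[~eligible] = np.nan
    return pvals


def dominance_permutation_threshold(
    res: ResidualPhenotype,
    panel: DiploidPanel,
    n_perm: int = 1000,
    min_class: int = 50,
    seed: int = 0,
    quantile: float = 5.0,
) -> float:
    """Permutation threshold for the dominance scan (shuffled residuals)."""
    rng = substream(seed, "dom_perm")
    y = res.values
    G = panel.genotypes[res.mask]
    n = y.size
    class_n = np.stack([(G == g).sum(axis=0) for g in (0, 1, 2)])
    eligible = (class_n >= max(min_class, 1)).all(axis=0)
    if not eligible.any():
        raise ValueError("no eligible markers")
    Gs = G[:, eligible]
    H = [(Gs == g).astype(np.float64) for g in (0, 1, 2)]
    n_g = class_n[:, eligible].astype(np.float64)

    Y = rng.permuted(np.tile(y[:, None], (1, n_perm)), axis=0)
    tot = Y.sum(axis=0)
    ss_tot = (Y**2).sum(axis=0) - tot**2 / n
    ssb = np.zeros((Gs.shape[1], n_perm))
    for g in range(3):
        S = H[g].T @ Y  # (m, n_perm)
        ssb += S**2 / n_g[g][:, None]
    ssb -= (tot**2 / n)[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        F = (ssb / 2.0) / np.maximum(ss_tot[None, :] - ssb, 1e-300) * (n - 3)
    pmat = stats.f.sf(F, 2, n - 3)
    return float(np.percentile(pmat.min(axis=0), quantile))


def dominance_scan(
    res: ResidualPhenotype,
    panel: DiploidPanel,
    threshold: float | None = None,
    n_perm: int = 1000,
    min_class: int = 50,
    seed: int = 0,
) -> ScanResult:
    """Forward-regression genome scan for dominance on midparent residuals."""
    y = res.values
    G = panel.genotypes[res.mask]
    if threshold is None:
        threshold = dominance_permutation_threshold(
            res, panel, n_perm=n_perm, min_class=min_class, seed=seed
        )

    def scan_fn(covs):
        return marker_pvalues_3class(y, G, covs, min_class=min_class)

    first, det, profiles = _forward_scan(scan_fn, panel.mmap, threshold)
    return ScanResult(first, det, threshold, panel.mmap, None, profiles)


# ---------------------------------------------------------------------------
# Degree of dominance
# ---------------------------------------------------------------------------


@dataclass
class LocusEffect:
    """Additive and dominance effects of one locus with its dominance class."""

    additive: float  # a = (mean_3S/3S - mean_BY/BY) / 2
    dominance: float  # d = mean_het - homozygote midpoint
    degree: float  # d / |a|; NaN when a == 0
    label: str
    class_means: np.ndarray  # means for dosage 0, 1, 2
    class_n: np.ndarray


def classify_dominance(degree: float, d: float) -> str:
    """Dominance class from the normalized degree d/|a|.

    Bands: |degree| < 0.9 incomplete, 0.9 <= |degree| <= 1.1 complete
    (positive toward the fitter allele, negative toward the deleterious
    allele), degree > 1.1 overdominant, < -1.1 underdominant.
    """
    if not np.isfinite(degree):
        return "undefined" if d == 0 else ("overdominant" if d > 0 else "underdominant")
    if degree > 1.1:
        return "overdominant"
    if degree < -1.1:
        return "underdominant"
    if degree >= 0.9:
        return "complete_fit"
    if degree <= -0.9:
        return "complete_deleterious"
    return "incomplete_fit" if degree >= 0 else "incomplete_deleterious"


def effect_and_dominance(
    phenotype: np.ndarray, panel: DiploidPanel, locus: int
) -> LocusEffect:
    """Additive effect, dominance deviation, and degree of dominance at a locus."""
    y = np.asarray(phenotype, dtype=np.float64)
    g = panel.genotypes[:, locus]
    ok = np.isfinite(y)
    means = np.array([y[ok & (g == k)].mean() if (ok & (g == k)).any() else np.nan
                      for k in (0, 1, 2)])
    n_cls = np.array([(ok & (g == k)).sum() for k in (0, 1, 2)])
    if np.any(n_cls == 0):
        raise ValueError("all three genotype classes must be non-empty")
    a = (means[2] - means[0]) / 2.0
    d = means[1] - (means[0] + means[2]) / 2.0
    degree = d / abs(a) if a != 0 else np.nan
    return LocusEffect(float(a), float(d), float(degree),
                       classify_dominance(degree, float(d)), means, n_cls)


# ---------------------------------------------------------------------------
# Pairwise interaction scan
# ---------------------------------------------------------------------------

# design matrix over the 9 joint cells for the additive (main-effects) model:
# [1, l1==1, l1==2, l2==1, l2==2]
_D9 = np.array(
    [[1, a == 1, a == 2, b == 1, b == 2] for a in range(3) for b in range(3)],
    dtype=np.float64,
)


@dataclass
class InteractionResult:
    """Interaction-scan output: per-pair (or trio) tests and consolidation."""

    pairs: pd.DataFrame
    threshold: float
    significant: pd.DataFrame = None
    consolidated: pd.DataFrame = None
    markers: np.ndarray = None  # scan marker indices into the map
    pmatrix: np.ndarray = field(default=None, repr=False)


def _pair_counts(G: np.ndarray) -> np.ndarray:
    """Joint-cell counts for all marker pairs: N[a, b, i, j]."""
    X = [(G == g).astype(np.float64) for g in (0, 1, 2)]
    m = G.shape[1]
    N = np.empty((3, 3, m, m))
    for a in range(3):
        for b in range(3):
            N[a, b] = X[a].T @ X[b]
    return N


def _pair_sums(y: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Joint-cell phenotype sums for all marker pairs: S[a, b, i, j]."""
    X = [(G == g).astype(np.float64) for g in (0, 1, 2)]
    m = G.shape[1]
    S = np.empty((3, 3, m, m))
    for a in range(3):
        Xa = X[a].T
        for b in range(3):
            S[a, b] = Xa @ (y[:, None] * X[b])
    return S


def _cell_stats_pairs(y: np.ndarray, G: np.ndarray):
    """Counts and y-sums of the 9 joint genotype cells for all marker pairs."""
    return _pair_counts(G), _pair_sums(y, G)


def _interaction_f_from_cells(N9, S9, ss_y, n, n_params, design):
    """Sequential interaction F test from per-cell counts and sums.

    N9, S9: (P, k_cells) per-candidate cell counts and y sums; ``design`` is
    the (k_cells, n_params) main-effects design.  Returns (F, df1, df2, p,
    reduced_rank flag).  RSS_full comes from the saturated cell means; the
    interaction SS is RSS(main effects) - RSS(saturated), the sequential sum
    of squares of the categorical interaction term.
    """
    P = N9.shape[0]
    XtWX = np.einsum("pk,ka,kb->pab", N9, design, design)
    XtWy = np.einsum("pk,ka->pa", S9, design)  # sum over obs of design * y
    beta = np.linalg.pinv(XtWX) @ XtWy[:, :, None]
    rss_add = ss_y - np.einsum("pa,pa->p", beta[:, :, 0], XtWy)
    rss_full = ss_y - np.nansum(_safe_div(S9**2, N9), axis=1)
    k_filled = (N9 > 0).sum(axis=1)
    # rank of the main-effects design restricted to filled cells
    rank = np.array(
        [np.linalg.matrix_rank(design[N9[p] > 0]) for p in range(P)]
    )
    df1 = k_filled - rank
    df2 = n - k_filled
    reduced = df1 < (design.shape[0] - n_params)
    with np.errstate(invalid="ignore", divide="ignore"):
        ss_int = np.clip(rss_add - rss_full, 0.0, None)
        F = (ss_int / np.maximum(df1, 1)) / np.maximum(rss_full / np.maximum(df2, 1), 1e-300)
    p = np.where(df1 > 0, stats.f.sf(F, np.maximum(df1, 1), np.maximum(df2, 1)), np.nan)
    return F, df1, df2, p, reduced


def _safe_div(a, b):
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(b > 0, a / np.where(b == 0, 1, b), 0.0)


def pair_interaction_pvalues(
    y: np.ndarray, G: np.ndarray, pairs: np.ndarray, min_cell: int = 0,
    cell_stats=None,
):
    """Interaction-term p values for the given (i, j) marker pairs.

    ``G`` holds dosage genotypes over the scanned diploids; pairs index its
    columns.  Pairs with any joint cell below ``min_cell`` get NaN.
    Returns a DataFrame with F, df, p, and the reduced-rank flag.
    """
    y = np.asarray(y, dtype=np.float64)
    n = y.size
    pairs = np.asarray(pairs)
    N, S = _cell_stats_pairs(y, G) if cell_stats is None else cell_stats
    i, j = pairs[:, 0], pairs[:, 1]
    N9 = N[:, :, i, j].reshape(9, -1).T  # (P, 9)
    S9 = S[:, :, i, j].reshape(9, -1).T
    ss_y = float(y @ y)
    F, df1, df2, p, reduced = _interaction_f_from_cells(N9, S9, ss_y, n, 5, _D9)
    if min_cell > 0:
        p = np.where((N9 >= min_cell).all(axis=1), p, np.nan)
    return pd.DataFrame(
        {"i": i, "j": j, "F": F, "df1": df1, "df2": df2, "p": p, "reduced": reduced}
    )


def pairwise_permutation_threshold(
    y: np.ndarray,
    G: np.ndarray,
    eligible_pairs: np.ndarray,
    n_perm: int = 1000,
    pairs_per_perm: int = 10_000,
    seed: int = 0,
    quantile: float = 5.0,
) -> float:
    """5th-percentile threshold of per-permutation minimum interaction p.

    Residuals are shuffled each permutation and ``pairs_per_perm`` random
    pairs (all pairs, when fewer are eligible) are tested.
    """
    rng = substream(seed, "pair_perm")
    minima = np.empty(n_perm)
    N = _pair_counts(G)  # counts are invariant under phenotype shuffles
    for b in range(n_perm):
        yp = rng.permutation(y)
        if eligible_pairs.shape[0] > pairs_per_perm:
            take = rng.choice(eligible_pairs.shape[0], size=pairs_per_perm, replace=False)
            pp = eligible_pairs[take]
        else:
            pp = eligible_pairs
        S = _pair_sums(yp, G)
        res = pair_interaction_pvalues(yp, G, pp, cell_stats=(N, S))
        minima[b] = np.nanmin(res["p"].to_numpy())
    return float(np.percentile(minima, quantile))


def pairwise_scan(
    res: ResidualPhenotype,
    panel: DiploidPanel,
    markers: np.ndarray | None = None,
    threshold: float | None = None,
    n_perm: int = 1000,
    pairs_per_perm: int = 10_000,
    min_cell: int = 20,
    seed: int = 0,
    consolidate: bool = True,
) -> InteractionResult:
    """Comprehensive scan for pairwise interactions on midparent residuals.

    Tests every pair of scan markers whose nine joint genotype classes all
    hold at least ``min_cell`` diploids.  Significant pairs whose two sides
    fall within each other's 3-LOD windows (computed from the pair p-value
    matrix with the partner side fixed) are consolidated to the most
    significant representative.
    """
    y = res.values
    G = panel.genotypes[res.mask]
    mmap = panel.mmap
    if markers is None:
        class_n = np.stack([(G == g).sum(axis=0) for g in (0, 1, 2)])
        markers = np.flatnonzero((class_n >= min_cell).all(axis=0))
    markers = np.asarray(markers)
    Gs = G[:, markers]
    ms = markers.size
    ii, jj = np.triu_indices(ms, k=1)
    all_pairs = np.column_stack([ii, jj])

    cell_stats = _cell_stats_pairs(y, Gs)
    table = pair_interaction_pvalues(y, Gs, all_pairs, min_cell=min_cell,
                                     cell_stats=cell_stats)
    eligible = all_pairs[np.isfinite(table["p"].to_numpy())]

    if threshold is None:
        threshold = pairwise_permutation_threshold(
            y, Gs, eligible, n_perm=n_perm, pairs_per_perm=pairs_per_perm, seed=seed
        )

    # symmetric p matrix over scan markers, for 3-LOD windows
    pmat = np.full((ms, ms), np.nan)
    pmat[table["i"], table["j"]] = table["p"]
    pmat[table["j"], table["i"]] = table["p"]

    table = table.assign(
        marker_i=markers[table["i"]],
        marker_j=markers[table["j"]],
        chrom_i=mmap.chrom[markers[table["i"]]],
        bp_i=mmap.bp[markers[table["i"]]],
        chrom_j=mmap.chrom[markers[table["j"]]],
        bp_j=mmap.bp[markers[table["j"]]],
    )
    sig = table[table["p"] < threshold].sort_values("p").reset_index(drop=True)
    consolidated = _consolidate_pairs(sig, pmat, markers, mmap) if consolidate else None
    return InteractionResult(table, threshold, sig, consolidated, markers, pmat)


def _lod_window_members(pmat, ms_index, fixed, mmap, markers, drop=3.0):
    """Scan-marker indices within the 3-LOD window of ``ms_index`` given a fixed partner."""
    chrom = mmap.chrom[markers[ms_index]]
    on_chrom = np.flatnonzero(mmap.chrom[markers] == chrom)
    prof = -np.log10(pmat[on_chrom, fixed])
    pos = int(np.flatnonzero(on_chrom == ms_index)[0])
    if not np.isfinite(prof[pos]):
        return {int(ms_index)}
    cut = prof[pos] - drop
    left = pos
    while left > 0 and np.isfinite(prof[left - 1]) and prof[left - 1] >= cut:
        left -= 1
    right = pos
    while right < prof.size - 1 and np.isfinite(prof[right + 1]) and prof[right + 1] >= cut:
        right += 1
    return set(int(k) for k in on_chrom[left:right + 1])


def _consolidate_pairs(sig: pd.DataFrame, pmat, markers, mmap) -> pd.DataFrame:
    """Greedy consolidation of significant pairs by mutual 3-LOD windows."""
    taken = np.zeros(len(sig), dtype=bool)
    rows = []
    for k in range(len(sig)):
        if taken[k]:
            continue
        r = sig.iloc[k]
        i, j = int(r["i"]), int(r["j"])
        win_i = _lod_window_members(pmat, i, j, mmap, markers)
        win_j = _lod_window_members(pmat, j, i, mmap, markers)
        absorbed = [k]
        for k2 in range(k + 1, len(sig)):
            if taken[k2]:
                continue
            r2 = sig.iloc[k2]
            i2, j2 = int(r2["i"]), int(r2["j"])
            if (i2 in win_i and j2 in win_j) or (i2 in win_j and j2 in win_i):
                absorbed.append(k2)
        taken[absorbed] = True
        rows.append(
            {
                "marker_i": int(r["marker_i"]),
                "marker_j": int(r["marker_j"]),
                "chrom_i": int(r["chrom_i"]),
                "bp_i": int(r["bp_i"]),
                "chrom_j": int(r["chrom_j"]),
                "bp_j": int(r["bp_j"]),
                "p": float(r["p"]),
                "n_absorbed": len(absorbed),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["marker_i", "marker_j", "chrom_i", "bp_i", "chrom_j", "bp_j", "p",
                 "n_absorbed"],
    )


def find_hubs(consolidated: pd.DataFrame, min_interactions: int = 20) -> pd.DataFrame:
    """Loci with more than ``min_interactions`` consolidated two-locus interactions."""
    if consolidated is None or len(consolidated) == 0:
        return pd.DataFrame(columns=["marker", "n_interactions"])
    counts = (
        pd.concat([consolidated["marker_i"], consolidated["marker_j"]])
        .value_counts()
        .rename_axis("marker")
        .reset_index(name="n_interactions")
    )
    return counts[counts["n_interactions"] > min_interactions].reset_index(drop=True)


def remove_pairs_near_hub(
    pairs: pd.DataFrame, hub_marker: int, mmap: MarkerMap, window_bp: int = 50_000
) -> pd.DataFrame:
    """Drop comprehensive-scan pairs with a side within ``window_bp`` of the hub."""
    hc, hb = mmap.chrom[hub_marker], mmap.bp[hub_marker]

    def near(chrom, bp):
        return (chrom == hc) & (np.abs(bp - hb) <= window_bp)

    drop = near(pairs["chrom_i"].to_numpy(), pairs["bp_i"].to_numpy()) | near(
        pairs["chrom_j"].to_numpy(), pairs["bp_j"].to_numpy()
    )
    return pairs[~drop].reset_index(drop=True)


def _categorical_design(g: np.ndarray) -> np.ndarray:
    """Two dummy columns for one dosage vector."""
    return np.column_stack([(g == 1).astype(float), (g == 2).astype(float)])


def _interaction_design(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """Four dummy columns for a categorical two-way interaction."""
    cols = []
    for a in (1, 2):
        for b in (1, 2):
            cols.append(((g1 == a) & (g2 == b)).astype(float))
    return np.column_stack(cols)


def hub_forward_scan(
    res: ResidualPhenotype,
    panel: DiploidPanel,
    hub: int,
    threshold: float,
    markers: np.ndarray | None = None,
    min_cell: int = 20,
    max_rounds: int = 10,
) -> pd.DataFrame:
    """Forward regression over interaction partners of a hub locus.

    Each round tests residuals ~ hub + locus2 + covariates + hub:locus2 for
    every candidate locus2 and adds the most significant above-threshold
    partner per chromosome (with its hub interaction) to the covariates,
    until no candidate passes.  Returns the detected partners.
    """
    y = res.values
    G = panel.genotypes[res.mask]
    mmap = panel.mmap
    if markers is None:
        class_n = np.stack([(G == g).sum(axis=0) for g in (0, 1, 2)])
        markers = np.flatnonzero((class_n >= min_cell).all(axis=0))
    markers = np.asarray(markers)
    g_hub = G[:, hub]
    candidates = [m for m in markers if m != hub]

    known: list[int] = []
    rows = []
    n = y.size
    for rnd in range(1, max_rounds + 1):
        base = [np.ones((n, 1)), _categorical_design(g_hub)]
        for k in known:
            base.append(_categorical_design(G[:, k]))
            base.append(_interaction_design(g_hub, G[:, k]))
        C = np.column_stack(base)
        # residualize once against the covariate block, then each candidate
        # needs only two small regressions on its 2+4 residualized columns
        Q, _ = np.linalg.qr(C)
        rank_c = np.linalg.matrix_rank(C)
        yr = y - Q @ (Q.T @ y)
        pvals = {}
        for m in candidates:
            if m in known:
                continue
            gm = G[:, m]
            Xm = np.column_stack(
                [_categorical_design(gm), _interaction_design(g_hub, gm)]
            )
            Xr = Xm - Q @ (Q.T @ Xm)
            b_red, _, r_red, _ = np.linalg.lstsq(Xr[:, :2], yr, rcond=None)
            b_full, _, r_full, _ = np.linalg.lstsq(Xr, yr, rcond=None)
            rss_red = float(np.sum((yr - Xr[:, :2] @ b_red) ** 2))
            rss_full = float(np.sum((yr - Xr @ b_full) ** 2))
            df1 = int(r_full) - int(r_red)
            df2 = n - rank_c - int(r_full)
            if df1 <= 0 or df2 <= 0:
                pvals[m] = np.nan
                continue
            F = (max(rss_red - rss_full, 0.0) / df1) / max(rss_full / df2, 1e-300)
            pvals[m] = float(stats.f.sf(F, df1, df2))
        added = False
        for c in mmap.chromosomes:
            on_c = [m for m in pvals if mmap.chrom[m] == c and np.isfinite(pvals[m])]
            if not on_c:
                continue
            best = min(on_c, key=lambda m: (pvals[m], mmap.bp[m]))
            if pvals[best] < threshold:
                known.append(best)
                rows.append(
                    {
                        "partner": int(best),
                        "chrom": int(mmap.chrom[best]),
                        "bp": int(mmap.bp[best]),
                        "p": float(pvals[best]),
                        "round": rnd,
                    }
                )
                added = True
        if not added:
            break
    return pd.DataFrame(rows, columns=["partner", "chrom", "bp", "p", "round"])


# ---------------------------------------------------------------------------
# Three-locus scan
# ---------------------------------------------------------------------------

# main-effects + all pairwise categorical interactions over the 27 joint cells
def _d27():
    rows = []
    for a in range(3):
        for b in range(3):
            for c in range(3):
                row = [1.0, a == 1, a == 2, b == 1, b == 2, c == 1, c == 2]
                for x, yv in ((a, b), (a, c), (b, c)):
                    for u in (1, 2):
                        for v in (1, 2):
                            row.append((x == u) and (yv == v))
                rows.append(row)
    return np.array(rows, dtype=np.float64)


_D27 = _d27()


def trio_interaction_pvalues(
    y: np.ndarray, G: np.ndarray, trios: np.ndarray, min_cell: int = 0
) -> pd.DataFrame:
    """Three-way categorical interaction p values for the given marker trios.

    The model includes all main effects and pairwise categorical
    interactions; the reported p is the sequential F test of the three-way
    term (the saturated 27-cell model against the pairwise model).
    """
    y = np.asarray(y, dtype=np.float64)
    n = y.size
    trios = np.asarray(trios)
    P = trios.shape[0]
    N27 = np.empty((P, 27))
    S27 = np.empty((P, 27))
    for t in range(P):
        i, j, k = trios[t]
        code = (G[:, i].astype(np.int64) * 9 + G[:, j] * 3 + G[:, k])
        N27[t] = np.bincount(code, minlength=27)
        S27[t] = np.bincount(code, weights=y, minlength=27)
    ss_y = float(y @ y)
    F, df1, df2, p, reduced = _interaction_f_from_cells(N27, S27, ss_y, n, 19, _D27)
    if min_cell > 0:
        p = np.where((N27 >= min_cell).all(axis=1), p, np.nan)
    return pd.DataFrame(
        {
            "i": trios[:, 0],
            "j": trios[:, 1],
            "k": trios[:, 2],
            "F": F,
            "df1": df1,
            "df2": df2,
            "p": p,
            "reduced": reduced,
        }
    )


def threeway_scan(
    res: ResidualPhenotype,
    panel: DiploidPanel,
    min_cm_spacing: float = 5.0,
    trios: np.ndarray | None = None,
    threshold: float | None = None,
    n_perm: int = 1000,
    trios_per_perm: int = 10_000,
    min_cell: int = 20,
    seed: int = 0,
) -> InteractionResult:
    """Scan marker trios for three-way categorical interactions.

    Markers are thinned to at least ``min_cm_spacing`` cM apart (greedy
    left-to-right).  By default all trios of the thinned set are tested; the
    permutation null shuffles residuals and draws ``trios_per_perm`` random
    trios per permutation.
    """
    from itertools import combinations

    y = res.values
    G = panel.genotypes[res.mask]
    markers = thin_markers(panel.mmap, min_cm_spacing)
    class_n = np.stack([(G[:, markers] == g).sum(axis=0) for g in (0, 1, 2)])
    markers = markers[(class_n >= min_cell).all(axis=0)]
    local = {m: t for t, m in enumerate(markers)}
    Gs = G[:, markers]

    if trios is None:
        trios_local = np.array(list(combinations(range(markers.size), 3)))
    else:
        trios_local = np.array([[local[a], local[b], local[c]] for a, b, c in trios])
    if trios_local.size == 0:
        raise ValueError("no eligible trios")

    table = trio_interaction_pvalues(y, Gs, trios_local, min_cell=min_cell)
    elig = trios_local[np.isfinite(table["p"].to_numpy())]

    if threshold is None:
        rng = substream(seed, "trio_perm")
        minima = np.empty(n_perm)
        for b in range(n_perm):
            yp = rng.permutation(y)
            if elig.shape[0] > trios_per_perm:
                take = rng.choice(elig.shape[0], size=trios_per_perm, replace=False)
                tt = elig[take]
            else:
                tt = elig
            sub = trio_interaction_pvalues(yp, Gs, tt)
            minima[b] = np.nanmin(sub["p"].to_numpy())
        threshold = float(np.percentile(minima, 5.0))

    table = table.assign(
        marker_i=markers[table["i"]],
        marker_j=markers[table["j"]],
        marker_k=markers[table["k"]],
    )
    sig = table[table["p"] < threshold].sort_values("p").reset_index(drop=True)
    return InteractionResult(table, threshold, sig, None, markers)


# ---------------------------------------------------------------------------
# Hub resolution from family-level detections
# ---------------------------------------------------------------------------


def resolve_hub(
    family_detections: pd.DataFrame,
    hub_chrom: int,
    hub_interval: tuple,
) -> dict:
    """Refine a hub's position from overlapping family-level detections.

    The hub peak is the most significant family-level marker whose
    confidence interval overlaps ``hub_interval`` on ``hub_chrom``; the
    minimal bounds are the interval endpoints closest to the peak on each
    side among the family intervals overlapping the peak.  When no family
    detection overlaps, the scan-level interval is kept and flagged.
    """
    det = family_detections
    lo, hi = hub_interval
    on = det[
        (det["chrom"] == hub_chrom)
        & (det["ci_left"] <= hi)
        & (det["ci_right"] >= lo)
    ]
    if len(on) == 0:
        return {
            "peak_bp": int((lo + hi) // 2),
            "left": int(lo),
            "right": int(hi),
            "n_support": 0,
            "flagged": True,
        }
    best = on.loc[on["neglog10p"].idxmax()]
    peak = int(best["bp"])
    cover = on[(on["ci_left"] <= peak) & (on["ci_right"] >= peak)]
    return {
        "peak_bp": peak,
        "left": int(cover["ci_left"].max()),
        "right": int(cover["ci_right"].min()),
        "n_support": int(len(cover)),
        "flagged": False,
    }
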