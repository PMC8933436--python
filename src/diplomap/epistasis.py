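"""Partition of pairwise epistasis into additive and dominance components.

A two-locus interaction is decomposed by crossing each locus's additive
code (3S dosage centered at the heterozygote, numeric -1/0/+1) with its
dominance code (heterozygosity indicator, categorical):

    residuals ~ locus1 + locus2 + a1:a2 + d1:a2 + a1:d2 + d1:d2

with the main locus terms categorical.  The percent variance explained
(PVE) by each interaction term is its sequential sum of squares over the
total sum of squares; because the main effects span all one-locus functions
and the four products span the remaining four interaction degrees of
freedom, the four PVEs add up exactly to the interaction PVE of the
saturated nine-class model.

The fraction of an interaction in which locus1's modifying effect on locus2
acts through locus1's dominance is (d1:a2 + d1:d2) / (sum of all four), and
symmetrically for locus2.  For a hub locus entered as locus1, a modifier's
effect on the hub's additive component is add_mod = PVE(a1:a2) + PVE(a1:d2)
and on its dominance component dom_mod = PVE(d1:a2) + PVE(d1:d2); modifiers
more than 1.5 IQR above the third quartile of either distribution are major
effect modifiers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream
from .panels import MAT_CLASS_LABELS, DiploidPanel
from .scan_nonadditive import ResidualPhenotype

__all__ = [
    "EpistasisPartition",
    "partition_interaction",
    "ModifierProfile",
    "hub_modifier_magnitudes",
    "background_effect_profile",
    "mat_parent_of_origin_split",
]

TERM_ORDER = ("aa", "da", "ad", "dd")


@dataclass
class EpistasisPartition:
    """PVE of the four epistasis components of one pairwise interaction."""

    locus1: int
    locus2: int
    pve: dict  # term -> PVE (fraction of total SS)
    frac_dominance_1: float  # locus1 modifies locus2 through locus1's dominance
    frac_dominance_2: float
    ss_total: float
    flagged: bool = False  # interaction SS at noise floor or empty cells


def _sequential_ss(y: np.ndarray, blocks: list[np.ndarray]) -> np.ndarray:
    """Sequential sums of squares for ordered design blocks (R aov order)."""
    n = y.size
    ss = []
    rss_prev = float(np.sum((y - y.mean()) ** 2))
    X = np.ones((n, 1))
    for b in blocks:
        X = np.column_stack([X, b])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ beta) ** 2))
        ss.append(max(rss_prev - rss, 0.0))
        rss_prev = rss
    return np.array(ss)


def partition_interaction(
    res: ResidualPhenotype | np.ndarray,
    panel: DiploidPanel,
    locus1: int,
    locus2: int,
) -> EpistasisPartition:
    """Partition one pairwise interaction into a/d x a/d components.

    ``res`` may be a ResidualPhenotype or a plain phenotype vector aligned
    with the panel (NaN entries are skipped).  Empty joint genotype cells
    yield a reduced-rank fit and set the flag.
    """
    if isinstance(res, ResidualPhenotype):
        y_full, mask = res.residuals, res.mask
    else:
        y_full = np.asarray(res, dtype=np.float64)
        mask = np.isfinite(y_full)
    y = y_full[mask]
    g1 = panel.genotypes[mask, locus1].astype(np.float64)
    g2 = panel.genotypes[mask, locus2].astype(np.float64)
    a1, a2 = g1 - 1.0, g2 - 1.0
    d1, d2 = (g1 == 1).astype(float), (g2 == 1).astype(float)

    cells = len(np.unique(g1 * 3 + g2))
    blocks = [
        np.column_stack([d1, (g1 == 2).astype(float)]),  # locus1 categorical
        np.column_stack([d2, (g2 == 2).astype(float)]),  # locus2 categorical
        (a1 * a2)[:, None],
        (d1 * a2)[:, None],
        (a1 * d2)[:, None],
        (d1 * d2)[:, None],
    ]
    ss = _sequential_ss(y, blocks)
    ss_total = float(np.sum((y - y.mean()) ** 2))
    pve = {t: float(s / ss_total) for t, s in zip(TERM_ORDER, ss[2:])}
    total4 = sum(pve.values())
    noise_floor = total4 * ss_total <= 1e-12 * max(ss_total, 1e-300)
    if noise_floor or total4 == 0:
        f1 = f2 = np.nan
    else:
        f1 = (pve["da"] + pve["dd"]) / total4
        f2 = (pve["ad"] + pve["dd"]) / total4
    return EpistasisPartition(
        locus1,
        locus2,
        pve,
        float(f1),
        float(f2),
        ss_total,
        flagged=bool(noise_floor or cells < 9),
    )


@dataclass
class ModifierProfile:
    """Modifier magnitudes of a hub (add_mod / dom_mod) or its background profile."""

    hub: int
    table: pd.DataFrame
    overall_additive: float = np.nan
    overall_dominance: float = np.nan


def hub_modifier_magnitudes(
    partitions: list[EpistasisPartition], hub: int, min_partners: int = 5
) -> ModifierProfile:
    """add_mod / dom_mod magnitudes of every modifier of one hub.

    Every partition must have the hub as locus1.  Major effect modifiers
    are values more than 1.5 IQR above the third quartile of the respective
    magnitude distribution; with fewer than ``min_partners`` partners the
    magnitudes are reported but no outlier calls are made.
    """
    rows = []
    for p in partitions:
        if p.locus1 != hub:
            raise ValueError("partitions must be oriented with the hub as locus1")
        rows.append(
            {
                "modifier": p.locus2,
                "add_mod": p.pve["aa"] + p.pve["ad"],
                "dom_mod": p.pve["da"] + p.pve["dd"],
            }
        )
    df = pd.DataFrame(rows, columns=["modifier", "add_mod", "dom_mod"])
    df["major_additive"] = False
    df["major_dominance"] = False
    if len(df) >= min_partners:
        for col, flag in (("add_mod", "major_additive"), ("dom_mod", "major_dominance")):
            q1, q3 = np.percentile(df[col], [25, 75])
            df[flag] = df[col] > q3 + 1.5 * (q3 - q1)
    else:
        warnings.warn("fewer than 5 partners; skipping major-modifier calls")
    return ModifierProfile(hub, df)


def background_effect_profile(
    phenotype: np.ndarray,
    panel: DiploidPanel,
    hub: int,
    modifiers,
    n_boot: int = 1000,
    min_class: int = 20,
    seed: int = 0,
) -> ModifierProfile:
    """Hub effect sizes across the 81 genotype classes of four modifiers.

    For each of the 3^4 modifier genotype combinations, the hub's additive
    effect is the (undivided) difference between the mean phenotypes of
    hub 3S/3S and BY/BY diploids in that class, and the dominance effect is
    the heterozygote mean minus the homozygote midpoint; 95% confidence
    intervals come from a percentile bootstrap over diploids within the
    class.  Classes below ``min_class`` diploids (or missing a hub genotype
    cell) are reported as missing, not zero.
    """
    modifiers = list(modifiers)
    if len(modifiers) != 4:
        raise ValueError("exactly four modifiers are required")
    if hub in modifiers:
        raise ValueError("the hub cannot be one of its own modifiers")
    y = np.asarray(phenotype, dtype=np.float64)
    ok = np.isfinite(y)
    rng = substream(seed, "background_profile")

    gm = panel.genotypes[:, modifiers].astype(np.int64)
    code = gm @ (3 ** np.arange(4))
    g_hub = panel.genotypes[:, hub]

    def effects(yv, gv):
        means = [yv[gv == k].mean() if (gv == k).any() else np.nan for k in (0, 1, 2)]
        a = means[2] - means[0]
        d = means[1] - (means[0] + means[2]) / 2.0
        return a, d

    rows = []
    for cls in range(81):
        sel = ok & (code == cls)
        n = int(sel.sum())
        geno = np.base_repr(cls, base=3).zfill(4)[::-1]  # modifier dosages
        row = {"class_code": cls, "genotype": geno, "n": n}
        yv, gv = y[sel], g_hub[sel]
        cells = [(gv == k).sum() for k in (0, 1, 2)]
        if n < min_class or min(cells) == 0:
            row.update(
                a_effect=np.nan, a_lo=np.nan, a_hi=np.nan,
                d_effect=np.nan, d_lo=np.nan, d_hi=np.nan, missing=True,
            )
        else:
            a, d = effects(yv, gv)
            idx = rng.integers(0, n, size=(n_boot, n))
            yb, gb = yv[idx], gv[idx]
            boots_a = np.full(n_boot, np.nan)
            boots_d = np.full(n_boot, np.nan)
            means = np.full((n_boot, 3), np.nan)
            for k in (0, 1, 2):
                msk = gb == k
                cnt = msk.sum(axis=1)
                s = np.where(msk, yb, 0.0).sum(axis=1)
                means[:, k] = np.where(cnt > 0, s / np.maximum(cnt, 1), np.nan)
            boots_a = means[:, 2] - means[:, 0]
            boots_d = means[:, 1] - (means[:, 0] + means[:, 2]) / 2.0
            row.update(
                a_effect=a,
                a_lo=float(np.nanpercentile(boots_a, 2.5)),
                a_hi=float(np.nanpercentile(boots_a, 97.5)),
                d_effect=d,
                d_lo=float(np.nanpercentile(boots_d, 2.5)),
                d_hi=float(np.nanpercentile(boots_d, 97.5)),
                missing=False,
            )
        rows.append(row)
    table = pd.DataFrame(rows)
    oa, od = np.nan, np.nan
    if ok.any():
        oa, od = (
            float(v)
            for v in (
                y[ok & (g_hub == 2)].mean() - y[ok & (g_hub == 0)].mean(),
                y[ok & (g_hub == 1)].mean()
                - (y[ok & (g_hub == 0)].mean() + y[ok & (g_hub == 2)].mean()) / 2.0,
            )
        )
    return ModifierProfile(hub, table, oa, od)


def mat_parent_of_origin_split(
    phenotype: np.ndarray, panel: DiploidPanel, focal: int
) -> pd.DataFrame:
    """Dominance at a focal locus within each mating-locus genotype class.

    The mating locus segregates four classes (BY and 3S alleles linked to
    either the MATa or the MATalpha cassette), so heterozygotes split by
    parent of origin.  Within each class the focal locus's genotype means,
    dominance deviation, and the no-dominance heterozygote expectation are
    reported.
    """
    if panel.mat_class is None:
        raise ValueError("panel lacks MAT class annotation")
    y = np.asarray(phenotype, dtype=np.float64)
    ok = np.isfinite(y)
    g = panel.genotypes[:, focal]
    rows = []
    for cls in range(4):
        sel = ok & (panel.mat_class == cls)
        means = [
            y[sel & (g == k)].mean() if (sel & (g == k)).any() else np.nan
            for k in (0, 1, 2)
        ]
        ns = [int((sel & (g == k)).sum()) for k in (0, 1, 2)]
        expected_het = (means[0] + means[2]) / 2.0
        rows.append(
            {
                "mat_class": MAT_CLASS_LABELS[cls],
                "n_BYBY": ns[0],
                "n_het": ns[1],
                "n_3S3S": ns[2],
                "mean_BYBY": means[0],
                "mean_het": means[1],
                "mean_3S3S": means[2],
                "expected_het": expected_het,
                "dominance": means[1] - expected_het,
            }
        )
    return pd.DataFrame(rows)
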