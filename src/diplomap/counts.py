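"""Double-barcode count tables and PCR-chimera correction.

Amplicon sequencing of a fused double barcode (one barcode from each
haploid parent separated by a fixed region) produces chimeric molecules by
template switching during PCR.  The expected count of a chimeric double
barcode is proportional to the product of the abundances of its two
constituent single barcodes, which yields a simple correction: fit a line
to the counts of known-impossible barcode pairs against that product, and
subtract the model expectation from every observed pair.

Parental control strains are never mated to segregants, so any
parental-by-segregant double barcode must be a chimera; those pairs anchor
the fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CountTable", "ChimeraModel", "fit_chimera_model", "correct_counts"]


@dataclass
class CountTable:
    """Read counts for double-barcode lineages across timepoints.

    One row per observed double barcode.  ``diploid >= 0`` marks a real
    lineage (a barcode pair constructed by mating); ``diploid == -1`` marks
    a chimera-candidate pair observed only through template switching.
    ``generations`` gives the cumulative generations of growth at each
    timepoint.
    """

    bc_a: np.ndarray  # MATa-side single barcode id per row
    bc_alpha: np.ndarray  # MATalpha-side single barcode id per row
    diploid: np.ndarray  # diploid index, -1 for chimera-candidate pairs
    replicate: np.ndarray  # replicate index within diploid, -1 if n/a
    counts: np.ndarray  # (n_rows, n_timepoints) raw read counts
    generations: np.ndarray  # (n_timepoints,)
    parental_a: np.ndarray = None  # bool, MATa barcode belongs to a parental strain
    parental_alpha: np.ndarray = None
    corrected: np.ndarray = None  # chimera-corrected counts, set by correct_counts
    valid: np.ndarray = None  # lineage passes the mean-count filter
    true_counts: np.ndarray = None  # simulator ground truth (chimera-free reads)

    def __post_init__(self):
        self.bc_a = np.asarray(self.bc_a)
        self.bc_alpha = np.asarray(self.bc_alpha)
        self.diploid = np.asarray(self.diploid, dtype=np.int64)
        self.replicate = np.asarray(self.replicate, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.float64)
        self.generations = np.asarray(self.generations, dtype=np.float64)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (rows x timepoints)")
        if self.counts.shape[1] != self.generations.size:
            raise ValueError("generations length must match count columns")
        if self.counts.shape[1] < 2:
            raise ValueError("at least two timepoints are required")
        if np.any(np.diff(self.generations) <= 0):
            raise ValueError("timepoints must be strictly ordered")
        n = self.counts.shape[0]
        if self.parental_a is None:
            self.parental_a = np.zeros(n, dtype=bool)
        if self.parental_alpha is None:
            self.parental_alpha = np.zeros(n, dtype=bool)
        self.parental_a = np.asarray(self.parental_a, dtype=bool)
        self.parental_alpha = np.asarray(self.parental_alpha, dtype=bool)
        if self.valid is None:
            self.valid = self.diploid >= 0
        self.valid = np.asarray(self.valid, dtype=bool)

    @property
    def n_rows(self) -> int:
        return self.counts.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.counts.shape[1]

    @property
    def lineage_ids(self) -> np.ndarray:
        return np.char.add(np.char.add(self.bc_a.astype(str), "+"), self.bc_alpha.astype(str))

    def impossible_pairs(self) -> np.ndarray:
        """Mask of pairs that cannot be real lineages: exactly one side parental."""
        return self.parental_a ^ self.parental_alpha

    def working_counts(self) -> np.ndarray:
        """Corrected counts if available, else raw counts."""
        return self.counts if self.corrected is None else self.corrected

    # -- marginal single-barcode totals --------------------------------------
    def barcode_totals(self, per_timepoint: bool = False):
        """Total reads of every single barcode, regardless of its partner.

        Returns two dict-like Series (MATa side, MATalpha side), either
        pooled across timepoints or as (n_barcodes, T) frames.
        """
        df_a = pd.DataFrame(self.counts)
        df_a["bc"] = self.bc_a
        tot_a = df_a.groupby("bc").sum()
        df_b = pd.DataFrame(self.counts)
        df_b["bc"] = self.bc_alpha
        tot_b = df_b.groupby("bc").sum()
        if per_timepoint:
            return tot_a, tot_b
        return tot_a.sum(axis=1), tot_b.sum(axis=1)

    # -- I/O ------------------------------------------------------------------
    def to_tsv(self, path, which: str = "raw") -> None:
        mat = self.counts if which == "raw" else self.corrected
        rows = []
        lin = self.lineage_ids
        for t in range(self.n_timepoints):
            rows.append(
                pd.DataFrame(
                    {
                        "lineage_id": lin,
                        "diploid_id": self.diploid,
                        "replicate_id": self.replicate,
                        "timepoint": t,
                        "generations": self.generations[t],
                        "count": mat[:, t],
                    }
                )
            )
        pd.concat(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "CountTable":
        df = pd.read_csv(path, sep="\t")
        wide = df.pivot_table(
            index=["lineage_id", "diploid_id", "replicate_id"],
            columns="timepoint",
            values="count",
        ).sort_index(axis=1)
        gens = df.groupby("timepoint")["generations"].first().sort_index().to_numpy()
        idx = wide.index.to_frame(index=False)
        bc = idx["lineage_id"].str.split("+", n=1, expand=True)
        return cls(
            bc_a=bc[0].to_numpy(),
            bc_alpha=bc[1].to_numpy(),
            diploid=idx["diploid_id"].to_numpy(),
            replicate=idx["replicate_id"].to_numpy(),
            counts=wide.to_numpy(),
            generations=gens,
        )


@dataclass
class ChimeraModel:
    """OLS fit of chimeric-pair counts on the product of single-barcode totals."""

    intercept: float
    slope: float
    r_squared: float
    n_pairs: int
    total_reads: float

    @property
    def implied_rate(self) -> float:
        """Template-switching rate implied by the fit (slope x total reads)."""
        return self.slope * self.total_reads


def fit_chimera_model(table: CountTable, impossible: np.ndarray | None = None) -> ChimeraModel:
    """Fit the chimera linear model on known-impossible barcode pairs.

    Counts are pooled across all timepoints.  The predictor for a pair is
    the product of the two single barcodes' total read counts in the whole
    data set; the response is the pair's pooled read count.  Ordinary least
    squares with intercept.
    """
    if impossible is None:
        impossible = table.impossible_pairs()
    impossible = np.asarray(impossible, dtype=bool)
    if impossible.sum() < 3:
        raise ValueError("need at least 3 impossible pairs to fit the chimera model")

    tot_a, tot_b = table.barcode_totals()
    x = (
        tot_a.reindex(table.bc_a).to_numpy() * tot_b.reindex(table.bc_alpha).to_numpy()
    )[impossible]
    y = table.counts.sum(axis=1)[impossible]
    if np.ptp(x) == 0:
        raise ValueError("zero variance in the abundance-product predictor")

    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    slope = np.sum((x - xm) * (y - ym)) / sxx
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    sst = np.sum((y - ym) ** 2)
    r2 = 1.0 if sst == 0 else 1.0 - np.sum(resid**2) / sst
    return ChimeraModel(
        intercept=float(intercept),
        slope=float(slope),
        r_squared=float(r2),
        n_pairs=int(impossible.sum()),
        total_reads=float(table.counts.sum()),
    )


def correct_counts(
    table: CountTable, model: ChimeraModel, min_mean_count: float = 5.0
) -> CountTable:
    """Subtract the expected chimeric reads from every double barcode.

    The model expectation (clamped at zero) is computed on pooled counts and
    apportioned to timepoints proportionally to each timepoint's share of
    the pair's abundance product, so trajectories are corrected while the
    fit itself follows the pooled data.  Corrected counts below zero are set
    to zero, and lineages whose mean corrected count across timepoints falls
    below ``min_mean_count`` are flagged invalid.
    """
    tot_a_t, tot_b_t = table.barcode_totals(per_timepoint=True)
    ra = tot_a_t.reindex(table.bc_a).to_numpy()  # (rows, T)
    rb = tot_b_t.reindex(table.bc_alpha).to_numpy()
    prod_t = ra * rb  # per-timepoint abundance product
    prod_pooled = ra.sum(axis=1) * rb.sum(axis=1)

    expected_pooled = np.clip(model.intercept + model.slope * prod_pooled, 0.0, None)
    denom = prod_t.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(denom[:, None] > 0, prod_t / np.where(denom == 0, 1, denom)[:, None],
                     1.0 / table.n_timepoints)
    corrected = np.clip(table.counts - expected_pooled[:, None] * w, 0.0, None)

    valid = (table.diploid >= 0) & (corrected.mean(axis=1) >= min_mean_count)
    out = CountTable(
        bc_a=table.bc_a,
        bc_alpha=table.bc_alpha,
        diploid=table.diploid,
        replicate=table.replicate,
        counts=table.counts,
        generations=table.generations,
        parental_a=table.parental_a,
        parental_alpha=table.parental_alpha,
        corrected=corrected,
        valid=valid,
        true_counts=table.true_counts,
    )
    if valid.sum() == 0:
        warnings.warn("no lineage passes the mean corrected-count filter")
    return out
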