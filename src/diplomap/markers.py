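"""Marker maps for a biallelic two-parent cross.

Markers are biallelic SNPs segregating between the two cross founders
(labelled BY and 3S throughout), ordered by chromosome and physical
position, with both a physical (bp) and a genetic (cM) coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MarkerMap", "yeast_like_map", "thin_markers"]

# Approximate S. cerevisiae chromosome lengths (bp), chromosomes I-XVI.
YEAST_CHROM_BP = np.array(
    [230_218, 813_184, 316_620, 1_531_933, 576_874, 270_161, 1_090_940,
     562_643, 439_888, 745_751, 666_816, 1_078_177, 924_431, 784_333,
     1_091_291, 948_066],
    dtype=np.int64,
)


@dataclass(frozen=True)
class MarkerMap:
    """Ordered biallelic markers with chromosome, bp and cM coordinates.

    Markers must be sorted by (chromosome, bp) with strictly increasing bp
    and cM within each chromosome.  Every marker carries exactly two
    alleles, coded 0 (BY) and 1 (3S) elsewhere in the package.
    """

    chrom: np.ndarray  # int, 1-based chromosome id
    bp: np.ndarray  # int, 1-based physical position
    cm: np.ndarray  # float, genetic position within chromosome
    ids: np.ndarray = field(default=None)  # marker names

    def __post_init__(self):
        chrom = np.asarray(self.chrom, dtype=np.int64)
        bp = np.asarray(self.bp, dtype=np.int64)
        cm = np.asarray(self.cm, dtype=np.float64)
        if chrom.size == 0:
            raise ValueError("marker map is empty")
        if not (chrom.size == bp.size == cm.size):
            raise ValueError("chrom, bp, cm must have equal length")
        if np.any(np.diff(chrom) < 0):
            raise ValueError("markers must be sorted by chromosome")
        if np.any(cm < 0):
            raise ValueError("cM positions must be non-negative")
        for c in np.unique(chrom):
            sel = chrom == c
            if np.any(np.diff(bp[sel]) <= 0):
                raise ValueError(f"bp not strictly increasing on chromosome {c}")
            if np.any(np.diff(cm[sel]) <= 0):
                raise ValueError(f"cM not strictly increasing on chromosome {c}")
        ids = self.ids
        if ids is None:
            ids = np.array([f"chr{c:02d}_{p}" for c, p in zip(chrom, bp)])
        object.__setattr__(self, "chrom", chrom)
        object.__setattr__(self, "bp", bp)
        object.__setattr__(self, "cm", cm)
        object.__setattr__(self, "ids", np.asarray(ids))

    @property
    def n_markers(self) -> int:
        return self.chrom.size

    @property
    def chromosomes(self) -> np.ndarray:
        return np.unique(self.chrom)

    def chrom_indices(self, c: int) -> np.ndarray:
        """Indices of the markers on chromosome ``c`` (in map order)."""
        return np.flatnonzero(self.chrom == c)

    def chrom_length_bp(self, c: int) -> int:
        """Physical span proxy: last marker position on the chromosome."""
        return int(self.bp[self.chrom == c].max())

    def chrom_length_cm(self, c: int) -> float:
        return float(self.cm[self.chrom == c].max())

    def subset(self, idx) -> "MarkerMap":
        idx = np.asarray(idx)
        return MarkerMap(self.chrom[idx], self.bp[idx], self.cm[idx], self.ids[idx])

    # -- I/O ---------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"marker": self.ids, "chrom": self.chrom, "bp": self.bp, "cm": self.cm}
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "MarkerMap":
        df = pd.read_csv(path, sep="\t")
        return cls(
            df["chrom"].to_numpy(),
            df["bp"].to_numpy(),
            df["cm"].to_numpy(),
            df["marker"].to_numpy(),
        )


def yeast_like_map(
    n_markers: int = 1000,
    n_chrom: int = 16,
    total_cm: float = 750.0,
    rng: np.random.Generator | None = None,
) -> MarkerMap:
    """Build a marker map resembling the 16-chromosome yeast genome.

    Marker counts per chromosome are proportional to physical length, with
    at least three markers per chromosome.  bp positions are uniform random
    (sorted); cM positions are proportional to bp within the chromosome,
    with the genome-wide genetic length fixed at ``total_cm``.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if n_chrom < 1 or n_chrom > 16:
        raise ValueError("n_chrom must be in 1..16")
    lengths = YEAST_CHROM_BP[:n_chrom].astype(float)
    weights = lengths / lengths.sum()
    per_chrom = np.maximum(3, np.round(weights * n_markers).astype(int))
    cm_per_chrom = total_cm * weights

    chroms, bps, cms = [], [], []
    for c in range(n_chrom):
        m = per_chrom[c]
        pos = np.sort(rng.choice(np.arange(1, int(lengths[c])), size=m, replace=False))
        chroms.append(np.full(m, c + 1))
        bps.append(pos)
        # strictly increasing cM, proportional to bp
        cms.append(cm_per_chrom[c] * pos / lengths[c])
    return MarkerMap(np.concatenate(chroms), np.concatenate(bps), np.concatenate(cms))


def thin_markers(mmap: MarkerMap, min_cm: float = 5.0) -> np.ndarray:
    """Greedy left-to-right thinning to a minimum cM spacing.

    Within each chromosome the first marker is kept and each subsequent
    marker is kept only if it lies at least ``min_cm`` centimorgans beyond
    the last kept marker.  Returns indices into the map.
    """
    keep = []
    for c in mmap.chromosomes:
        idx = mmap.chrom_indices(c)
        last = -np.inf
        for i in idx:
            # small tolerance so exact-spacing grids are not broken by rounding
            if mmap.cm[i] - last >= min_cm - 1e-9 or not np.isfinite(last):
                keep.append(i)
                last = mmap.cm[i]
    return np.array(sorted(keep))
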