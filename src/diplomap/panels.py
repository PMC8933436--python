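"""Haploid segregant panels and factorially mated diploid panels.

Haploid genotypes are coded 0 (BY allele) / 1 (3S allele).  Diploid
genotypes are coded as 3S allele dosage 0/1/2, i.e. the sum of the two
parental haploid codes.  Diploids sharing a haploid parent form a family.

The mating locus on chromosome III is tracked explicitly: a MATa parent
contributes its ChrIII allele linked to the MATa cassette and a MATalpha
parent its allele linked to the MATalpha cassette, so the two heterozygous
diploid classes at this locus are distinguishable by parent of origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markers import MarkerMap

__all__ = ["HaploidPanel", "DiploidPanel", "mate_panels", "MAT_CLASS_LABELS"]

MAT_A, MAT_ALPHA = 0, 1

# MAT parent-of-origin classes for a diploid, keyed by
# (allele from MATa parent, allele from MATalpha parent) at the ChrIII marker.
MAT_CLASS_LABELS = np.array(
    ["BYa/BYalpha", "3Sa/3Salpha", "BYa/3Salpha", "3Sa/BYalpha"]
)
_MAT_CLASS_CODE = {(0, 0): 0, (1, 1): 1, (0, 1): 2, (1, 0): 3}


def default_mat_marker(mmap: MarkerMap, mat_chrom: int = 3) -> int:
    """Designate the ChrIII marker closest to mid-chromosome as the MAT locus."""
    idx = mmap.chrom_indices(mat_chrom)
    if idx.size == 0:
        raise ValueError(f"no markers on chromosome {mat_chrom}")
    mid = (mmap.bp[idx].min() + mmap.bp[idx].max()) / 2
    return int(idx[np.argmin(np.abs(mmap.bp[idx] - mid))])


@dataclass
class HaploidPanel:
    """A panel of haploid segregants with known genotypes.

    Attributes
    ----------
    mmap : MarkerMap
    genotypes : (n_segregants, n_markers) int8, 0=BY, 1=3S
    mating_type : (n,) int8, 0=MATa, 1=MATalpha
    mat_marker : index of the designated mating-locus marker on ChrIII
    n_barcodes : (n,) int, uniquely barcoded clones per segregant
    """

    mmap: MarkerMap
    genotypes: np.ndarray
    mating_type: np.ndarray
    mat_marker: int
    n_barcodes: np.ndarray = field(default=None)

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.mating_type = np.asarray(self.mating_type, dtype=np.int8)
        if self.genotypes.shape[1] != self.mmap.n_markers:
            raise ValueError("genotype matrix does not match marker map")
        if self.genotypes.shape[0] != self.mating_type.size:
            raise ValueError("mating_type length mismatch")
        if self.n_barcodes is None:
            self.n_barcodes = np.full(self.n_segregants, 2, dtype=np.int64)
        self.n_barcodes = np.asarray(self.n_barcodes, dtype=np.int64)

    @property
    def n_segregants(self) -> int:
        return self.genotypes.shape[0]

    @property
    def mat_allele(self) -> np.ndarray:
        """Allele of origin at the mating locus: the genotype at the MAT marker."""
        return self.genotypes[:, self.mat_marker]

    def subset(self, mask) -> "HaploidPanel":
        mask = np.asarray(mask)
        return HaploidPanel(
            self.mmap,
            self.genotypes[mask],
            self.mating_type[mask],
            self.mat_marker,
            self.n_barcodes[mask],
        )

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.genotypes, columns=self.mmap.ids)
        df.insert(0, "mating_type", np.where(self.mating_type == MAT_A, "MATa", "MATalpha"))
        df.insert(1, "n_barcodes", self.n_barcodes)
        df.to_csv(path, sep="\t", index=True, index_label="segregant")


@dataclass
class DiploidPanel:
    """Full factorial diploid panel with family labels and MAT classes.

    ``genotypes`` holds the 3S allele dosage (0/1/2) per diploid per marker;
    each row equals the sum of the two parental haploid rows.  ``mata_parent``
    and ``matalpha_parent`` index into the respective haploid panels and
    define the two family labellings.
    """

    mmap: MarkerMap
    genotypes: np.ndarray  # (n_diploids, n_markers) int8 dosage of 3S
    mata_parent: np.ndarray
    matalpha_parent: np.ndarray
    mat_class: np.ndarray  # int8 code into MAT_CLASS_LABELS
    mat_marker: int
    n_replicates: np.ndarray = field(default=None)  # barcode-pair lineages per diploid

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.mata_parent = np.asarray(self.mata_parent, dtype=np.int64)
        self.matalpha_parent = np.asarray(self.matalpha_parent, dtype=np.int64)
        self.mat_class = np.asarray(self.mat_class, dtype=np.int8)
        if self.n_replicates is None:
            self.n_replicates = np.full(self.n_diploids, 2, dtype=np.int64)
        self.n_replicates = np.asarray(self.n_replicates, dtype=np.int64)

    @property
    def n_diploids(self) -> int:
        return self.genotypes.shape[0]

    @property
    def heterozygous(self) -> np.ndarray:
        """(n, m) boolean heterozygosity indicator."""
        return self.genotypes == 1

    @property
    def mat_heterozygous(self) -> np.ndarray:
        return self.genotypes[:, self.mat_marker] == 1

    def family_members(self, mata_parent: int) -> np.ndarray:
        """Indices of the diploids descending from one MATa parent."""
        return np.flatnonzero(self.mata_parent == mata_parent)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.genotypes, columns=self.mmap.ids)
        df.insert(0, "mata_parent", self.mata_parent)
        df.insert(1, "matalpha_parent", self.matalpha_parent)
        df.insert(2, "mat_class", MAT_CLASS_LABELS[self.mat_class])
        df.to_csv(path, sep="\t", index=True, index_label="diploid")

    @classmethod
    def from_tsv(cls, path, mmap: MarkerMap, mat_marker: int | None = None) -> "DiploidPanel":
        df = pd.read_csv(path, sep="\t", index_col="diploid")
        label_code = {lab: i for i, lab in enumerate(MAT_CLASS_LABELS)}
        if mat_marker is None:
            mat_marker = default_mat_marker(mmap) if np.any(mmap.chrom == 3) else 0
        return cls(
            mmap,
            df[mmap.ids].to_numpy(dtype=np.int8),
            df["mata_parent"].to_numpy(),
            df["matalpha_parent"].to_numpy(),
            np.array([label_code[x] for x in df["mat_class"]], dtype=np.int8),
            mat_marker,
        )


def mate_panels(mata: HaploidPanel, matalpha: HaploidPanel) -> DiploidPanel:
    """Mate every MATa segregant to every MATalpha segregant.

    Produces the full factorial panel of ``n_a * n_alpha`` diploids whose
    genotype rows are the sums of the two parental rows, with the MAT
    parent-of-origin class recorded from the parents' ChrIII alleles.
    The number of barcode-pair lineages per diploid is the product of the
    two parents' barcode counts.
    """
    if mata.mmap.n_markers != matalpha.mmap.n_markers or not (
        np.array_equal(mata.mmap.chrom, matalpha.mmap.chrom)
        and np.array_equal(mata.mmap.bp, matalpha.mmap.bp)
    ):
        raise ValueError("parents were genotyped on different marker maps")
    if np.any(mata.mating_type != MAT_A) or np.any(matalpha.mating_type != MAT_ALPHA):
        raise ValueError("panels must be pure MATa and MATalpha respectively")

    na, nalpha = mata.n_segregants, matalpha.n_segregants
    ia = np.repeat(np.arange(na), nalpha)
    ja = np.tile(np.arange(nalpha), na)
    geno = mata.genotypes[ia].astype(np.int8) + matalpha.genotypes[ja].astype(np.int8)

    a_allele = mata.mat_allele[ia]
    alpha_allele = matalpha.mat_allele[ja]
    mat_class = np.empty(na * nalpha, dtype=np.int8)
    for (aa, bb), code in _MAT_CLASS_CODE.items():
        mat_class[(a_allele == aa) & (alpha_allele == bb)] = code

    n_rep = mata.n_barcodes[ia] * matalpha.n_barcodes[ja]
    return DiploidPanel(
        mata.mmap, geno, ia, ja, mat_class, mata.mat_marker, n_rep
    )
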