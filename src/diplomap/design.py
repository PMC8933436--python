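"""Experimental design arithmetic for the barcoded diploid cross.

Small closed-form helpers for the scale of the design: panel sizes from
factorial mating, barcode-pair and UMI label spaces, bottleneck census
sizes, and the class counts of the categorical interaction models.
"""

from __future__ import annotations

__all__ = [
    "n_diploids",
    "n_double_barcodes",
    "umi_label_space",
    "bottleneck_size",
    "n_joint_classes",
    "n_modifier_classes",
]


def n_diploids(n_mata: int, n_matalpha: int) -> int:
    """Diploids produced by full factorial mating."""
    return n_mata * n_matalpha


def n_double_barcodes(n_mata: int, n_matalpha: int, replicates_per_diploid: int = 4) -> int:
    """Total double-barcode lineages across the panel."""
    return n_diploids(n_mata, n_matalpha) * replicates_per_diploid


def umi_label_space(n_mers: int = 2, k: int = 3) -> int:
    """Distinct unique-molecular-identifier labels from ``n_mers`` random k-mers."""
    return 4 ** (n_mers * k)


def bottleneck_size(cells_per_lineage: float, dilution: float) -> float:
    """Cells per lineage surviving a 1:(1/dilution) serial-transfer bottleneck."""
    if not 0 < dilution < 1:
        raise ValueError("dilution must be in (0, 1)")
    return cells_per_lineage * dilution


def n_joint_classes(n_loci: int = 2) -> int:
    """Genotype classes of the fully categorical n-locus interaction model."""
    return 3**n_loci


def n_modifier_classes(n_modifiers: int = 4) -> int:
    """Genotype classes defined by a set of modifier loci."""
    return 3**n_modifiers
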