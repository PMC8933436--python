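"""End-to-end synthetic study: cross, trait, and pooled readout.

Bundles the simulation stages behind one configuration object so a whole
synthetic experiment — marker map, segregant panels, factorial diploid
panel, trait architecture, true fitness, and the barcode count table — can
be produced from a single seed.  Defaults are desk scale: 16 chromosomes,
750 cM, 1,000 markers, 50 MATa x 60 MATalpha parents with two barcodes
each, four serial-batch cycles at 1:8 dilution, and a PCR chimera rate of
0.11%.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

from ._rng import substream
from .markers import MarkerMap, yeast_like_map
from .panels import DiploidPanel, HaploidPanel, mate_panels, MAT_A, MAT_ALPHA
from .simulate import (
    Interaction,
    TraitArchitecture,
    simulate_gametes,
    simulate_phenotypes,
    simulate_pool_counts,
)

__all__ = ["StudyConfig", "Study", "random_architecture", "simulate_study"]


@dataclass
class StudyConfig:
    """Parameters of a synthetic study (defaults are desk scale)."""

    n_markers: int = 1000
    n_chrom: int = 16
    total_cm: float = 750.0
    n_mata: int = 50
    n_matalpha: int = 60
    barcodes_per_segregant: int = 2
    crossover_rate: float = 1.0
    # trait architecture
    n_qtl: int = 12
    additive_sd: float = 0.05
    mean_degree: float = 0.5
    degree_sd: float = 0.4
    n_hub_partners: int = 0
    hub_aa: float = 0.04
    hub_dd: float = 0.0
    mat_modifier: bool = True
    target_h2: float = 0.6
    # competition and sequencing
    cycles: int = 4
    dilution: float = 0.125
    depth: float = 2e6
    chimera_rate: float = 1.1e-3
    cells_per_lineage: float = 2000.0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Study:
    """A fully simulated study with ground truth at every stage."""

    config: StudyConfig
    mmap: MarkerMap
    mata: HaploidPanel
    matalpha: HaploidPanel
    panel: DiploidPanel
    arch: TraitArchitecture
    fitness: np.ndarray  # true per-diploid fitness
    counts: object = None  # CountTable when simulated


def random_architecture(
    mmap: MarkerMap,
    panel: DiploidPanel,
    config: StudyConfig,
    seed: int,
) -> TraitArchitecture:
    """Draw a trait architecture under the configured study conditions.

    QTL positions are sampled without replacement across the map; additive
    effects are Gaussian; each QTL's dominance deviation is its |a| times a
    Gaussian degree of dominance.  An optional hub interacts (additive by
    additive, optionally dominance by dominance) with partners on distinct
    chromosomes, and the mating locus can mask the dominance of the
    largest-dominance QTL in one heterozygous parent-of-origin class.
    The residual noise SD is set from the realized genetic variance to hit
    ``target_h2``.
    """
    rng = substream(seed, "architecture")
    qtl = np.sort(rng.choice(mmap.n_markers, size=config.n_qtl, replace=False))
    a = rng.normal(0.0, config.additive_sd, size=config.n_qtl)
    degree = rng.normal(config.mean_degree, config.degree_sd, size=config.n_qtl)
    d = degree * np.abs(a)
    arch = TraitArchitecture(
        additive={int(j): float(v) for j, v in zip(qtl, a)},
        dominance={int(j): float(v) for j, v in zip(qtl, d)},
        noise_sd=0.0,
    )
    if config.n_hub_partners > 0:
        hub = int(qtl[int(np.argmax(np.abs(a)))])
        others = np.setdiff1d(np.arange(mmap.n_markers), [hub])
        chroms_seen = {int(mmap.chrom[hub])}
        partners = []
        for j in rng.permutation(others):
            c = int(mmap.chrom[j])
            if c in chroms_seen:
                continue
            partners.append(int(j))
            chroms_seen.add(c)
            if len(partners) == config.n_hub_partners:
                break
        for j in partners:
            sign = rng.choice([-1.0, 1.0])
            arch.interactions.append(
                Interaction(hub, j, aa=sign * config.hub_aa, dd=config.hub_dd)
            )
    if config.mat_modifier and arch.dominance:
        focal = max(arch.dominance, key=lambda j: abs(arch.dominance[j]))
        # dominance masked in the BYa/3Salpha heterozygous class
        arch.mat_dominance_multiplier[focal] = {2: 0.0, 3: 1.0}

    g = arch.genetic_values(panel)
    var_g = float(np.var(g))
    h2 = config.target_h2
    arch.noise_sd = float(np.sqrt(var_g * (1.0 - h2) / h2)) if var_g > 0 else 0.0
    return arch


def simulate_study(
    config: StudyConfig | None = None, seed: int = 0, with_counts: bool = True
) -> Study:
    """Simulate the full study from a single seed."""
    if config is None:
        config = StudyConfig()
    rng_map = substream(seed, "map")
    mmap = yeast_like_map(config.n_markers, config.n_chrom, config.total_cm, rng_map)
    n_seg = 2 * max(config.n_mata, config.n_matalpha) + 20
    hap = simulate_gametes(
        mmap,
        n_segregants=n_seg,
        crossover_rate=config.crossover_rate,
        seed=seed,
        n_barcodes=config.barcodes_per_segregant,
    )
    mata_all = hap.subset(hap.mating_type == MAT_A)
    matalpha_all = hap.subset(hap.mating_type == MAT_ALPHA)
    if mata_all.n_segregants < config.n_mata or matalpha_all.n_segregants < config.n_matalpha:
        raise RuntimeError("not enough segregants of each mating type; increase n_seg")
    mata = mata_all.subset(np.arange(config.n_mata))
    matalpha = matalpha_all.subset(np.arange(config.n_matalpha))
    panel = mate_panels(mata, matalpha)
    arch = random_architecture(mmap, panel, config, seed)
    fitness = simulate_phenotypes(panel, arch, seed)
    counts = None
    if with_counts:
        counts = simulate_pool_counts(
            panel,
            fitness,
            cycles=config.cycles,
            dilution=config.dilution,
            depth_per_timepoint=config.depth,
            chimera_rate=config.chimera_rate,
            seed=seed,
            barcodes_per_parent=(
                config.barcodes_per_segregant,
                config.barcodes_per_segregant,
            ),
            cells_per_lineage=config.cells_per_lineage,
        )
    return Study(config, mmap, mata, matalpha, panel, arch, fitness, counts)
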