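"""Synthetic cross, trait, and pooled-sequencing simulator.

This module generates ground-truth data for every downstream stage of the
pipeline: haploid segregants produced by meiosis of a two-parent diploid,
a full factorial mating into a diploid panel, a quantitative trait with
additive, dominance, epistatic, and mating-locus parent-of-origin effects,
a serial-batch pooled competition read out by amplicon sequencing with PCR
chimeras, and low-coverage whole-genome allele fractions for genotype
calling.

Meiosis model
-------------
Crossovers occur as a Poisson process along the genetic map with no
interference (Haldane).  Rather than materialising breakpoints, marker
phases are simulated as the equivalent two-state Markov chain: the phase
switches between adjacent markers separated by d cM with probability
(1 - exp(-2d/100)) / 2, which is exactly the parity distribution of a
Poisson(d/100) crossover count.  A crossover_rate multiplier scales the
map length (0 disables recombination).

Competition model
-----------------
Within each serial-batch cycle, lineage cell numbers evolve as

    n_i(t+1) = n_i(t) * 2**dg * exp((s_i - sbar(t)) * dg)

where dg = log2(1/dilution) generations per cycle and sbar(t) is the
abundance-weighted mean fitness; the neutral doubling term keeps the
population stationary across the 1:dilution bottleneck (binomially
sampled).  Reads at each timepoint are multinomial at the stated depth,
and chimeric double-barcode reads are added with expectation
chimera_rate * reads(bc1) * reads(bc2) / total reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import substream
from .counts import CountTable
from .markers import MarkerMap
from .panels import MAT_A, MAT_ALPHA, DiploidPanel, HaploidPanel, default_mat_marker

__all__ = [
    "simulate_gametes",
    "Interaction",
    "TraitArchitecture",
    "simulate_phenotypes",
    "simulate_pool_counts",
    "AlleleFractionMatrix",
    "simulate_allele_fractions",
]


def simulate_gametes(
    mmap: MarkerMap,
    n_segregants: int,
    crossover_rate: float = 1.0,
    seed: int = 0,
    parent_genomes: np.ndarray | None = None,
    fraction_mata: float = 0.5,
    mat_marker: int | None = None,
    n_barcodes: int = 2,
) -> HaploidPanel:
    """Simulate haploid segregants from meiosis of a two-parent diploid.

    Each segregant is a mosaic of the two parental genomes with Poisson
    crossovers (no interference) along the cM map; the expected number of
    crossovers per chromosome is its cM length / 100 times
    ``crossover_rate``.  Mating types are assigned in the configured
    proportion (exact counts, shuffled).
    """
    if n_segregants < 2:
        raise ValueError("n_segregants must be >= 2")
    if crossover_rate < 0:
        raise ValueError("crossover_rate must be non-negative")
    if parent_genomes is None:
        parent_genomes = np.vstack(
            [np.zeros(mmap.n_markers, np.int8), np.ones(mmap.n_markers, np.int8)]
        )
    parent_genomes = np.asarray(parent_genomes, dtype=np.int8)
    if parent_genomes.shape != (2, mmap.n_markers):
        raise ValueError("parent_genomes must be (2, n_markers)")

    rng = substream(seed, "gametes")
    phase = np.empty((n_segregants, mmap.n_markers), dtype=np.int8)
    for c in mmap.chromosomes:
        idx = mmap.chrom_indices(c)
        d = np.diff(mmap.cm[idx]) * crossover_rate
        # parity of a Poisson(d/100) crossover count between adjacent markers
        p_switch = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
        start = rng.integers(0, 2, size=n_segregants, dtype=np.int8)
        switches = (rng.random((n_segregants, d.size)) < p_switch).astype(np.int8)
        chain = np.concatenate([start[:, None], switches], axis=1)
        phase[:, idx] = np.cumsum(chain, axis=1, dtype=np.int64) % 2

    genotypes = np.take_along_axis(
        parent_genomes.T[None, :, :], phase[:, :, None].astype(np.int64), axis=2
    )[:, :, 0]

    n_a = int(round(fraction_mata * n_segregants))
    mating = np.concatenate(
        [np.full(n_a, MAT_A, np.int8), np.full(n_segregants - n_a, MAT_ALPHA, np.int8)]
    )
    rng.shuffle(mating)
    if mat_marker is None:
        mat_marker = default_mat_marker(mmap) if np.any(mmap.chrom == 3) else 0
    return HaploidPanel(
        mmap,
        genotypes,
        mating,
        mat_marker,
        np.full(n_segregants, n_barcodes, dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# Trait architecture
# ---------------------------------------------------------------------------


@dataclass
class Interaction:
    """A pairwise interaction split into its four additive/dominance parts.

    Effects multiply the centered dosage code ``x - 1`` (additive side) and
    the heterozygosity indicator ``h`` (dominance side) of each locus:
    aa*(x1-1)(x2-1) + da*h1*(x2-1) + ad*(x1-1)*h2 + dd*h1*h2.
    """

    locus1: int
    locus2: int
    aa: float = 0.0
    da: float = 0.0
    ad: float = 0.0
    dd: float = 0.0


@dataclass
class TraitArchitecture:
    """Genetic architecture of the simulated trait.

    additive : {marker index: a}, effect of one 3S allele (trait changes by
        2a between the homozygotes).
    dominance : {marker index: d}, deviation of heterozygotes from the
        homozygote midpoint.
    interactions : list of Interaction.
    mat_dominance_multiplier : {focal marker: {MAT class code: multiplier}};
        the dominance deviation d at a designated focal locus is multiplied
        by the class-specific factor, so a parent-of-origin dominance
        modifier at the mating locus can be planted (unlisted classes keep
        multiplier 1).
    noise_sd : environmental (residual) standard deviation.
    n_env : number of replicate environments sharing the genetic values.
    """

    additive: dict = field(default_factory=dict)
    dominance: dict = field(default_factory=dict)
    interactions: list = field(default_factory=list)
    mat_dominance_multiplier: dict = field(default_factory=dict)
    noise_sd: float = 0.1
    n_env: int = 1

    def causal_markers(self) -> set:
        out = set(self.additive) | set(self.dominance) | set(self.mat_dominance_multiplier)
        for it in self.interactions:
            out |= {it.locus1, it.locus2}
        return out

    def genetic_values(self, panel: DiploidPanel) -> np.ndarray:
        m = panel.genotypes.shape[1]
        bad = [j for j in self.causal_markers() if not 0 <= j < m]
        if bad:
            raise ValueError(f"causal markers outside the map: {bad}")
        x = panel.genotypes.astype(np.float64)
        h = (panel.genotypes == 1).astype(np.float64)
        y = np.zeros(panel.n_diploids)
        for j, a in self.additive.items():
            y += a * (x[:, j] - 1.0)
        for j, d in self.dominance.items():
            mult = np.ones(panel.n_diploids)
            if j in self.mat_dominance_multiplier:
                for cls, f in self.mat_dominance_multiplier[j].items():
                    mult[panel.mat_class == cls] = f
            y += d * h[:, j] * mult
        for it in self.interactions:
            x1, x2 = x[:, it.locus1] - 1.0, x[:, it.locus2] - 1.0
            h1, h2 = h[:, it.locus1], h[:, it.locus2]
            y += it.aa * x1 * x2 + it.da * h1 * x2 + it.ad * x1 * h2 + it.dd * h1 * h2
        return y


def simulate_phenotypes(
    panel: DiploidPanel, arch: TraitArchitecture, seed: int = 0
) -> np.ndarray:
    """True per-diploid fitness: genetic value plus Gaussian noise.

    Returns shape (n_diploids,) when ``arch.n_env == 1`` and
    (n_diploids, n_env) otherwise; the genetic value is shared across
    environments while noise is drawn independently.
    """
    rng = substream(seed, "phenotypes")
    g = arch.genetic_values(panel)
    noise = rng.normal(0.0, arch.noise_sd, size=(panel.n_diploids, arch.n_env))
    y = g[:, None] + noise
    return y[:, 0] if arch.n_env == 1 else y


# ---------------------------------------------------------------------------
# Pooled competition and sequencing readout
# ---------------------------------------------------------------------------


def simulate_pool_counts(
    panel: DiploidPanel,
    fitness: np.ndarray,
    cycles: int = 4,
    generations_per_cycle: float | None = None,
    dilution: float = 1.0 / 8.0,
    depth_per_timepoint: float | np.ndarray = 2e6,
    chimera_rate: float = 0.0,
    seed: int = 0,
    barcodes_per_parent: tuple = (2, 2),
    cells_per_lineage: float = 2000.0,
    replicate_jitter_sd: float = 0.0,
    include_parents: bool = True,
    n_parent_barcodes: int = 3,
    parental_fraction: float = 0.05,
    parental_fitness: float = 0.0,
    sampling: str = "multinomial",
    keep_truth: bool = True,
) -> CountTable:
    """Simulate the pooled serial-batch competition and barcode sequencing.

    Every diploid contributes one lineage per barcode pair (the factorial
    combination of its two parents' barcodes).  Four parental control
    diploids, barcoded independently, are spiked in at ``parental_fraction``
    of the starting pool; their pairings with segregant barcodes can only
    arise by template switching, which anchors the chimera model downstream.

    ``sampling='exact'`` disables all stochastic sampling (expected reads
    and noiseless bottlenecks) for closed-form checks.
    """
    if not 0.0 < dilution < 1.0:
        raise ValueError("dilution must be in (0, 1)")
    if cycles < 1:
        raise ValueError("cycles must be >= 1")
    n_t = cycles + 1
    depth = np.broadcast_to(np.asarray(depth_per_timepoint, dtype=np.float64), (n_t,)).copy()
    if np.any(depth <= 0):
        raise ValueError("sequencing depth must be positive at every timepoint")
    if generations_per_cycle is None:
        generations_per_cycle = float(np.log2(1.0 / dilution))
    dg = float(generations_per_cycle)
    fitness = np.asarray(fitness, dtype=np.float64)
    if fitness.shape != (panel.n_diploids,):
        raise ValueError("fitness must have one entry per diploid")

    rng = substream(seed, "pool")
    ka, kal = barcodes_per_parent

    # --- enumerate lineages --------------------------------------------------
    n_dip = panel.n_diploids
    dip = np.repeat(np.arange(n_dip), ka * kal)
    rep = np.tile(np.arange(ka * kal), n_dip)
    bca_local, bcal_local = rep // kal, rep % kal
    bc_a = np.char.add(
        np.char.add("a", panel.mata_parent[dip].astype(str)),
        np.char.add(".", bca_local.astype(str)),
    )
    bc_alpha = np.char.add(
        np.char.add("o", panel.matalpha_parent[dip].astype(str)),
        np.char.add(".", bcal_local.astype(str)),
    )
    s = fitness[dip]
    par_a = np.zeros(dip.size, dtype=bool)
    par_al = np.zeros(dip.size, dtype=bool)
    cells0 = np.full(dip.size, cells_per_lineage, dtype=np.float64)

    if include_parents:
        # 4 parental diploids (BY/BY, BY/3S, 3S/BY, 3S/3S), each from dedicated
        # parental barcodes; diploid id -2 marks parental controls.
        pa_names = ["pBYa", "p3Sa"]
        pal_names = ["pBYo", "p3So"]
        rows_a, rows_al = [], []
        for na in pa_names:
            for no in pal_names:
                for i in range(n_parent_barcodes):
                    for j in range(n_parent_barcodes):
                        rows_a.append(f"{na}.{i}")
                        rows_al.append(f"{no}.{j}")
        n_par = len(rows_a)
        bc_a = np.concatenate([bc_a, np.array(rows_a)])
        bc_alpha = np.concatenate([bc_alpha, np.array(rows_al)])
        dip = np.concatenate([dip, np.full(n_par, -2)])
        rep = np.concatenate([rep, np.arange(n_par)])
        s = np.concatenate([s, np.full(n_par, float(parental_fitness))])
        par_a = np.concatenate([par_a, np.ones(n_par, dtype=bool)])
        par_al = np.concatenate([par_al, np.ones(n_par, dtype=bool)])
        par_cells = parental_fraction * cells0.sum() / n_par
        cells0 = np.concatenate([cells0, np.full(n_par, par_cells)])

    if replicate_jitter_sd > 0:
        jit = rng.normal(0.0, replicate_jitter_sd, size=cells0.size)
        cells0 = cells0 * np.exp(jit - replicate_jitter_sd**2 / 2.0)

    # --- competition dynamics ------------------------------------------------
    n_rows = cells0.size
    true_reads = np.zeros((n_rows, n_t))
    cells = cells0.copy()
    gens = np.arange(n_t) * dg
    for t in range(n_t):
        freq = cells / cells.sum()
        if sampling == "exact":
            true_reads[:, t] = freq * depth[t]
        else:
            true_reads[:, t] = rng.multinomial(int(depth[t]), freq)
        if t == n_t - 1:
            break
        sbar = float(np.dot(freq, s))
        grown = cells * 2.0**dg * np.exp((s - sbar) * dg)
        if sampling == "exact":
            cells = grown * dilution
        else:
            cells = rng.binomial(np.round(grown).astype(np.int64), dilution).astype(float)
            cells = np.maximum(cells, 0.0)

    # --- chimeric reads ------------------------------------------------------
    if chimera_rate > 0:
        uniq_a, inv_a = np.unique(bc_a, return_inverse=True)
        uniq_al, inv_al = np.unique(bc_alpha, return_inverse=True)
        chim = np.zeros((uniq_a.size, uniq_al.size, n_t))
        for t in range(n_t):
            ra = np.bincount(inv_a, weights=true_reads[:, t], minlength=uniq_a.size)
            rb = np.bincount(inv_al, weights=true_reads[:, t], minlength=uniq_al.size)
            lam = chimera_rate * np.outer(ra, rb) / max(true_reads[:, t].sum(), 1.0)
            chim[:, :, t] = lam if sampling == "exact" else rng.poisson(lam)
        observed = true_reads + chim[inv_a, inv_al, :]
        chim[inv_a, inv_al, :] = 0.0  # remaining mass lands on non-lineage pairs
        # keep every impossible (parental x segregant) pair, even at zero reads,
        # so the chimera regression is not truncated to positive counts
        pma = np.char.startswith(uniq_a, "p")
        pmal = np.char.startswith(uniq_al, "p")
        keep = (pma[:, None] ^ pmal[None, :]) | (chim.sum(axis=2) > 0)
        extra = np.argwhere(keep)
        if extra.size:
            ex_a, ex_al = extra[:, 0], extra[:, 1]
            bc_a = np.concatenate([bc_a, uniq_a[ex_a]])
            bc_alpha = np.concatenate([bc_alpha, uniq_al[ex_al]])
            dip = np.concatenate([dip, np.full(ex_a.size, -1)])
            rep = np.concatenate([rep, np.full(ex_a.size, -1)])
            par_a = np.concatenate([par_a, np.char.startswith(uniq_a[ex_a], "p")])
            par_al = np.concatenate([par_al, np.char.startswith(uniq_al[ex_al], "p")])
            observed = np.vstack([observed, chim[ex_a, ex_al, :]])
            true_reads = np.vstack([true_reads, np.zeros((ex_a.size, n_t))])
    else:
        observed = true_reads.copy()

    # parental controls keep diploid id -2 so they are excluded from genetics
    return CountTable(
        bc_a=bc_a,
        bc_alpha=bc_alpha,
        diploid=dip,
        replicate=rep,
        counts=observed,
        generations=gens,
        parental_a=par_a,
        parental_alpha=par_al,
        true_counts=true_reads if keep_truth else None,
    )


# ---------------------------------------------------------------------------
# Low-coverage sequencing of haploid segregants
# ---------------------------------------------------------------------------


@dataclass
class AlleleFractionMatrix:
    """Per-segregant, per-marker 3S read counts and total coverage."""

    reads_3s: np.ndarray  # (n_segregants, n_markers)
    total: np.ndarray

    def __post_init__(self):
        self.reads_3s = np.asarray(self.reads_3s, dtype=np.int64)
        self.total = np.asarray(self.total, dtype=np.int64)
        if self.reads_3s.shape != self.total.shape:
            raise ValueError("reads_3s and total must have the same shape")
        if np.any(self.reads_3s > self.total) or np.any(self.reads_3s < 0):
            raise ValueError("3S reads must lie in [0, total]")

    @property
    def fraction(self) -> np.ndarray:
        """Fraction of 3S reads; NaN where coverage is zero."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.total > 0, self.reads_3s / self.total, np.nan)

    @property
    def mean_coverage(self) -> np.ndarray:
        return self.total.mean(axis=1)


def simulate_allele_fractions(
    hap: HaploidPanel,
    mean_coverage: float = 10.0,
    error_rate: float = 0.002,
    seed: int = 0,
) -> AlleleFractionMatrix:
    """Simulate low-coverage sequencing pileups at every marker.

    Total counts are Poisson(mean_coverage); 3S reads are binomial with
    success probability 1 - error_rate where the true allele is 3S and
    error_rate where it is BY.
    """
    if mean_coverage <= 0:
        raise ValueError("mean_coverage must be positive")
    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    rng = substream(seed, "allele_fractions")
    shape = hap.genotypes.shape
    total = rng.poisson(mean_coverage, size=shape)
    p = np.where(hap.genotypes == 1, 1.0 - error_rate, error_rate)
    reads = rng.binomial(total, p)
    return AlleleFractionMatrix(reads, total)
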