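# Methods

This note documents the models behind `diplomap`, the defaults and why they
were chosen, the numerical decisions, and the limits of what the synthetic
data can show.

## The cross and its simulation

Two founder strains (BY and 3S) differ at biallelic SNP markers ordered on
16 chromosomes with physical (bp) and genetic (cM) coordinates. Haploid
segregants are meiotic products of the BY/3S diploid; mating every MATa
segregant to every MATalpha segregant gives the factorial diploid panel, in
which all diploids sharing a haploid parent form a family. Diploid genotypes
are coded as 3S dosage (0/1/2); a diploid's row is exactly the sum of its two
parents' rows.

**Meiosis.** Crossovers follow a Poisson process on the genetic map with no
interference (Haldane's model). We simulate marker phases directly as the
equivalent two-state Markov chain — the switch probability between markers
separated by d cM is `(1 - exp(-2d/100))/2`, the parity of a Poisson(d/100)
crossover count — which is identical in distribution to sampling breakpoints
and much faster. `crossover_rate` scales the map (0 disables recombination).
Tetrad structure and crossover interference are not modelled.

**Mating locus.** One ChrIII marker is designated the mating locus. A MATa
parent contributes its allele linked to the MATa cassette, a MATalpha parent
its allele linked to the MATalpha cassette, so four diploid classes segregate
(BY·a/BY·α, 3S·a/3S·α, BY·a/3S·α, 3S·a/BY·α) and the two heterozygous
classes are distinguishable by parent of origin.

**Trait model.** The genetic value is

    g = Σ a_j (x_j - 1) + Σ d_j h_j m_j + Σ [aa x1x2 + da h1x2 + ad x1h2 + dd h1h2]

with x the centered dosage, h the heterozygosity indicator, and m_j an
optional MAT-class-specific multiplier on the dominance of designated focal
loci (how a parent-of-origin dominance modifier is planted). Phenotype = g +
Gaussian noise; the study-level generator sets the noise SD from the realized
genetic variance to hit a target broad-sense heritability (default 0.6, the
middle of the range such pooled fitness assays report).

**Pooled competition.** Per cycle, lineage cell numbers evolve as
`n_i' = n_i * 2^dg * exp((s_i - sbar) dg)` with `dg = log2(1/dilution)`
generations per cycle (3 at the default 1:8 dilution) and sbar the
abundance-weighted mean fitness; the neutral `2^dg` factor keeps the census
stationary across the binomial bottleneck and does not change relative
dynamics. Reads per timepoint are multinomial at the configured depth.
Defaults: 4 cycles (5 timepoints, 12 generations), 2,000 cells per lineage at
seeding.

**Chimeras.** Template switching during PCR creates artifactual double
barcodes; chimeric reads for a pair are Poisson with expectation
`rate * reads(bc1) * reads(bc2) / total reads`, added on top of real pairs
and creating new impossible pairs. Because the factorial mating makes every
segregant-by-segregant barcode combination a real lineage, the impossible
pairs are exactly the parental-by-segregant combinations; the simulator emits
them even at zero reads so the downstream regression is not truncated to
positive counts. Four parental control diploids are spiked at 5% of starting
cells with 3 barcodes per parental strain per mating type — a deliberately
generous spike so that, at desk-scale depth, impossible pairs carry enough
chimeric reads for a usable regression (the real experiment achieves the
same with vastly deeper sequencing). Default chimera rate 0.11%, the
template-switching rate such assays estimate.

**Low-coverage genotyping reads.** Per segregant and marker, coverage is
Poisson (default mean 10x) and 3S reads are binomial with success
probability `1 - error_rate` on 3S backgrounds and `error_rate` on BY.

## Counting and chimera correction

The chimera model is ordinary least squares of an impossible pair's pooled
read count on the product of its two single barcodes' total counts (all
timepoints pooled), with intercept. Corrected counts subtract the model
expectation (clamped at zero), apportioned across timepoints proportionally
to the timepoint's share of the pair's abundance product — the paper-level
description fits pooled counts, and proportional allocation is the minimal
assumption that corrects trajectories. Corrected counts are floored at zero,
and lineages with mean corrected count below 5 across timepoints are flagged
invalid. Note that subtracting an expectation helps only when the chimeric
load per count cell is appreciable; at very low load the subtraction can
increase mean absolute error even though it is unbiased.

## Fitness estimation

Counts are modelled as Poisson with mean `depth(t) * f_i(t)` under
`f_i(t+1) = f_i(t) exp((s_i - sbar(t)) dg)`. Given the mean-fitness
trajectory, each lineage is a two-parameter Poisson regression (intercept and
slope on generations, with `log depth - cumulative mean fitness` as offset),
solved by damped Newton steps vectorized across lineages. The trajectory
update is `sbar(t) = Σ f_i(t) s_i` with observed frequencies; iteration stops
when the summed trajectory changes by less than 1e-6 (relative) or after 50
sweeps (warning).

Two deliberate choices:

- **Gauge.** The relative dynamics identify s only up to an additive
  constant, and the model omits the normalizer `log E_f[exp((s - sbar) dg)]`
  (Jensen term), so an unconstrained iteration drifts along that neutral
  direction. The gauge is fixed at `sbar(0) = 0` inside the loop and
  fitnesses are reported relative to the initial population mean. Relative
  fitnesses are unaffected (verified by the shift-invariance test).
- **Noise model.** A plain Poisson likelihood, not the more elaborate
  count-noise model of purpose-built lineage-tracking tools; adequate at the
  depths simulated here, and the parameter-recovery tests quantify it
  (r > 0.99, |bias| ~ 1e-3 at depth 1e6).

QC: lineages with log-likelihood score below `Q1 - 1.5 IQR` are dropped; for
diploids with ≥3 replicates, a replicate more than 0.5 fitness units from
the median of the others is dropped (our disambiguation of the pairwise-
difference rule); two replicates differing by more than 0.5 are both
dropped; singleton diploids are omitted. Replicate means are quantile
normalized to standard-normal scores at offset quantiles `(rank - 0.5)/n`
with average ranks for ties.

## Genotype calling

Initial calls threshold the 3S allele fraction at 0.5 (exactly 0.5 or no
coverage is missing). Smoothing uses a two-state HMM with per-step stay
probability 0.9999 (independent of marker distance, as specified) and
emission probability 0.75 of observing the true state, decoded by the most
probable path (Viterbi) — path decoding, rather than posterior marginals,
yields the block structure the collapsing step assumes. Missing observations
are skipped with the transition composed across the gap; unobserved markers
take the state of the nearest decoded neighbour (left on ties).

These matrices imply a switch costs about nine markers of consistent
evidence, so recovery above 99% requires the marker density of the real data
(~10 markers/cM); the tests and the acceptance script therefore run the
recovery check at that density. At sparse desk-scale maps the HMM is
intentionally conservative and will miss short recombination blocks.

Filters: markers within 30 kb of a chromosome's first/last marker are
dropped (never emptying a chromosome); segregants with mean coverage < 2 are
removed; cross-contamination is operationalized as >10% of covered markers
with allele fraction in [0.2, 0.8]; aneuploidy as a chromosome whose mean
coverage deviates from the genome mean by >35% with a normal test at
alpha = 1e-3. The paper-level description names no explicit statistics for
the last two; both thresholds are exposed as parameters. Collapsing merges
maximal runs of adjacent markers with identical genotype columns across all
segregants, keeps the leftmost as representative, and records the spanned
interval; it is idempotent and preserves every segregant's genotypes at
retained markers.

## Heritability

`broad_sense` is the replicate-concordance statistic: per random subsample
of genotypes (default 2,500, 1,000 repeats), `SS_between / SS_total` on
replicate-level fitnesses. This ratio is upward-biased as an estimator of
the variance ratio — with k replicates its expectation is approximately
`(1 + (k-1)H²)/k`, hence ~0.5 under the null with k = 2 — which is a
property of the estimator itself, documented and tested against the
closed-form expectation. `broad_sense_components` provides the classic
expected-mean-squares estimator `(MSB - MSW)/k0`, which is unbiased for the
underlying variance ratio and is used wherever the target is the true H².

The A/D/E decomposition builds A from column-centered dosage, D from the
centered heterozygosity indicator (both scaled to unit mean diagonal), and
E = A∘A (additive-by-additive kernel), then estimates components by
Haseman–Elston regression of off-diagonal phenotypic cross-products on the
kernel entries, averaged over subsamples. REML (the conventional tool for
this estimand) is replaced by method of moments: same estimand,
dependency-free, fast at desk scale. Degenerate kernels (no heterozygotes)
are dropped with a warning. Single-draw estimates fluctuate substantially
with the realized architecture relative to the family structure; recovery is
therefore assessed on averages over independent trait draws.

## Mapping

Family scans use the two-class structure within a MATa family: the locus
term's partial F test (1 df) given any detected covariate loci, computed in
closed form for all markers at once (identical to the equal-variance t test
when covariate-free). Forward regression adds, per chromosome and round, the
most significant marker above threshold until none passes; ties break on
lowest (chromosome, bp). Permutation thresholds shuffle phenotypes within
each of 10 randomly chosen families, record the genome-wide minimum p per
permutation, and take the 5th percentile (linear interpolation between order
statistics). Confidence intervals are 3-LOD drops: contiguous markers within
3 units of the peak's -log10 p. Detections are consolidated across families
by single-linkage interval overlap; enrichment tiles each chromosome from
bp 1 in 20 kb bins (final short bin kept), bins detections by peak position,
and calls bins exceeding the smallest k with Poisson upper tail ≤
0.05/#bins at lambda = detections/#bins.

Midparent residuals: each haploid parent's fitness is its offspring mean
(parents under 20 phenotyped offspring exclude their diploids), the midparent
is the parental average, and residuals come from the linear regression of
phenotype on midparent. This removes additive structure exactly in
expectation, but estimating parent means from finite families leaves a small
correlated component in the residuals; at desk scale the dominance-scan
null is therefore checked as a rate over many simulations rather than a
single draw.

Dominance scans test the 3-level categorical locus term (2 df, equal to
one-way ANOVA when covariate-free) on residuals, with global-shuffle
permutation thresholds and the same forward-regression loop; markers need
all three classes at a minimum size (default 50). Degrees of dominance use
`a = (mean_3S/3S - mean_BY/BY)/2`, `d = mean_het - homozygote midpoint`,
degree `d/|a|`, with bands: |degree| < 0.9 incomplete, 0.9–1.1 complete,
>1.1 overdominant, <-1.1 underdominant; a = 0 is flagged with the class
taken from the sign of d.

Pairwise scans treat all 9 joint classes as categories; the interaction p is
the sequential F test (saturated cell-mean model against the main-effects
model), computed for all marker pairs from per-cell counts and sums obtained
by nine matrix products. Pairs need all cells at a minimum size (default 20;
emptier fits are reduced-rank and flagged). Permutations shuffle residuals
and draw 10,000 random pairs each (all pairs when fewer are eligible); cell
counts are reused across permutations. Significant pairs whose sides fall in
each other's 3-LOD windows (profiles taken from the pair p-value matrix with
the partner fixed) consolidate to the most significant representative. Hubs
are loci with more than 20 consolidated interactions; the hub forward scan
retests `residuals ~ hub + locus2 + covariates + hub:locus2` with
accumulated partner and hub:partner covariates (residualized once per round
for speed), and comprehensive-scan pairs within 50 kb of a hub are removed
to avoid double counting. Note that with strongly linked markers the forward
scan can report linked shadows of true partners as additional interactions;
counts should be read as upper bounds on distinct partners at desk-scale
marker spacing.

Three-locus scans run on a 5 cM greedily thinned marker set with the full
categorical model (all mains and pairwise terms included); the three-way
term's sequential F test comes from 27-cell statistics with batched
weighted fits. Hub resolution takes the most significant family-level marker
whose interval overlaps the hub, then the tightest interval endpoints among
family intervals covering that peak.

## Epistasis partition

For a pair (locus1, locus2): main effects enter as categorical terms, then
the four products of the additive code (`dosage - 1`, numeric) and dominance
code (heterozygosity, categorical) in the fixed order a1:a2, d1:a2, a1:d2,
d1:d2, with sequential sums of squares over the total SS as PVE. The main
effects span all one-locus functions and the four products span the
remaining 4-df interaction space, so the four PVEs sum exactly to the
saturated interaction PVE; on balanced designs the decomposition is
order-invariant, and imbalance sensitivity is inherited from sequential SS
(documented, tested on balanced oracles). The dominance fraction of locus1's
modifying effect is `(d1:a2 + d1:d2)/(a1:a2 + d1:a2 + a1:d2 + d1:d2)`, and
symmetrically for locus2; with the hub as locus1, `add_mod = PVE(a1:a2) +
PVE(a1:d2)` and `dom_mod = PVE(d1:a2) + PVE(d1:d2)`, with major modifiers
above `Q3 + 1.5 IQR` per channel (no calls under five partners).

Background profiles subset diploids into the 81 genotype classes of four
modifiers and report the hub's per-class additive effect as the undivided
homozygote difference (the per-class convention) — note this intentionally
differs by a factor of two from the degree-of-dominance additive effect,
which halves the difference; both conventions are implemented where each is
used. Class CIs are percentile bootstraps over diploids within the class
(default 1,000 resamples); classes under 20 diploids, or missing a hub
genotype, are reported missing rather than zero. The mating-locus
parent-of-origin split computes the focal locus's dominance separately in
each of the four MAT classes.

## Problem sizes and defaults

Desk-scale defaults throughout: 16 chromosomes, 750 cM, 1,000 markers
(simulator default; most analyses in the tests and the acceptance script use
120 markers), 50 MATa x 60 MATalpha parents with two barcodes each, depth
2e6 per timepoint, 4 cycles at 1:8 dilution. The acceptance script runs
3,900-diploid panels for scans, a 15,600-diploid panel for variance
decomposition, 500 null simulations for threshold calibration, and a
1,500-marker, 4-chromosome map for genotype recovery. These sizes were
chosen so each estimator operates in a regime where its statistical
properties are measurable; they are configurable upward.

## Limitations

- The synthetic readout has no UMIs, read errors, or barcode clustering —
  the pipeline starts at count tables keyed by known barcodes.
- Mixed-model genome-wide mapping is out of scope; family-level scans plus
  enrichment are the supported detection route.
- Poisson read noise understates real overdispersion; fitness-recovery
  numbers on synthetic data are an upper bound on real-data accuracy.
- Passing tests on simulated data show the estimators recover the generative
  model's parameters; they cannot certify behavior under real-data artifacts
  the generator does not emulate (batch effects, barcode hopping,
  growth-phase dependence of fitness).
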