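# diplomap

Statistical genetics of fitness in a barcoded diploid yeast cross.

Large diploid mapping panels can be built by mating haploid segregants of a
two-parent cross (here labelled BY and 3S) in a full factorial design, fusing
one genomic barcode from each parent into a double barcode that uniquely
identifies every diploid lineage. Sequencing the double-barcode locus over a
pooled serial-batch competition yields frequency trajectories, and hence a
fitness phenotype, for hundreds of thousands of diploids at once. Because
every diploid shares a haploid parent with many others, the panel decomposes
into interrelated families, which makes additive, dominance, and epistatic
effects separable.

`diplomap` implements that analysis end to end, plus a synthetic-data
generator that simulates the cross, trait architecture, and sequencing
readout so every stage can be validated against ground truth:

- **Counting** — correction of PCR chimeras, whose expected count for a
  barcode pair is `intercept + slope * (reads of bc1 x reads of bc2)`, fitted
  on known-impossible (parental x segregant) pairs; a mean-count filter.
- **Fitness** — per-lineage fitness from a Poisson model of read counts under
  `f_i(t+1) = f_i(t) exp((s_i - sbar(t)) dg)`, iterated with the
  mean-fitness trajectory; likelihood-score and replicate-concordance QC;
  per-diploid averaging and rank-based quantile normalization.
- **Genotypes** — haploid calls from low-coverage allele fractions, smoothed
  by a two-state HMM (stay probability 0.9999, emission 0.75), 30 kb end
  trimming, contamination/aneuploidy filters, and collapsing of
  non-recombinant adjacent markers.
- **Heritability** — broad-sense H² from replicate concordance (sum-of-squares
  ratio, plus an expected-mean-squares variance-component estimator) and an
  additive/dominance/epistatic decomposition via genomic relationship
  matrices (A, D, E = A∘A) and Haseman–Elston regression.
- **Mapping** — fixed-effect scans within MATa families with forward
  regression, permutation thresholds (5th percentile of genome-wide minimum
  p), 3-LOD-drop intervals, cross-family consolidation, and a Poisson
  enrichment test in 20 kb bins.
- **Non-additive genetics** — midparent residuals to remove additive family
  structure; dominance scans (3-level categorical model) with degree-of-
  dominance classification (`d/|a|`; incomplete, complete, over/under);
  comprehensive 9-class pairwise and 27-class three-locus interaction scans;
  hub detection (>20 interactions) with forward regression over partners.
- **Epistasis partition** — each pairwise interaction split into
  `a1:a2 + d1:a2 + a1:d2 + d1:d2` (dosage numeric, heterozygosity
  categorical); the fraction of epistasis acting through dominance,
  `(d1:a2 + d1:d2) / (sum of all four)`; `add_mod`/`dom_mod` modifier
  magnitudes of hubs with 1.5-IQR outlier calls; hub effect-size profiles
  across the 81 genotype classes of four modifiers with bootstrap CIs; and
  the parent-of-origin split of dominance at the mating locus.

## Worked example

```python
import numpy as np, pandas as pd
import diplomap as dm

cfg = dm.StudyConfig(n_markers=120, n_mata=20, n_matalpha=24, n_qtl=4,
                     depth=1e6, chimera_rate=1.1e-3)
study = dm.simulate_study(cfg, seed=7)

model = dm.fit_chimera_model(study.counts)
corrected = dm.correct_counts(study.counts, model)
fit = dm.aggregate_and_normalize(dm.filter_replicates(dm.estimate_fitness(corrected)))

y = np.full(study.panel.n_diploids, np.nan)
y[fit.phenotypes["diploid"]] = fit.phenotypes["qnorm_s"]
thr = dm.permutation_threshold(y, study.panel, n_perm=500, n_families=10, seed=1)
dets = [dm.family_scan(y, study.panel, f, threshold=thr).detections.assign(family=f)
        for f in np.unique(study.panel.mata_parent)]
loci = dm.consolidate_across_families(pd.concat(dets, ignore_index=True))
```

Printed with the summaries in between (480 diploids, 20 x 24 parents):

```
480 diploids, 2484 double-barcode rows, 5 timepoints
chimera rate: 0.087% (injected 0.110%)
480 diploids phenotyped; r(estimated, true fitness) = 0.994
permutation threshold 6.47e-05; 1 distinct loci from 2 family detections
 chrom  start    end  peak_bp  n_families
    12 400700 782253   568019           2
```

The estimated chimera rate sits near the injected 0.11%, the lineage fitness
estimates track the planted truth at r = 0.994, and the one distinct locus
peaks at chrom 12, bp 568019 — exactly the position of the largest planted
QTL (a = 0.036); the smaller planted effects are below the power of this
tiny panel.

A CLI mirrors the pipeline for shell use: `diplomap simulate`,
`correct-counts`, `estimate-fitness`, `call-genotypes`, `heritability`,
`scan-families`, `scan-dominance`, `scan-pairs`, `scan-trios`,
`partition-epistasis`.

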