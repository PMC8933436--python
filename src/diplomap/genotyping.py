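"""Haploid genotype calling from low-coverage allele fractions.

A segregant genome is a mosaic of large parental blocks, so raw per-marker
calls from ~10x coverage can be cleaned up with a two-state hidden Markov
model along each chromosome.  The chain uses a per-step stay probability of
0.9999 between adjacent markers (independent of distance) and an emission
probability of 0.75 that an observed call matches the true state, and is
decoded by the most probable state path (Viterbi).  Missing observations
are skipped, with the transition composed across the gap.

After smoothing, chromosome ends are trimmed (default 30 kb), segregants
with low mean coverage, contamination, or aneuploidy signatures are
removed, and runs of adjacent markers that never recombine in the panel
are collapsed to a single representative marker.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markers import MarkerMap
from .simulate import AlleleFractionMatrix

__all__ = [
    "initial_calls",
    "hmm_smooth",
    "viterbi_path",
    "filter_segregants",
    "SegregantFilterResult",
    "collapse_markers",
]

BY, S3, MISSING = 0, 1, -1

STAY_PROB = 0.9999
EMIT_CORRECT = 0.75


def initial_calls(afm: AlleleFractionMatrix) -> np.ndarray:
    """Threshold allele fractions into calls: >0.5 is 3S, <0.5 is BY.

    Markers at exactly 0.5 or with zero coverage are missing (-1).
    """
    frac = afm.fraction
    calls = np.full(frac.shape, MISSING, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        calls[frac > 0.5] = S3
        calls[frac < 0.5] = BY
    return calls


def _switch_prob(gap: np.ndarray) -> np.ndarray:
    """Probability of being in the other state after ``gap`` steps.

    Composition of the symmetric two-state transition matrix with per-step
    switch probability 1 - STAY_PROB.
    """
    eps = 1.0 - STAY_PROB
    return 0.5 * (1.0 - (1.0 - 2.0 * eps) ** gap)


def viterbi_path(obs: np.ndarray, steps: np.ndarray | None = None) -> np.ndarray:
    """Most probable two-state path for one chromosome of one segregant.

    ``obs`` holds calls in {0, 1} at the observed markers (missing markers
    already removed); ``steps`` gives the number of map steps between
    consecutive observations (default 1).  Uniform initial distribution.
    """
    obs = np.asarray(obs)
    n = obs.size
    if n == 0:
        return obs.astype(np.int8)
    if steps is None:
        steps = np.ones(n - 1, dtype=np.int64)
    log_emit = np.log(np.array([[EMIT_CORRECT, 1 - EMIT_CORRECT],
                                [1 - EMIT_CORRECT, EMIT_CORRECT]]))
    # score[s] = best log prob of a path ending in state s
    score = np.log(0.5) + log_emit[:, obs[0]]
    back = np.zeros((n, 2), dtype=np.int8)
    for t in range(1, n):
        ps = _switch_prob(steps[t - 1])
        log_t = np.log(np.array([[1 - ps, ps], [ps, 1 - ps]]))
        cand = score[:, None] + log_t  # cand[prev, cur]
        back[t] = np.argmax(cand, axis=0)
        score = cand[back[t], [0, 1]] + log_emit[:, obs[t]]
    path = np.empty(n, dtype=np.int8)
    path[-1] = int(np.argmax(score))
    for t in range(n - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def hmm_smooth(calls: np.ndarray, mmap: MarkerMap) -> np.ndarray:
    """Smooth initial calls with the two-state HMM, per chromosome.

    Missing observations are skipped and the transition is composed across
    the gap; markers with no observation on a chromosome inherit the state
    of the nearest decoded marker (left neighbour on ties).  Chromosomes
    with no observed markers for a segregant are left missing.
    """
    calls = np.asarray(calls, dtype=np.int8)
    out = np.full(calls.shape, MISSING, dtype=np.int8)
    for c in mmap.chromosomes:
        idx = mmap.chrom_indices(c)
        if idx.size == 0:
            continue
        sub = calls[:, idx]
        for i in range(calls.shape[0]):
            observed = np.flatnonzero(sub[i] != MISSING)
            if observed.size == 0:
                continue
            steps = np.diff(observed)
            path = viterbi_path(sub[i, observed], steps)
            row = np.full(idx.size, MISSING, dtype=np.int8)
            row[observed] = path
            # fill unobserved markers from the nearest decoded neighbour
            missing = np.flatnonzero(row == MISSING)
            if missing.size:
                left = np.searchsorted(observed, missing) - 1
                right = np.clip(left + 1, 0, observed.size - 1)
                left = np.clip(left, 0, observed.size - 1)
                dl = np.abs(missing - observed[left])
                dr = np.abs(observed[right] - missing)
                nearest = np.where(dl <= dr, observed[left], observed[right])
                row[missing] = row[nearest]
            out[i, idx] = row
    return out


@dataclass
class SegregantFilterResult:
    """Outcome of segregant- and marker-level quality filtering."""

    kept_segregants: np.ndarray  # bool mask over segregants
    kept_markers: np.ndarray  # bool mask over markers (end trimming)
    low_coverage: np.ndarray
    contaminated: np.ndarray
    aneuploid: np.ndarray

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "kept": self.kept_segregants,
                "low_coverage": self.low_coverage,
                "contaminated": self.contaminated,
                "aneuploid": self.aneuploid,
            }
        )


def filter_segregants(
    afm: AlleleFractionMatrix,
    mmap: MarkerMap,
    end_trim_bp: int = 30_000,
    min_mean_coverage: float = 2.0,
    intermediate_band: tuple = (0.2, 0.8),
    max_intermediate_frac: float = 0.10,
    aneuploidy_rel_dev: float = 0.35,
    aneuploidy_alpha: float = 1e-3,
) -> SegregantFilterResult:
    """Apply the marker end-trimming and segregant quality filters.

    Markers within ``end_trim_bp`` of either chromosome end are dropped.
    Segregants are removed when mean coverage is below
    ``min_mean_coverage``; flagged as cross-contaminated when more than
    ``max_intermediate_frac`` of covered markers have an allele fraction in
    ``intermediate_band`` (a haploid should sit near 0 or 1); and flagged
    as aneuploid when any chromosome's mean coverage deviates from the
    genome-wide mean by more than ``aneuploidy_rel_dev`` (relative) and the
    deviation is significant under a normal test at ``aneuploidy_alpha``.
    """
    from scipy import stats

    kept_markers = np.ones(mmap.n_markers, dtype=bool)
    for c in mmap.chromosomes:
        idx = mmap.chrom_indices(c)
        lo, hi = mmap.bp[idx].min(), mmap.bp[idx].max()
        near_end = (mmap.bp[idx] < lo + end_trim_bp) | (mmap.bp[idx] > hi - end_trim_bp)
        kept_markers[idx[near_end]] = False
    # never trim a whole chromosome away
    for c in mmap.chromosomes:
        idx = mmap.chrom_indices(c)
        if not kept_markers[idx].any():
            kept_markers[idx] = True

    cov = afm.total.astype(float)
    mean_cov = cov.mean(axis=1)
    low_coverage = mean_cov < min_mean_coverage

    frac = afm.fraction
    covered = afm.total > 0
    lo, hi = intermediate_band
    with np.errstate(invalid="ignore"):
        inter = (frac >= lo) & (frac <= hi) & covered
    n_cov = np.maximum(covered.sum(axis=1), 1)
    contaminated = inter.sum(axis=1) / n_cov > max_intermediate_frac

    aneuploid = np.zeros(cov.shape[0], dtype=bool)
    z_crit = stats.norm.isf(aneuploidy_alpha / 2.0)
    genome_mean = cov.mean(axis=1)
    for c in mmap.chromosomes:
        idx = mmap.chrom_indices(c)
        chrom_mean = cov[:, idx].mean(axis=1)
        rel = np.abs(chrom_mean - genome_mean) / np.maximum(genome_mean, 1e-12)
        # Poisson-based normal approximation for the chromosome mean
        se = np.sqrt(np.maximum(genome_mean, 1e-12) / idx.size)
        z = np.abs(chrom_mean - genome_mean) / se
        aneuploid |= (rel > aneuploidy_rel_dev) & (z > z_crit)

    kept = ~(low_coverage | contaminated | aneuploid)
    return SegregantFilterResult(kept, kept_markers, low_coverage, contaminated, aneuploid)


def collapse_markers(smoothed: np.ndarray, mmap: MarkerMap):
    """Collapse adjacent markers that never recombine in the panel.

    Maximal runs of adjacent markers (within a chromosome) whose genotype
    columns are identical across all segregants become a single marker; the
    leftmost marker represents the run and the spanned bp interval is
    recorded.  Returns ``(reduced_genotypes, reduced_map, groups)`` where
    ``groups`` is a DataFrame with the representative and the run interval.
    """
    smoothed = np.asarray(smoothed)
    if np.any(smoothed == MISSING):
        raise ValueError("collapse_markers requires complete (smoothed) calls")
    keep = []
    rep_start, rep_end = [], []
    for c in mmap.chromosomes:
        idx = mmap.chrom_indices(c)
        cols = smoothed[:, idx]
        new_run = np.ones(idx.size, dtype=bool)
        if idx.size > 1:
            new_run[1:] = np.any(cols[:, 1:] != cols[:, :-1], axis=0)
        run_id = np.cumsum(new_run) - 1
        for r in range(run_id.max() + 1):
            members = idx[run_id == r]
            keep.append(members[0])
            rep_start.append(mmap.bp[members[0]])
            rep_end.append(mmap.bp[members[-1]])
    keep = np.array(keep)
    groups = pd.DataFrame(
        {
            "marker": mmap.ids[keep],
            "chrom": mmap.chrom[keep],
            "start_bp": rep_start,
            "end_bp": rep_end,
        }
    )
    return smoothed[:, keep], mmap.subset(keep), groups
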