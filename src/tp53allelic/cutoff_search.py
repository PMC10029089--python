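"""Survival-guided search for the VAF cutoff separating probable
monoallelic from probable biallelic TP53 mutations.

The procedure treats survival as a surrogate for the unobservable allelic
state: among mutated patients without obligatory biallelic evidence, the
cutoff is placed where splitting on combined VAF best separates survival.
It is the identifiable core of a single-covariate survival tree — the
root-node log-rank split under a minimum-node-size constraint — wrapped in
two robustness layers:

* ``subsampled_splits`` repeats the split on bootstrap resamples and
  reports how often each candidate wins (split stability);
* ``crossval_cutoff`` scores each candidate cutoff by the test-set
  Harrell concordance of the resulting four-level ordinal risk score
  (WT = 0, probable monoallelic = 1, probable biallelic = 2, obligatory
  biallelic = 3) over repeated 80/20 train/test splits and selects the
  candidate with the best mean test concordance.

Ties are always broken toward the smaller cutoff, which labels more
patients probable biallelic — the conservative direction for a lesion
whose presence, not absence, carries the hazard.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .classifier import ORDINAL_RISK, classify_allelic
from .core_io import AllelicLabel, PatientRecord, RunConfig
from .survival_stats import harrell_c, logrank_2sample_stat

__all__ = [
    "CutoffSearchResult",
    "SubsampleResult",
    "candidate_grid",
    "fixed_grid",
    "best_split",
    "subsampled_splits",
    "crossval_cutoff",
    "cohort_risk_features",
]


@dataclass(frozen=True)
class SubsampleResult:
    """Bootstrap split-stability profile.

    ``frequencies[i]`` counts resamples whose best split fell on
    ``candidates[i]`` (candidates are the splits actually chosen, sorted
    increasing); ``n_no_split`` counts resamples whose candidate grid was
    empty under the node-size constraint.
    """

    candidates: np.ndarray
    frequencies: np.ndarray
    n_runs: int
    n_no_split: int


@dataclass(frozen=True)
class CutoffSearchResult:
    """Outcome of the cross-validated cutoff search."""

    candidate_cutoffs: np.ndarray
    cv_mean: np.ndarray
    cv_sd: np.ndarray
    n_scored_runs: np.ndarray
    selected_cutoff: float
    runs: int
    seed: int
    split_frequencies: Optional[SubsampleResult] = None

    def to_dict(self) -> dict:
        out = {
            "candidate_cutoffs": [float(c) for c in self.candidate_cutoffs],
            "cv_mean": [float(v) for v in self.cv_mean],
            "cv_sd": [float(v) for v in self.cv_sd],
            "n_scored_runs": [int(v) for v in self.n_scored_runs],
            "selected_cutoff": float(self.selected_cutoff),
            "runs": int(self.runs),
            "seed": int(self.seed),
        }
        if self.split_frequencies is not None:
            sf = self.split_frequencies
            out["split_frequencies"] = {
                "candidates": [float(c) for c in sf.candidates],
                "frequencies": [int(f) for f in sf.frequencies],
                "n_runs": int(sf.n_runs),
                "n_no_split": int(sf.n_no_split),
            }
        return out


def candidate_grid(vafs, min_node: int) -> np.ndarray:
    """Data-driven candidate cutpoints under the node-size constraint.

    Candidates are midpoints between consecutive distinct sorted VAFs,
    keeping only cutpoints that leave at least ``min_node`` patients on
    each side of the split {VAF <= c} / {VAF > c}.  Returns an empty array
    when no cutpoint is feasible (in particular whenever n < 2*min_node).
    """
    v = np.sort(np.asarray(vafs, dtype=float))
    if v.size < 2 * min_node:
        return np.empty(0)
    distinct = np.unique(v)
    if distinct.size < 2:
        return np.empty(0)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    keep = [
        c for c in mids if min_node <= (v <= c).sum() and (v > c).sum() >= min_node
    ]
    return np.asarray(keep)


def fixed_grid(lo: float = 0.01, hi: float = 0.49, step: float = 0.01) -> np.ndarray:
    """Evenly spaced cutoff grid (default 1%..49% in 1% steps).

    Used for profiling survival separation across cutoffs; the data-driven
    :func:`candidate_grid` is the default for the split search itself.
    """
    n = int(round((hi - lo) / step)) + 1
    return lo + step * np.arange(n)


def best_split(vafs, times, events, min_node: int) -> float:
    """Cutpoint maximising the two-sample log-rank statistic.

    The split compares {VAF <= c} against {VAF > c} over the candidate
    grid; exact statistic ties break toward the smallest cutoff.  Raises
    when the grid is empty.
    """
    grid = candidate_grid(vafs, min_node)
    if grid.size == 0:
        raise ValueError("no feasible split: candidate grid is empty")
    v = np.asarray(vafs, dtype=float)
    stats_ = np.array(
        [logrank_2sample_stat(times, events, v > c) for c in grid]
    )
    return float(grid[int(np.argmax(stats_))])  # argmax takes first = smallest


def subsampled_splits(vafs, times, events, config: RunConfig) -> SubsampleResult:
    """Bootstrap the split choice: size-n resamples with replacement.

    Mirrors the resampling a survival forest would apply around its root
    split.  Resamples whose grid is infeasible are counted as "no split"
    and excluded from the frequency table.  Fully determined by
    ``config.seed``.
    """
    v = np.asarray(vafs, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    n = v.size
    rng = np.random.default_rng(config.seed)
    chosen: list[float] = []
    n_no_split = 0
    for _ in range(config.subsamples):
        idx = rng.integers(0, n, size=n)
        try:
            chosen.append(best_split(v[idx], t[idx], e[idx], config.min_node))
        except ValueError:
            n_no_split += 1
    cands, freqs = np.unique(np.asarray(chosen), return_counts=True)
    return SubsampleResult(
        candidates=cands,
        frequencies=freqs,
        n_runs=config.subsamples,
        n_no_split=n_no_split,
    )


def cohort_risk_features(
    cohort: Sequence[PatientRecord], config: RunConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Cutoff-independent per-patient features for fast candidate scoring.

    Returns (times, events, combined_vaf, obligatory_mask, baseline_mask)
    where ``baseline_mask`` marks patients whose risk score is 0 at every
    cutoff (WT and deletion-only).  Obligatory-biallelic status and the
    baseline classes do not depend on the cutoff, so the ordinal score at
    cutoff c reduces to a vectorised comparison of combined VAF with c for
    the remaining patients — equivalent to calling ``classify_allelic``
    per patient at every candidate, but usable inside the CV loop.
    """
    calls = [classify_allelic(p, config) for p in cohort]
    times = np.array([p.os_months for p in cohort], dtype=float)
    events = np.array([p.os_event for p in cohort], dtype=bool)
    cvaf = np.array([c.combined_vaf for c in calls], dtype=float)
    obligatory = np.array(
        [c.label is AllelicLabel.obligatory_biallelic for c in calls], dtype=bool
    )
    baseline = np.array(
        [c.label in (AllelicLabel.WT, AllelicLabel.del17p_only) for c in calls],
        dtype=bool,
    )
    return times, events, cvaf, obligatory, baseline


def _scores_at_cutoff(
    cvaf: np.ndarray, obligatory: np.ndarray, baseline: np.ndarray, cutoff: float
) -> np.ndarray:
    scores = np.where(cvaf > cutoff, 2, 1)
    scores[obligatory] = 3
    scores[baseline] = 0
    return scores


def crossval_cutoff(
    cohort: Sequence[PatientRecord],
    candidate_cutoffs,
    config: RunConfig,
    split_frequencies: Optional[SubsampleResult] = None,
) -> CutoffSearchResult:
    """Select the cutoff by cross-validated test-set concordance.

    For each of ``config.cv_runs`` random train/test partitions (test share
    ``config.test_fraction``) and each candidate cutoff c, patients are
    classified under c, the ordinal risk score is evaluated on the held-out
    test fold, and Harrell's C is computed there.  The per-candidate mean
    test C over runs is the selection criterion; ties go to the smaller
    cutoff.  Test folds with no comparable pairs are skipped for that
    candidate and counted in ``n_scored_runs``.

    The train fold carries no fitted parameters beyond the candidate under
    evaluation; it is held out so that the concordance is measured on data
    disjoint from any subsequent refit, mirroring how an out-of-sample
    profile is read.
    """
    cands = np.sort(np.asarray(candidate_cutoffs, dtype=float))
    if cands.size == 0:
        raise ValueError("candidate cutoff list is empty")
    n = len(cohort)
    n_test = max(2, int(round(config.test_fraction * n)))
    if n_test >= n:
        raise ValueError("test fold would swallow the whole cohort")

    # classification features do not depend on the cutoff except through
    # the probable mono/biallelic comparison, precomputed once
    times, events, cvaf, obligatory, baseline = cohort_risk_features(cohort, config)

    rng = np.random.default_rng(config.seed)
    c_sum = np.zeros(cands.size)
    c_sumsq = np.zeros(cands.size)
    c_count = np.zeros(cands.size, dtype=int)
    for _ in range(config.cv_runs):
        perm = rng.permutation(n)
        test = perm[:n_test]
        tt, te = times[test], events[test]
        for i, c in enumerate(cands):
            scores = _scores_at_cutoff(cvaf[test], obligatory[test], baseline[test], c)
            try:
                ci = harrell_c(tt, te, scores)
            except ValueError:
                continue  # no comparable pairs in this fold
            c_sum[i] += ci
            c_sumsq[i] += ci * ci
            c_count[i] += 1

    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(c_count > 0, c_sum / np.maximum(c_count, 1), np.nan)
        var = np.where(
            c_count > 1,
            (c_sumsq - c_sum**2 / np.maximum(c_count, 1)) / np.maximum(c_count - 1, 1),
            0.0,
        )
    sd = np.sqrt(np.clip(var, 0.0, None))
    if np.all(np.isnan(mean)):
        raise ValueError("no candidate could be scored on any test fold")
    best = int(np.nanargmax(mean))  # first occurrence = smallest cutoff on ties
    return CutoffSearchResult(
        candidate_cutoffs=cands,
        cv_mean=mean,
        cv_sd=sd,
        n_scored_runs=c_count,
        selected_cutoff=float(cands[best]),
        runs=config.cv_runs,
        seed=config.seed,
        split_frequencies=split_frequencies,
    )
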