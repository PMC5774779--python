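"""Repeated random split-half reliability with Spearman–Brown correction.

The estimator is generic over the score: the caller supplies, per
participant, the set of trials relevant to the score (e.g. only cross-race
pairs for a race preference score) and a ``scorer`` that maps any subset of
those trials to a scalar. On each run every participant's trials are split
into two random halves (sizes differing by at most one), the scorer is
applied per half, and the half-scores are correlated (Pearson) across
participants. Runs whose correlation is undefined — fewer than three
participants with both half-scores, or zero variance in a half — are dropped
and counted. The mean of the remaining correlations is Spearman–Brown
corrected once, projecting the half-length reliability to full length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from .errors import DegenerateDataError, InvalidInputError

__all__ = ["ReliabilityEstimate", "spearman_brown", "split_half_reliability"]


@dataclass(frozen=True)
class ReliabilityEstimate:
    mean_half_correlation: float
    corrected: float
    n_runs_used: int
    n_runs_dropped: int
    rng_seed: int


def spearman_brown(r: float) -> float:
    """Spearman–Brown step-up: 2r / (1 + r), the reliability of a test twice
    as long as one with reliability ``r``. Defined for r > −1."""
    if r <= -1.0:
        raise InvalidInputError(f"Spearman-Brown undefined for r <= -1 (got {r})")
    return 2.0 * r / (1.0 + r)


def split_half_reliability(
    per_participant_trials: Mapping[str, Sequence],
    scorer: Callable[[Sequence], float],
    runs: int = 10_000,
    rng_seed: int = 0,
) -> ReliabilityEstimate:
    """Monte-Carlo split-half reliability of ``scorer`` across participants.

    Parameters
    ----------
    per_participant_trials
        Participant id → the trials relevant to the score. Numpy arrays work
        and are fastest; any indexable sequence is accepted.
    scorer
        Maps a trial subset to a scalar score (nan = unscoreable half).
    runs
        Number of random half-partitions (the reference analysis used 10,000).
    rng_seed
        Seed controlling every partition; the estimate is reproducible.
    """
    if runs < 1:
        raise InvalidInputError("runs must be >= 1")
    pids = [p for p, ts in per_participant_trials.items() if len(ts) >= 2]
    if len(pids) < 3:
        raise InvalidInputError("need >= 3 participants with >= 2 trials each")

    arrays = {p: np.asarray(per_participant_trials[p]) for p in pids}
    rng = np.random.default_rng(rng_seed)
    correlations = []
    dropped = 0
    for _ in range(runs):
        a_scores = np.empty(len(pids))
        b_scores = np.empty(len(pids))
        for i, pid in enumerate(pids):
            arr = arrays[pid]
            perm = rng.permutation(len(arr))
            half = len(arr) // 2  # odd counts: halves differ by one
            a_scores[i] = scorer(arr[perm[:half]])
            b_scores[i] = scorer(arr[perm[half:]])
        ok = np.isfinite(a_scores) & np.isfinite(b_scores)
        if ok.sum() < 3:
            dropped += 1
            continue
        a, b = a_scores[ok], b_scores[ok]
        if a.std() == 0.0 or b.std() == 0.0:
            dropped += 1
            continue
        r = float(np.corrcoef(a, b)[0, 1])
        if not math.isfinite(r):
            dropped += 1
            continue
        correlations.append(r)

    if not correlations:
        raise DegenerateDataError(
            "degenerate data: every split-half run had an undefined correlation"
        )
    mean_r = float(np.mean(correlations))
    return ReliabilityEstimate(
        mean_half_correlation=mean_r,
        corrected=spearman_brown(mean_r),
        n_runs_used=len(correlations),
        n_runs_dropped=dropped,
        rng_seed=rng_seed,
    )
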