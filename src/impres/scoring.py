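"""Preference-score formulas and the participant × stimulus preference-count matrix.

All scores index the preference for one level of a binary stimulus feature
(the *focal level*) over the other:

* IMPRES / EXPRES: the proportion of cross-category trials on which the
  chosen side's prime carried the focal level (0.5 = indifference).
* AMP: P("more pleasant" | focal-level prime) − P("more pleasant" | other
  level), in [−1, 1].
* Ratings: mean rating of focal-level stimuli minus mean rating of the
  other level.

A participant with no usable trials for a score gets ``value = nan`` (flagged
missing, never imputed). Latency filtering is a separate, explicit step:
the reference analysis applies the 150–1500 ms window to the AMP only, so no
score function filters implicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .trials import (
    AmpTrial,
    ImpresTrial,
    PrimeStimulus,
    QuestionnaireResponse,
    RatingRecord,
)

__all__ = [
    "PreferenceScore",
    "PreferenceMatrix",
    "filter_latency",
    "amp_score",
    "impres_preference_score",
    "expres_preference_score",
    "rating_difference_score",
    "questionnaire_sum_score",
    "preference_count_matrix",
    "feature_levels",
    "scores_to_frame",
]


@dataclass(frozen=True)
class PreferenceScore:
    participant_id: str
    feature: str
    focal_level: str
    value: float  # nan when missing
    n_trials_used: int

    @property
    def missing(self) -> bool:
        return math.isnan(self.value)


@dataclass(frozen=True)
class PreferenceMatrix:
    """Counts of how often each stimulus's side was chosen, per participant.

    ``appearances_per_stimulus`` (K) is the maximum number of trials any
    stimulus appeared in for any participant; in a complete all-pairs design
    with n stimuli, K = n − 1.
    """

    participant_ids: tuple
    stimulus_ids: tuple
    counts: np.ndarray  # participants x stimuli, nonnegative ints
    appearances_per_stimulus: int

    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.participant_ids), columns=list(self.stimulus_ids)
        )


def _level_map(stimuli: Sequence[PrimeStimulus], feature: str) -> dict[str, str]:
    levels: dict[str, str] = {}
    for s in stimuli:
        if feature not in s.categorical_features:
            raise InvalidInputError(
                f"stimulus {s.stimulus_id} lacks feature {feature!r}"
            )
        levels[s.stimulus_id] = s.categorical_features[feature]
    return levels


def feature_levels(stimuli: Sequence[PrimeStimulus], feature: str) -> tuple[str, str]:
    """The two levels of a binary feature, sorted for determinism."""
    distinct = sorted(set(_level_map(stimuli, feature).values()))
    if len(distinct) != 2:
        raise InvalidInputError(
            f"feature {feature!r} has {len(distinct)} level(s); exactly 2 required"
        )
    return distinct[0], distinct[1]


def _has_response(trial) -> bool:
    if isinstance(trial, AmpTrial):
        return trial.response != "none"
    return trial.response_side != "none"


def filter_latency(
    trials: Sequence, lo_ms: float = 150.0, hi_ms: float = 1500.0
) -> tuple[list, float]:
    """Drop trials with no response or a latency outside [lo_ms, hi_ms].

    The bounds are inclusive (a 150-ms or 1500-ms latency is kept; the window
    excludes latencies strictly *below* 150 ms or *above* 1500 ms). Returns
    the kept trials and the excluded fraction. Trials with a recorded
    response but no latency are dropped (their speed cannot be vetted).
    """
    if not trials:
        return [], 0.0
    kept = [
        t
        for t in trials
        if _has_response(t) and t.latency_ms is not None and lo_ms <= t.latency_ms <= hi_ms
    ]
    return kept, 1.0 - len(kept) / len(trials)


def _by_participant(trials: Sequence) -> dict[str, list]:
    out: dict[str, list] = {}
    for t in trials:
        out.setdefault(t.participant_id, []).append(t)
    return out


def amp_score(
    trials: Sequence[AmpTrial],
    stimuli: Sequence[PrimeStimulus],
    feature: str,
    positive_level: str,
) -> dict[str, PreferenceScore]:
    """AMP difference-of-proportions score per participant.

    ``value = P(more_pleasant | positive_level) − P(more_pleasant | other)``.
    A participant with zero responded trials for either level gets a missing
    (nan) score, never 0.
    """
    levels = _level_map(stimuli, feature)
    lo, hi = feature_levels(stimuli, feature)
    if positive_level not in (lo, hi):
        raise InvalidInputError(f"{positive_level!r} is not a level of {feature!r}")
    scores = {}
    for pid, ts in _by_participant(trials).items():
        n = {positive_level: 0, "other": 0}
        more = {positive_level: 0, "other": 0}
        for t in ts:
            if t.response == "none":
                continue
            if t.prime not in levels:
                raise InvalidInputError(f"trial references unknown stimulus {t.prime!r}")
            key = positive_level if levels[t.prime] == positive_level else "other"
            n[key] += 1
            more[key] += t.response == "more_pleasant"
        used = n[positive_level] + n["other"]
        if n[positive_level] == 0 or n["other"] == 0:
            scores[pid] = PreferenceScore(pid, feature, positive_level, math.nan, used)
        else:
            value = more[positive_level] / n[positive_level] - more["other"] / n["other"]
            scores[pid] = PreferenceScore(pid, feature, positive_level, value, used)
    return scores


def _pairwise_preference_score(
    trials: Sequence[ImpresTrial],
    stimuli: Sequence[PrimeStimulus],
    feature: str,
    focal_level: str,
) -> dict[str, PreferenceScore]:
    levels = _level_map(stimuli, feature)
    lo, hi = feature_levels(stimuli, feature)
    if focal_level not in (lo, hi):
        raise InvalidInputError(f"{focal_level!r} is not a level of {feature!r}")
    scores = {}
    for pid, ts in _by_participant(trials).items():
        n_used = 0
        n_focal = 0
        for t in ts:
            for prime in (t.left_prime, t.right_prime):
                if prime not in levels:
                    raise InvalidInputError(f"trial references unknown stimulus {prime!r}")
            if levels[t.left_prime] == levels[t.right_prime]:
                continue  # same-category pair: uninformative for this feature
            chosen = t.chosen_prime
            if chosen is None:
                continue
            n_used += 1
            n_focal += levels[chosen] == focal_level
        if n_used == 0:
            scores[pid] = PreferenceScore(pid, feature, focal_level, math.nan, 0)
        else:
            scores[pid] = PreferenceScore(pid, feature, focal_level, n_focal / n_used, n_used)
    return scores


def impres_preference_score(
    trials: Sequence[ImpresTrial],
    stimuli: Sequence[PrimeStimulus],
    feature: str,
    focal_level: str,
) -> dict[str, PreferenceScore]:
    """Proportion of cross-category IMPRES trials whose chosen side carried
    ``focal_level``; non-responses and same-category pairs are excluded."""
    return _pairwise_preference_score(trials, stimuli, feature, focal_level)


def expres_preference_score(
    trials: Sequence,
    stimuli: Sequence[PrimeStimulus],
    feature: str,
    focal_level: str,
) -> dict[str, PreferenceScore]:
    """EXPRES analogue of :func:`impres_preference_score` (same contract)."""
    return _pairwise_preference_score(trials, stimuli, feature, focal_level)


def rating_difference_score(
    ratings: Sequence[RatingRecord],
    stimuli: Sequence[PrimeStimulus],
    feature: str,
    focal_level: str,
) -> dict[str, PreferenceScore]:
    """mean(rating | focal level) − mean(rating | other level), per participant."""
    levels = _level_map(stimuli, feature)
    lo, hi = feature_levels(stimuli, feature)
    if focal_level not in (lo, hi):
        raise InvalidInputError(f"{focal_level!r} is not a level of {feature!r}")
    scores = {}
    by_pid: dict[str, list[RatingRecord]] = {}
    for r in ratings:
        by_pid.setdefault(r.participant_id, []).append(r)
    for pid, rs in by_pid.items():
        focal, other = [], []
        for r in rs:
            if r.stimulus_id not in levels:
                raise InvalidInputError(f"rating references unknown stimulus {r.stimulus_id!r}")
            (focal if levels[r.stimulus_id] == focal_level else other).append(r.rating)
        if not focal or not other:
            scores[pid] = PreferenceScore(pid, feature, focal_level, math.nan, len(rs))
        else:
            value = float(np.mean(focal) - np.mean(other))
            scores[pid] = PreferenceScore(pid, feature, focal_level, value, len(focal) + len(other))
    return scores


def questionnaire_sum_score(response: QuestionnaireResponse, scale_max: int = 5) -> int:
    """Sum of item scores after reversing negatively keyed items.

    A reversed item contributes ``scale_max + 1 − score``; midpoint scores are
    invariant under reversal.
    """
    total = 0
    for i, s in enumerate(response.item_scores):
        if not 1 <= s <= scale_max:
            raise InvalidInputError(f"item {i} score {s} outside [1, {scale_max}]")
        total += (scale_max + 1 - s) if i in response.reverse_items else s
    return total


def preference_count_matrix(
    trials: Sequence[ImpresTrial],
    stimuli: Sequence[PrimeStimulus],
    participant_ids: Optional[Sequence[str]] = None,
) -> PreferenceMatrix:
    """Tally how often each stimulus's side was chosen by each participant.

    Every responded trial increments the chosen prime by one; non-responses
    are skipped (but still count toward appearances). Same-category pairs are
    included — that is the point of presenting them.
    """
    sid_index = {s.stimulus_id: j for j, s in enumerate(stimuli)}
    if participant_ids is None:
        seen = []
        for t in trials:
            if t.participant_id not in seen:
                seen.append(t.participant_id)
        participant_ids = seen
    pid_index = {p: i for i, p in enumerate(participant_ids)}
    counts = np.zeros((len(participant_ids), len(stimuli)), dtype=int)
    appearances = np.zeros_like(counts)
    for t in trials:
        if t.participant_id not in pid_index:
            raise InvalidInputError(f"trial references unknown participant {t.participant_id!r}")
        for prime in (t.left_prime, t.right_prime):
            if prime not in sid_index:
                raise InvalidInputError(f"trial references unknown stimulus {prime!r}")
            appearances[pid_index[t.participant_id], sid_index[prime]] += 1
        chosen = t.chosen_prime
        if chosen is not None:
            counts[pid_index[t.participant_id], sid_index[chosen]] += 1
    k = int(appearances.max()) if trials else 0
    return PreferenceMatrix(tuple(participant_ids), tuple(s.stimulus_id for s in stimuli), counts, k)


def scores_to_frame(scores: Mapping[str, PreferenceScore], task: str) -> pd.DataFrame:
    """Long-format score table: participant_id, task, feature, focal_level,
    value, n_trials_used."""
    rows = [
        (s.participant_id, task, s.feature, s.focal_level, s.value, s.n_trials_used)
        for s in scores.values()
    ]
    return pd.DataFrame(
        rows,
        columns=["participant_id", "task", "feature", "focal_level", "value", "n_trials_used"],
    )
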