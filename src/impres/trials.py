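"""Domain types, trial-schedule builders and CSV I/O for comparative-judgment tasks.

Three tasks are modelled:

* **IMPRES** — implicit preference scale: on each trial two primes are flashed
  left/right of fixation, each followed by a Chinese ideograph, and the
  participant picks the preferred ideograph. Every unordered pair of primes
  appears exactly once, so ``n`` primes yield ``n(n-1)/2`` trials.
* **AMP** — affect misattribution procedure: one prime per trial, and the
  target ideograph is judged "less pleasant" or "more pleasant" than average.
* **EXPRES** — explicit preference scale: same all-pairs design as the IMPRES
  but the primes themselves are judged, with no ideographs and no deadline.

Schedules carry presentation timings only as metadata (:class:`ScheduleMeta`);
nothing in the analysis pipeline consumes them. Trial logs are plain UTF-8
CSV with a fixed column set per task.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import InvalidInputError, ParseError

__all__ = [
    "PrimeStimulus",
    "ImpresTrial",
    "AmpTrial",
    "ExpresTrial",
    "RatingRecord",
    "QuestionnaireResponse",
    "ScheduleMeta",
    "build_impres_schedule",
    "build_amp_schedule",
    "build_expres_schedule",
    "read_trials",
    "write_trials",
    "read_stimulus_table",
    "write_stimulus_table",
    "validate_stimulus_set",
    "default_schedule_meta",
    "TASKS",
]

TASKS = ("impres", "amp", "expres")

RESPONSE_SIDES = ("left", "right", "none")
AMP_RESPONSES = ("less_pleasant", "more_pleasant", "none")


@dataclass(frozen=True)
class PrimeStimulus:
    """A prime stimulus with its categorical (and optional continuous) features.

    ``categorical_features`` maps a feature name (e.g. ``"race"``) to one of
    two levels (e.g. ``"white"``); ``continuous_features`` maps a feature name
    to a real value (e.g. a mean trustworthiness rating).
    """

    stimulus_id: str
    categorical_features: Mapping[str, str] = field(default_factory=dict)
    continuous_features: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class ImpresTrial:
    """One IMPRES trial: two primes, a side choice, and a response latency."""

    participant_id: str
    trial_index: int
    left_prime: str
    right_prime: str
    response_side: str = "none"  # left | right | none
    latency_ms: Optional[float] = None

    def __post_init__(self) -> None:
        if self.left_prime == self.right_prime:
            raise InvalidInputError(
                f"trial {self.trial_index} of participant {self.participant_id}: "
                f"left_prime == right_prime ({self.left_prime!r})"
            )
        if self.response_side not in RESPONSE_SIDES:
            raise InvalidInputError(f"invalid response_side {self.response_side!r}")
        if self.latency_ms is not None and self.latency_ms < 0:
            raise InvalidInputError(f"negative latency {self.latency_ms}")

    @property
    def chosen_prime(self) -> Optional[str]:
        if self.response_side == "left":
            return self.left_prime
        if self.response_side == "right":
            return self.right_prime
        return None


class ExpresTrial(ImpresTrial):
    """An EXPRES trial — same pair structure as IMPRES, no deadline semantics."""


@dataclass(frozen=True)
class AmpTrial:
    """One AMP trial: a single prime and a binary pleasantness judgment."""

    participant_id: str
    trial_index: int
    prime: str
    response: str = "none"  # less_pleasant | more_pleasant | none
    latency_ms: Optional[float] = None

    def __post_init__(self) -> None:
        if self.response not in AMP_RESPONSES:
            raise InvalidInputError(f"invalid AMP response {self.response!r}")
        if self.latency_ms is not None and self.latency_ms < 0:
            raise InvalidInputError(f"negative latency {self.latency_ms}")


@dataclass(frozen=True)
class RatingRecord:
    """A pleasantness rating of one stimulus on a k-point scale (default 9)."""

    participant_id: str
    stimulus_id: str
    rating: int
    scale_max: int = 9

    def __post_init__(self) -> None:
        if not 1 <= self.rating <= self.scale_max:
            raise InvalidInputError(
                f"rating {self.rating} outside [1, {self.scale_max}] "
                f"for participant {self.participant_id}"
            )


@dataclass(frozen=True)
class QuestionnaireResponse:
    """Item scores for one participant on a Likert questionnaire.

    ``reverse_items`` holds 0-based indices of negatively keyed items; they are
    reversed (``scale_max + 1 - score``) before summing.
    """

    participant_id: str
    item_scores: Sequence[int]
    reverse_items: frozenset = frozenset()
    scale_max: int = 5

    def __post_init__(self) -> None:
        for i, s in enumerate(self.item_scores):
            if not 1 <= s <= self.scale_max:
                raise InvalidInputError(
                    f"item {i} score {s} outside [1, {self.scale_max}] "
                    f"for participant {self.participant_id}"
                )


@dataclass(frozen=True)
class ScheduleMeta:
    """Presentation timings (ms) for one task; documentation only, never computed on.

    ``deadline_ms`` is ``None`` for the EXPRES, which imposes no response deadline.
    """

    task: str
    fixation_ms: float = 500.0
    prime_ms: float = 75.0
    blank_ms: float = 125.0
    target_ms: float = 100.0
    deadline_ms: Optional[float] = 1500.0
    rng_seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise InvalidInputError(f"unknown task {self.task!r}")
        for name in ("fixation_ms", "prime_ms", "blank_ms", "target_ms"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be positive")
        if self.deadline_ms is not None and self.deadline_ms <= 0:
            raise InvalidInputError("deadline_ms must be positive or None")


def default_schedule_meta(task: str, rng_seed: Optional[int] = None) -> ScheduleMeta:
    """Timings of the reference design: 75-ms primes in the AMP, 150-ms
    simultaneous primes in the IMPRES, untimed EXPRES."""
    if task == "amp":
        return ScheduleMeta("amp", 500.0, 75.0, 125.0, 100.0, 1500.0, rng_seed)
    if task == "impres":
        return ScheduleMeta("impres", 500.0, 150.0, 150.0, 100.0, 1500.0, rng_seed)
    if task == "expres":
        return ScheduleMeta("expres", 500.0, 150.0, 150.0, 100.0, None, rng_seed)
    raise InvalidInputError(f"unknown task {task!r}")


# ---------------------------------------------------------------------------
# schedule builders
# ---------------------------------------------------------------------------

def _prime_ids(primes: Iterable) -> list[str]:
    ids = [p.stimulus_id if isinstance(p, PrimeStimulus) else str(p) for p in primes]
    if len(set(ids)) != len(ids):
        raise InvalidInputError("duplicate stimulus IDs in prime set")
    return ids


def build_impres_schedule(
    primes: Sequence,
    rng_seed: int,
    participant_id: str = "sim",
    trial_cls: type = ImpresTrial,
) -> list[ImpresTrial]:
    """All-pairs pairwise schedule: one trial per unordered pair of primes.

    Left/right placement is an independent fair coin per trial and the trial
    order is randomly permuted; both are deterministic given ``rng_seed``.
    """
    ids = _prime_ids(primes)
    if len(ids) < 2:
        raise InvalidInputError("need at least 2 primes for a pairwise schedule")
    rng = np.random.default_rng(rng_seed)
    pairs = list(itertools.combinations(ids, 2))
    rng.shuffle(pairs)
    flips = rng.random(len(pairs)) < 0.5
    trials = []
    for idx, ((a, b), flip) in enumerate(zip(pairs, flips)):
        left, right = (b, a) if flip else (a, b)
        trials.append(trial_cls(participant_id, idx, left, right))
    return trials


def build_expres_schedule(
    primes: Sequence, rng_seed: int, participant_id: str = "sim"
) -> list[ExpresTrial]:
    """All-pairs schedule for the explicit preference task; same contract as
    :func:`build_impres_schedule`."""
    return build_impres_schedule(primes, rng_seed, participant_id, trial_cls=ExpresTrial)


def build_amp_schedule(
    primes: Sequence,
    repetitions: int = 6,
    rng_seed: int = 0,
    participant_id: str = "sim",
) -> list[AmpTrial]:
    """AMP schedule: each prime presented ``repetitions`` times in random order."""
    ids = _prime_ids(primes)
    if not ids:
        raise InvalidInputError("need at least 1 prime")
    if repetitions < 1:
        raise InvalidInputError("repetitions must be >= 1")
    rng = np.random.default_rng(rng_seed)
    seq = np.repeat(np.arange(len(ids)), repetitions)
    rng.shuffle(seq)
    return [AmpTrial(participant_id, idx, ids[j]) for idx, j in enumerate(seq)]


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_PAIR_COLUMNS = [
    "participant_id",
    "trial_index",
    "left_prime",
    "right_prime",
    "response_side",
    "latency_ms",
]
_AMP_COLUMNS = ["participant_id", "trial_index", "prime", "response", "latency_ms"]


def _fmt_latency(latency: Optional[float]) -> str:
    # repr gives the shortest digits that round-trip exactly
    return "" if latency is None else repr(float(latency))


def write_trials(trials: Sequence, path: Union[str, Path]) -> None:
    """Write a homogeneous trial list as CSV; the task dialect is inferred
    from the record type."""
    path = Path(path)
    if not trials:
        raise InvalidInputError("refusing to write an empty trial list")
    if isinstance(trials[0], AmpTrial):
        rows = [
            (t.participant_id, t.trial_index, t.prime, t.response, _fmt_latency(t.latency_ms))
            for t in trials
        ]
        cols = _AMP_COLUMNS
    else:
        rows = [
            (
                t.participant_id,
                t.trial_index,
                t.left_prime,
                t.right_prime,
                t.response_side,
                _fmt_latency(t.latency_ms),
            )
            for t in trials
        ]
        cols = _PAIR_COLUMNS
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_trials(path: Union[str, Path], task: str) -> list:
    """Read a trial log CSV for ``task`` ∈ {impres, amp, expres}.

    Raises :class:`ParseError` naming the offending row for unknown columns,
    duplicate ``(participant_id, trial_index)`` keys, malformed response
    codes, or identical left/right primes. A missing ``latency_ms`` field
    yields a record with ``latency_ms=None``.
    """
    if task not in TASKS:
        raise InvalidInputError(f"unknown task {task!r}")
    expected = _AMP_COLUMNS if task == "amp" else _PAIR_COLUMNS
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != expected:
        unknown = [c for c in df.columns if c not in expected]
        missing = [c for c in expected if c not in df.columns]
        raise ParseError(
            f"{path}: bad header; unknown columns {unknown}, missing {missing}"
        )

    seen: set[tuple[str, int]] = set()
    records = []
    for rownum, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        try:
            trial_index = int(row.trial_index)
        except ValueError as exc:
            raise ParseError(f"{path}, row {rownum}: bad trial_index {row.trial_index!r}") from exc
        key = (row.participant_id, trial_index)
        if key in seen:
            raise ParseError(f"{path}, row {rownum}: duplicate (participant, trial_index) {key}")
        seen.add(key)
        latency = None if row.latency_ms == "" else float(row.latency_ms)
        try:
            if task == "amp":
                records.append(
                    AmpTrial(row.participant_id, trial_index, row.prime, row.response, latency)
                )
            else:
                cls = ImpresTrial if task == "impres" else ExpresTrial
                records.append(
                    cls(
                        row.participant_id,
                        trial_index,
                        row.left_prime,
                        row.right_prime,
                        row.response_side,
                        latency,
                    )
                )
        except InvalidInputError as exc:
            raise ParseError(f"{path}, row {rownum}: {exc}") from exc
    return records


# ---------------------------------------------------------------------------
# stimulus tables
# ---------------------------------------------------------------------------

def validate_stimulus_set(stimuli: Sequence[PrimeStimulus]) -> None:
    """Check ID uniqueness and that every stimulus defines the same feature names."""
    ids = [s.stimulus_id for s in stimuli]
    if len(set(ids)) != len(ids):
        raise InvalidInputError("duplicate stimulus_id in stimulus set")
    if not stimuli:
        return
    cat = set(stimuli[0].categorical_features)
    cont = set(stimuli[0].continuous_features)
    for s in stimuli[1:]:
        if set(s.categorical_features) != cat or set(s.continuous_features) != cont:
            raise InvalidInputError(
                f"stimulus {s.stimulus_id} defines different feature names than "
                f"{stimuli[0].stimulus_id}"
            )


def write_stimulus_table(stimuli: Sequence[PrimeStimulus], path: Union[str, Path]) -> None:
    validate_stimulus_set(stimuli)
    rows = []
    for s in stimuli:
        row: dict = {"stimulus_id": s.stimulus_id}
        row.update(s.categorical_features)
        row.update(s.continuous_features)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_stimulus_table(path: Union[str, Path]) -> list[PrimeStimulus]:
    """Read a stimulus table CSV: ``stimulus_id`` plus one column per feature.

    Columns that parse as numbers become continuous features; the rest are
    categorical.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "stimulus_id" not in df.columns:
        raise ParseError(f"{path}: missing stimulus_id column")
    feature_cols = [c for c in df.columns if c != "stimulus_id"]
    numeric: dict[str, bool] = {}
    for c in feature_cols:
        try:
            df[c].astype(float)
            numeric[c] = True
        except ValueError:
            numeric[c] = False
    stimuli = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        cat = {c: d[c] for c in feature_cols if not numeric[c]}
        cont = {c: float(d[c]) for c in feature_cols if numeric[c]}
        stimuli.append(PrimeStimulus(d["stimulus_id"], cat, cont))
    validate_stimulus_set(stimuli)
    return stimuli
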