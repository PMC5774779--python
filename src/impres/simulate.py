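"""Generative model of misattribution-based task behavior.

The simulator formalizes the misattribution hypothesis behind the IMPRES —
that the preference between two briefly primed ideographs tracks the
preference between the primes — as a Bradley–Terry-style logistic choice
law over latent attitudes.

Latent structure. Each participant p holds an attitude toward each stimulus
s built from the stimulus's binary features (coded x_f ∈ {−1/2, +1/2}, so a
participant's feature weight is the full between-level attitude gap) plus a
stimulus-specific idiosyncrasy:

    a(p, s) = sum_f beta_f(p) * x_f(s) + gamma(p, s),
    beta_f(p) ~ Normal(beta_mean_f, beta_sd_f^2),
    gamma(p, s) ~ Normal(0, gamma_sd^2).

A small fraction of "outlier" participants get their betas multiplied by a
constant, emulating extreme responders.

Choice laws (lapse rate eps mixes in uniform guessing):

    IMPRES:  P(choose left)     = eps/2 + (1 − eps) * logistic(lam * (a_left − a_right))
    AMP:     P("more pleasant") = eps/2 + (1 − eps) * logistic(kappa * a_prime + bias)
    EXPRES:  as IMPRES with its own discrimination lam_explicit (explicit
             judgments are modeled as higher-discrimination comparisons)
    Ratings: clip(round(midpoint + rating_scale * a + noise), 1, k)

Latencies are lognormal with small uniform fast-guess and slow-tail
contamination, so the standard 150–1500 ms filter has work to do.

Defaults reproduce the reference study design: 20 primes (5 per race × age
cell, IDs like ``WY1``/``BO3``), 53 participants, 190 IMPRES trials (all
pairs), 120 AMP trials (6 per prime), 190 EXPRES trials, 9-point ratings,
and a 10-item 5-point questionnaire.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import InvalidInputError
from .trials import (
    AmpTrial,
    ExpresTrial,
    ImpresTrial,
    PrimeStimulus,
    QuestionnaireResponse,
    RatingRecord,
    build_amp_schedule,
    build_expres_schedule,
    build_impres_schedule,
    write_stimulus_table,
    write_trials,
)

__all__ = [
    "PopulationConfig",
    "TaskParams",
    "LatentAttitudes",
    "StudyData",
    "default_stimulus_set",
    "draw_population",
    "simulate_impres",
    "simulate_amp",
    "simulate_expres",
    "simulate_ratings",
    "simulate_questionnaire",
    "make_study",
    "write_study",
]


@dataclass(frozen=True)
class PopulationConfig:
    """Population-level generative parameters.

    ``feature_effects`` maps feature name → (mean, sd) of the per-participant
    attitude gap beta_f; ``positive_levels`` names the level coded +1/2.
    """

    n_participants: int = 53
    feature_effects: Mapping[str, tuple] = field(
        default_factory=lambda: {"race": (0.0, 1.0), "age": (0.3, 1.0)}
    )
    positive_levels: Mapping[str, str] = field(
        default_factory=lambda: {"race": "white", "age": "young"}
    )
    gamma_sd: float = 0.5
    outlier_fraction: float = 0.04
    outlier_multiplier: float = 4.0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise InvalidInputError("n_participants must be >= 1")
        for f, (_, sd) in self.feature_effects.items():
            if sd < 0:
                raise InvalidInputError(f"negative sd for feature {f!r}")
        if self.gamma_sd < 0:
            raise InvalidInputError("gamma_sd must be >= 0")
        if not 0.0 <= self.outlier_fraction <= 1.0:
            raise InvalidInputError("outlier_fraction must be in [0, 1]")


@dataclass(frozen=True)
class TaskParams:
    """Task-level response and latency parameters."""

    lam: float = 2.0  # IMPRES misattribution strength
    kappa: float = 2.0  # AMP judgment scale
    amp_bias: float = 0.0  # AMP response bias toward "more pleasant"
    lam_explicit: float = 6.0  # EXPRES discrimination
    lapse_rate: float = 0.02
    rating_scale: float = 1.5
    rating_noise_sd: float = 1.0
    rating_points: int = 9
    latency_log_mean: float = 6.4  # exp(6.4) ~ 600 ms
    latency_log_sd: float = 0.3
    fast_guess_rate: float = 0.02
    slow_tail_rate: float = 0.03
    choice_link: str = "logistic"  # or "probit"

    def __post_init__(self) -> None:
        if min(self.lam, self.kappa, self.lam_explicit) < 0:
            raise InvalidInputError("discrimination parameters must be >= 0")
        if not 0.0 <= self.lapse_rate <= 0.5:
            raise InvalidInputError("lapse_rate must be in [0, 0.5]")
        if self.choice_link not in ("logistic", "probit"):
            raise InvalidInputError(f"unknown choice link {self.choice_link!r}")

    def link(self, z: np.ndarray) -> np.ndarray:
        if self.choice_link == "probit":
            from scipy.stats import norm

            return norm.cdf(z)
        return expit(z)


@dataclass(frozen=True)
class LatentAttitudes:
    """Ground-truth attitudes a(p, s) with the draws that produced them."""

    participant_ids: tuple
    stimulus_ids: tuple
    attitudes: np.ndarray  # participants x stimuli
    betas: pd.DataFrame  # participants x features
    gamma: np.ndarray  # participants x stimuli
    is_outlier: np.ndarray  # bool per participant

    def attitude(self, participant_id: str, stimulus_id: str) -> float:
        i = self.participant_ids.index(participant_id)
        j = self.stimulus_ids.index(stimulus_id)
        return float(self.attitudes[i, j])


def default_stimulus_set() -> list[PrimeStimulus]:
    """The reference prime set: 20 faces, 5 per race × age cell.

    IDs follow the field's convention: first letter race (B/W), second
    letter age (Y/O), then the exemplar number — e.g. ``WY5``, ``BO2``.
    """
    stimuli = []
    for race, r in (("black", "B"), ("white", "W")):
        for age, a in (("young", "Y"), ("old", "O")):
            for i in range(1, 6):
                stimuli.append(
                    PrimeStimulus(f"{r}{a}{i}", {"race": race, "age": age})
                )
    return stimuli


def draw_population(
    config: PopulationConfig,
    stimuli: Sequence[PrimeStimulus],
    rng_seed: int = 0,
) -> LatentAttitudes:
    """Draw per-participant feature weights and idiosyncrasies, and assemble
    the attitude matrix. Deterministic given the seed."""
    rng = np.random.default_rng(rng_seed)
    n_p = config.n_participants
    n_s = len(stimuli)
    features = list(config.feature_effects)
    pids = tuple(f"P{i + 1:02d}" for i in range(n_p))
    sids = tuple(s.stimulus_id for s in stimuli)

    betas = np.empty((n_p, len(features)))
    for j, f in enumerate(features):
        mean, sd = config.feature_effects[f]
        betas[:, j] = rng.normal(mean, sd, size=n_p)
    is_outlier = rng.random(n_p) < config.outlier_fraction
    betas[is_outlier] *= config.outlier_multiplier
    gamma = rng.normal(0.0, config.gamma_sd, size=(n_p, n_s))

    coding = np.empty((n_s, len(features)))
    for j, f in enumerate(features):
        pos = config.positive_levels.get(f)
        if pos is None:
            raise InvalidInputError(f"no positive level configured for feature {f!r}")
        for i, s in enumerate(stimuli):
            if f not in s.categorical_features:
                raise InvalidInputError(f"stimulus {s.stimulus_id} lacks feature {f!r}")
            coding[i, j] = 0.5 if s.categorical_features[f] == pos else -0.5

    attitudes = betas @ coding.T + gamma
    return LatentAttitudes(
        participant_ids=pids,
        stimulus_ids=sids,
        attitudes=attitudes,
        betas=pd.DataFrame(betas, index=list(pids), columns=features),
        gamma=gamma,
        is_outlier=is_outlier,
    )


def _draw_latencies(rng: np.random.Generator, n: int, params: TaskParams) -> np.ndarray:
    lat = rng.lognormal(params.latency_log_mean, params.latency_log_sd, size=n)
    u = rng.random(n)
    fast = u < params.fast_guess_rate
    slow = u > 1.0 - params.slow_tail_rate
    lat[fast] = rng.uniform(0.0, 150.0, size=fast.sum())
    lat[slow] = rng.uniform(1500.0, 3000.0, size=slow.sum())
    return lat


def _indices(attitudes: LatentAttitudes) -> tuple[dict, dict]:
    return (
        {p: i for i, p in enumerate(attitudes.participant_ids)},
        {s: j for j, s in enumerate(attitudes.stimulus_ids)},
    )


def _pairwise_choice_prob(
    trials: Sequence[ImpresTrial],
    attitudes: LatentAttitudes,
    discrimination: float,
    params: TaskParams,
) -> np.ndarray:
    pidx, sidx = _indices(attitudes)
    try:
        diff = np.array(
            [
                attitudes.attitudes[pidx[t.participant_id], sidx[t.left_prime]]
                - attitudes.attitudes[pidx[t.participant_id], sidx[t.right_prime]]
                for t in trials
            ]
        )
    except KeyError as exc:
        raise InvalidInputError(f"schedule references unknown id {exc.args[0]!r}") from exc
    eps = params.lapse_rate
    return eps / 2.0 + (1.0 - eps) * params.link(discrimination * diff)


def _simulate_pairwise(
    schedule: Sequence[ImpresTrial],
    attitudes: LatentAttitudes,
    discrimination: float,
    params: TaskParams,
    rng_seed: int,
    trial_cls: type,
) -> list:
    rng = np.random.default_rng(rng_seed)
    p_left = _pairwise_choice_prob(schedule, attitudes, discrimination, params)
    choose_left = rng.random(len(schedule)) < p_left
    latencies = _draw_latencies(rng, len(schedule), params)
    return [
        trial_cls(
            t.participant_id,
            t.trial_index,
            t.left_prime,
            t.right_prime,
            "left" if cl else "right",
            float(lat),
        )
        for t, cl, lat in zip(schedule, choose_left, latencies)
    ]


def simulate_impres(
    schedule: Sequence[ImpresTrial],
    attitudes: LatentAttitudes,
    params: TaskParams,
    rng_seed: int = 0,
) -> list[ImpresTrial]:
    """Fill an IMPRES schedule with choices from the misattribution model:
    P(choose left) = eps/2 + (1 − eps)·link(lam·(a_left − a_right))."""
    return _simulate_pairwise(schedule, attitudes, params.lam, params, rng_seed, ImpresTrial)


def simulate_expres(
    schedule: Sequence[ExpresTrial],
    attitudes: LatentAttitudes,
    params: TaskParams,
    rng_seed: int = 0,
) -> list[ExpresTrial]:
    """As :func:`simulate_impres` with the explicit discrimination lam_explicit."""
    return _simulate_pairwise(
        schedule, attitudes, params.lam_explicit, params, rng_seed, ExpresTrial
    )


def simulate_amp(
    schedule: Sequence[AmpTrial],
    attitudes: LatentAttitudes,
    params: TaskParams,
    rng_seed: int = 0,
) -> list[AmpTrial]:
    """Fill an AMP schedule: P("more pleasant") = eps/2 + (1 − eps)·link(kappa·a + bias)."""
    rng = np.random.default_rng(rng_seed)
    pidx, sidx = _indices(attitudes)
    try:
        a = np.array(
            [attitudes.attitudes[pidx[t.participant_id], sidx[t.prime]] for t in schedule]
        )
    except KeyError as exc:
        raise InvalidInputError(f"schedule references unknown id {exc.args[0]!r}") from exc
    eps = params.lapse_rate
    p_more = eps / 2.0 + (1.0 - eps) * params.link(params.kappa * a + params.amp_bias)
    more = rng.random(len(schedule)) < p_more
    latencies = _draw_latencies(rng, len(schedule), params)
    return [
        AmpTrial(
            t.participant_id,
            t.trial_index,
            t.prime,
            "more_pleasant" if m else "less_pleasant",
            float(lat),
        )
        for t, m, lat in zip(schedule, more, latencies)
    ]


def simulate_ratings(
    stimuli: Sequence[PrimeStimulus],
    attitudes: LatentAttitudes,
    params: TaskParams,
    rng_seed: int = 0,
) -> list[RatingRecord]:
    """Pleasantness ratings: clip(round(midpoint + scale·a + noise), 1, k)."""
    rng = np.random.default_rng(rng_seed)
    k = params.rating_points
    midpoint = (k + 1) / 2.0
    _, sidx = _indices(attitudes)
    records = []
    for i, pid in enumerate(attitudes.participant_ids):
        for s in stimuli:
            a = attitudes.attitudes[i, sidx[s.stimulus_id]]
            raw = midpoint + params.rating_scale * a + rng.normal(0.0, params.rating_noise_sd)
            records.append(
                RatingRecord(pid, s.stimulus_id, int(np.clip(round(raw), 1, k)), k)
            )
    return records


#: items keyed negatively in the simulated 10-item questionnaire
DEFAULT_REVERSE_ITEMS = frozenset({2, 5, 7, 9})


def simulate_questionnaire(
    attitudes: LatentAttitudes,
    rng_seed: int = 0,
    n_items: int = 10,
    scale_max: int = 5,
    loading: float = 0.5,
    noise_sd: float = 0.8,
    reverse_items: frozenset = DEFAULT_REVERSE_ITEMS,
) -> list[QuestionnaireResponse]:
    """Questionnaire items as noisy linear functions of the race attitude —
    enough structure to exercise sum-scoring, with no claim of psychometric
    realism."""
    rng = np.random.default_rng(rng_seed)
    beta_race = (
        attitudes.betas["race"].to_numpy()
        if "race" in attitudes.betas.columns
        else np.zeros(len(attitudes.participant_ids))
    )
    midpoint = (scale_max + 1) / 2.0
    responses = []
    for i, pid in enumerate(attitudes.participant_ids):
        scores = []
        for item in range(n_items):
            raw = midpoint + loading * beta_race[i] + rng.normal(0.0, noise_sd)
            score = int(np.clip(round(raw), 1, scale_max))
            if item in reverse_items:  # negatively keyed item
                score = scale_max + 1 - score
            scores.append(score)
        responses.append(QuestionnaireResponse(pid, tuple(scores), reverse_items, scale_max))
    return responses


@dataclass(frozen=True)
class StudyData:
    """One complete synthetic study: stimuli, all four task logs, the
    questionnaire, and the ground truth that generated them."""

    stimuli: list
    impres: list
    amp: list
    expres: list
    ratings: list
    questionnaire: list
    attitudes: LatentAttitudes
    rng_seed: int
    config: PopulationConfig
    params: TaskParams


def make_study(
    config: Optional[PopulationConfig] = None,
    params: Optional[TaskParams] = None,
    rng_seed: int = 0,
    stimuli: Optional[Sequence[PrimeStimulus]] = None,
    amp_repetitions: int = 6,
) -> StudyData:
    """Simulate a full study under the reference design.

    One seed controls everything: per-stage seeds are spawned
    deterministically from ``rng_seed``, so two runs with the same seed
    produce byte-identical CSV bundles.
    """
    config = config or PopulationConfig()
    params = params or TaskParams()
    stimuli = list(stimuli) if stimuli is not None else default_stimulus_set()

    seeds = np.random.SeedSequence(rng_seed).generate_state(6) % (2**31)
    attitudes = draw_population(config, stimuli, rng_seed=int(seeds[0]))

    impres_trials: list[ImpresTrial] = []
    amp_trials: list[AmpTrial] = []
    expres_trials: list[ExpresTrial] = []
    for i, pid in enumerate(attitudes.participant_ids):
        base = np.random.SeedSequence([rng_seed, i]).generate_state(6) % (2**31)
        sched_i = build_impres_schedule(stimuli, int(base[0]), participant_id=pid)
        impres_trials += simulate_impres(sched_i, attitudes, params, int(base[1]))
        sched_a = build_amp_schedule(
            stimuli, repetitions=amp_repetitions, rng_seed=int(base[2]), participant_id=pid
        )
        amp_trials += simulate_amp(sched_a, attitudes, params, int(base[3]))
        sched_e = build_expres_schedule(stimuli, int(base[4]), participant_id=pid)
        expres_trials += simulate_expres(sched_e, attitudes, params, int(base[5]))

    ratings = simulate_ratings(stimuli, attitudes, params, rng_seed=int(seeds[1]))
    questionnaire = simulate_questionnaire(attitudes, rng_seed=int(seeds[2]))
    return StudyData(
        stimuli=stimuli,
        impres=impres_trials,
        amp=amp_trials,
        expres=expres_trials,
        ratings=ratings,
        questionnaire=questionnaire,
        attitudes=attitudes,
        rng_seed=rng_seed,
        config=config,
        params=params,
    )


def write_study(study: StudyData, out_dir: Union[str, Path]) -> dict[str, Path]:
    """Write the CSV bundle the analysis pipeline consumes, plus ground truth.

    Files: stimuli.csv, impres.csv, amp.csv, expres.csv, ratings.csv,
    questionnaire.csv, truth_participants.csv, truth_attitudes.csv and a
    study.json sidecar recording the seed and parameters.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    write_stimulus_table(study.stimuli, out / "stimuli.csv")
    paths["stimuli"] = out / "stimuli.csv"
    for name, trials in (
        ("impres", study.impres),
        ("amp", study.amp),
        ("expres", study.expres),
    ):
        write_trials(trials, out / f"{name}.csv")
        paths[name] = out / f"{name}.csv"

    pd.DataFrame(
        [(r.participant_id, r.stimulus_id, r.rating) for r in study.ratings],
        columns=["participant_id", "stimulus_id", "rating"],
    ).to_csv(out / "ratings.csv", index=False)
    paths["ratings"] = out / "ratings.csv"

    n_items = len(study.questionnaire[0].item_scores) if study.questionnaire else 0
    q_rows = [
        [q.participant_id, *q.item_scores] for q in study.questionnaire
    ]
    pd.DataFrame(
        q_rows, columns=["participant_id"] + [f"item_{i + 1:02d}" for i in range(n_items)]
    ).to_csv(out / "questionnaire.csv", index=False)
    paths["questionnaire"] = out / "questionnaire.csv"

    truth_p = study.attitudes.betas.copy()
    truth_p.insert(0, "participant_id", list(study.attitudes.participant_ids))
    truth_p["is_outlier"] = study.attitudes.is_outlier
    truth_p.to_csv(out / "truth_participants.csv", index=False)
    paths["truth_participants"] = out / "truth_participants.csv"

    att = pd.DataFrame(
        study.attitudes.attitudes,
        index=list(study.attitudes.participant_ids),
        columns=list(study.attitudes.stimulus_ids),
    )
    att.index.name = "participant_id"
    att.to_csv(out / "truth_attitudes.csv")
    paths["truth_attitudes"] = out / "truth_attitudes.csv"

    sidecar = {
        "rng_seed": study.rng_seed,
        "n_participants": study.config.n_participants,
        "n_stimuli": len(study.stimuli),
        "feature_effects": {f: list(v) for f, v in study.config.feature_effects.items()},
        "positive_levels": dict(study.config.positive_levels),
        "gamma_sd": study.config.gamma_sd,
        "outlier_fraction": study.config.outlier_fraction,
        "outlier_multiplier": study.config.outlier_multiplier,
        "task_params": {
            "lam": study.params.lam,
            "kappa": study.params.kappa,
            "amp_bias": study.params.amp_bias,
            "lam_explicit": study.params.lam_explicit,
            "lapse_rate": study.params.lapse_rate,
            "choice_link": study.params.choice_link,
        },
    }
    (out / "study.json").write_text(json.dumps(sidecar, indent=2) + "\n")
    paths["sidecar"] = out / "study.json"
    return paths
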