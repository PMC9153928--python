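"""Synthetic cohort simulator for the within-subject crossover design.

Emulates a 31-subject trial in which every participant performs the dual
2-back once under each of five sound conditions (silence, a 240 Hz pure
tone, and 10/16/40 Hz binaural beats), in an independently randomized
order, five 8-minute blocks per session.

Responding is Bernoulli on the log-odds scale: each subject carries
baseline hit and false-alarm probabilities per modality, a per-block
training trend, a half-block "fatigue" contrast (so the configured effect
is exactly the second-minus-first-half delta the scoring stage measures),
a lure odds multiplier, and additive condition shifts. Latencies are
truncated lognormal with per-subject location, within-block scale, and
age/volume covariate effects on the log scale.

Generative magnitudes are calibration choices set once to reproduce the
qualitative group structure of a published cohort of this design (hit
rates ~0.80-0.91, false-alarm rates ~0.04-0.14, mean latencies ~1.4-1.6 s
with within-block SDs ~0.43-0.55 s, negative visuospatial and near-zero
verbal half-block hit deltas, opposite-signed false-alarm deltas); see
docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .specs import BlockSpec, MODALITIES, default_spec
from .sequences import StimulusSequence, generate_dual_block

__all__ = [
    "CONDITIONS",
    "Population",
    "SubjectProfile",
    "CohortDesign",
    "sample_profile",
    "simulate_trial",
    "simulate_cohort",
    "default_condition_effects",
]

CONDITIONS = ("silence", "pure_tone_240Hz", "BB_10Hz", "BB_16Hz", "BB_40Hz")

#: Reference age (years) about which the latency covariate effect is centred.
AGE_CENTER = 30.84


def default_condition_effects() -> Dict[str, Dict[str, Dict[str, float]]]:
    """Additive condition shifts: log-odds for hit/fa, log-seconds for rt.

    Silence is the all-zero reference. The non-zero defaults encode the
    directional cohort findings: a lower verbal hit rate under the 10 Hz
    binaural beat, a raised verbal false-alarm rate under the pure tone,
    and slightly faster visuospatial responding under the 10 Hz beat.
    """
    effects = {
        c: {m: {"hit": 0.0, "fa": 0.0, "rt": 0.0} for m in MODALITIES}
        for c in CONDITIONS
    }
    effects["BB_10Hz"]["auditory_verbal"]["hit"] = -0.20
    effects["pure_tone_240Hz"]["auditory_verbal"]["fa"] = 0.10
    effects["BB_10Hz"]["visuospatial"]["rt"] = -0.025
    return effects


@dataclass(frozen=True)
class Population:
    """Hyperparameters of the synthetic subject population.

    Probabilities are parameterised on the logit scale (mean, SD of a
    normal); latencies on the log scale. ``fatigue`` terms are half-block
    contrasts, ``training`` terms per-block linear trends.
    """

    age_mean: float = 30.84
    age_sd: float = 6.16
    age_bounds: Tuple[float, float] = (19.0, 42.0)
    p_female: float = 17 / 31
    volume_sd: float = 1.0
    hit_logit_mean: Dict[str, float] = field(
        default_factory=lambda: {"visuospatial": 1.59, "auditory_verbal": 2.04}
    )
    hit_logit_sd: float = 0.80
    fa_logit_mean: Dict[str, float] = field(
        default_factory=lambda: {"visuospatial": -3.00, "auditory_verbal": -2.50}
    )
    fa_logit_sd: float = 0.80
    log_lure_mult_mean: float = 0.70
    log_lure_mult_sd: float = 0.30
    training_hit_mean: float = 0.10
    training_hit_sd: float = 0.05
    training_fa_mean: float = -0.05
    training_fa_sd: float = 0.05
    fatigue_hit_mean: Dict[str, float] = field(
        default_factory=lambda: {"visuospatial": -0.35, "auditory_verbal": -0.10}
    )
    fatigue_hit_sd: float = 0.30
    fatigue_fa_mean: Dict[str, float] = field(
        default_factory=lambda: {"visuospatial": -0.15, "auditory_verbal": 0.20}
    )
    fatigue_fa_sd: float = 0.25
    rt_location_mean: Dict[str, float] = field(
        default_factory=lambda: {"visuospatial": 0.33, "auditory_verbal": 0.40}
    )
    rt_location_sd: Dict[str, float] = field(
        default_factory=lambda: {"visuospatial": 0.17, "auditory_verbal": 0.13}
    )
    rt_scale_mean: Dict[str, float] = field(
        default_factory=lambda: {"visuospatial": 0.330, "auditory_verbal": 0.295}
    )
    rt_scale_sd: float = 0.04
    rt_training_mean: float = -0.012
    rt_training_sd: float = 0.010
    rt_half_mean: Dict[str, float] = field(
        default_factory=lambda: {"visuospatial": -0.034, "auditory_verbal": -0.020}
    )
    rt_half_sd: float = 0.08
    age_rt_coeff: float = 0.006
    volume_rt_coeff: float = -0.02

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_female <= 1.0:
            raise ValueError("p_female must lie in [0, 1]")
        if self.age_sd < 0 or self.age_bounds[0] >= self.age_bounds[1]:
            raise ValueError("invalid age hyperparameters")
        for sd_name in ("hit_logit_sd", "fa_logit_sd", "rt_scale_sd"):
            if getattr(self, sd_name) < 0:
                raise ValueError(f"{sd_name} must be >= 0")


@dataclass(frozen=True)
class SubjectProfile:
    """Generative parameters of one synthetic participant."""

    subject_id: str
    sex: str
    age: float
    volume: float
    baseline_hit_prob: Dict[str, float]
    baseline_fa_prob: Dict[str, float]
    lure_fa_multiplier: float
    training_hit_slope: float
    training_fa_slope: float
    fatigue_hit_slope: Dict[str, float]
    fatigue_fa_slope: Dict[str, float]
    rt_location: Dict[str, float]
    rt_scale: Dict[str, float]
    rt_training_slope: float
    rt_half_slope: Dict[str, float]
    age_rt_coeff: float
    volume_rt_coeff: float

    def __post_init__(self) -> None:
        for d in (self.baseline_hit_prob, self.baseline_fa_prob):
            for p in d.values():
                if not 0.0 < p < 1.0:
                    raise ValueError("baseline probabilities must lie in (0, 1)")
        if self.lure_fa_multiplier < 1.0:
            raise ValueError("lure_fa_multiplier must be >= 1")
        for s in self.rt_scale.values():
            if s <= 0:
                raise ValueError("rt_scale must be positive")


def sample_profile(
    population: Population, rng: np.random.Generator, subject_id: str = "S01"
) -> SubjectProfile:
    """Draw one subject from the population.

    Age is truncated normal on the configured bounds; sex a Bernoulli with
    the cohort's 17:14 female:male odds; sound volume a standardized
    per-subject constant; probabilities are drawn on the logit scale so
    they stay strictly inside (0, 1).
    """
    pop = population
    a = (pop.age_bounds[0] - pop.age_mean) / pop.age_sd if pop.age_sd > 0 else -np.inf
    b = (pop.age_bounds[1] - pop.age_mean) / pop.age_sd if pop.age_sd > 0 else np.inf
    if pop.age_sd > 0:
        age = float(
            stats.truncnorm.ppf(rng.uniform(), a, b, loc=pop.age_mean, scale=pop.age_sd)
        )
    else:
        age = pop.age_mean
    sex = "female" if rng.uniform() < pop.p_female else "male"
    volume = float(rng.normal(0.0, pop.volume_sd))

    hit = {
        m: float(expit(rng.normal(pop.hit_logit_mean[m], pop.hit_logit_sd)))
        for m in MODALITIES
    }
    fa = {
        m: float(expit(rng.normal(pop.fa_logit_mean[m], pop.fa_logit_sd)))
        for m in MODALITIES
    }
    lure_mult = float(
        max(1.0, math.exp(rng.normal(pop.log_lure_mult_mean, pop.log_lure_mult_sd)))
    )
    return SubjectProfile(
        subject_id=subject_id,
        sex=sex,
        age=age,
        volume=volume,
        baseline_hit_prob=hit,
        baseline_fa_prob=fa,
        lure_fa_multiplier=lure_mult,
        training_hit_slope=float(rng.normal(pop.training_hit_mean, pop.training_hit_sd)),
        training_fa_slope=float(rng.normal(pop.training_fa_mean, pop.training_fa_sd)),
        fatigue_hit_slope={
            m: float(rng.normal(pop.fatigue_hit_mean[m], pop.fatigue_hit_sd))
            for m in MODALITIES
        },
        fatigue_fa_slope={
            m: float(rng.normal(pop.fatigue_fa_mean[m], pop.fatigue_fa_sd))
            for m in MODALITIES
        },
        rt_location={
            m: float(rng.normal(pop.rt_location_mean[m], pop.rt_location_sd[m]))
            for m in MODALITIES
        },
        rt_scale={
            m: float(max(0.05, rng.normal(pop.rt_scale_mean[m], pop.rt_scale_sd)))
            for m in MODALITIES
        },
        rt_training_slope=float(rng.normal(pop.rt_training_mean, pop.rt_training_sd)),
        rt_half_slope={
            m: float(rng.normal(pop.rt_half_mean[m], pop.rt_half_sd))
            for m in MODALITIES
        },
        age_rt_coeff=pop.age_rt_coeff,
        volume_rt_coeff=pop.volume_rt_coeff,
    )


@dataclass(frozen=True)
class CohortDesign:
    """The crossover layout: subjects x conditions x blocks x modalities."""

    n_subjects: int = 31
    conditions: Tuple[str, ...] = CONDITIONS
    condition_effects: Dict[str, Dict[str, Dict[str, float]]] = field(
        default_factory=default_condition_effects
    )
    blocks_per_session: int = 5
    block_specs: Dict[str, BlockSpec] = field(
        default_factory=lambda: {m: default_spec(m) for m in MODALITIES}
    )
    target_count: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.blocks_per_session != len(self.conditions):
            raise ValueError(
                "within-subject crossover requires one block per condition"
            )
        for c in self.conditions:
            if c not in self.condition_effects:
                raise ValueError(f"condition_effects missing entry for {c!r}")
        ns = {spec.n_trials for spec in self.block_specs.values()}
        if len(ns) != 1:
            raise ValueError("all modalities must share n_trials")


def _response_logits(
    profile: SubjectProfile,
    modality: str,
    condition_effect: Dict[str, float],
    block_index: int,
    is_target: np.ndarray,
    is_lure: np.ndarray,
    second_half: np.ndarray,
) -> np.ndarray:
    """Per-trial log-odds of pressing the key."""
    hit_logit = (
        logit(profile.baseline_hit_prob[modality])
        + profile.training_hit_slope * (block_index - 1)
        + profile.fatigue_hit_slope[modality] * second_half
        + condition_effect["hit"]
    )
    fa_logit = (
        logit(profile.baseline_fa_prob[modality])
        + profile.training_fa_slope * (block_index - 1)
        + profile.fatigue_fa_slope[modality] * second_half
        + condition_effect["fa"]
        + math.log(profile.lure_fa_multiplier) * is_lure
    )
    return np.where(is_target, hit_logit, fa_logit)


def _rt_location(
    profile: SubjectProfile,
    modality: str,
    condition_effect: Dict[str, float],
    block_index: int,
    second_half: np.ndarray,
) -> np.ndarray:
    return (
        profile.rt_location[modality]
        + profile.rt_training_slope * (block_index - 1)
        + profile.rt_half_slope[modality] * second_half
        + profile.age_rt_coeff * (profile.age - AGE_CENTER)
        + profile.volume_rt_coeff * profile.volume
        + condition_effect["rt"]
    )


def _simulate_modality_block(
    profile: SubjectProfile,
    condition: str,
    condition_effects: Dict[str, Dict[str, Dict[str, float]]],
    block_index: int,
    sequence: StimulusSequence,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorized responses for one modality's 145-trial block."""
    modality = sequence.modality
    n = sequence.spec.n_trials
    trial_duration = sequence.spec.trial_duration
    idx = np.arange(1, n + 1)
    second_half = (idx > n // 2).astype(float)
    eff = condition_effects[condition][modality]
    p = expit(
        _response_logits(
            profile, modality, eff, block_index,
            sequence.is_target, sequence.is_lure, second_half,
        )
    )
    responded = rng.uniform(size=n) < p
    loc = _rt_location(profile, modality, eff, block_index, second_half)
    rt = np.exp(rng.normal(loc, profile.rt_scale[modality]))
    rt = np.minimum(rt, trial_duration)
    rt = np.where(responded, rt, np.nan)
    return responded, rt


def simulate_trial(
    profile: SubjectProfile,
    condition: str,
    block_index: int,
    trial_index: int,
    is_target: bool,
    is_lure: bool,
    rng: np.random.Generator,
    modality: str = "visuospatial",
    condition_effects: Optional[Dict] = None,
    n_trials: int = 145,
    trial_duration: float = 3.330,
) -> Tuple[bool, float]:
    """Simulate a single trial's (responded, latency) pair.

    Latency is ``nan`` when no response occurs. The half-block fatigue
    contrast switches on for 1-based ``trial_index > n_trials // 2``.
    """
    if condition_effects is None:
        condition_effects = default_condition_effects()
    if not 1 <= block_index:
        raise ValueError("block_index is 1-based")
    second_half = float(trial_index > n_trials // 2)
    eff = condition_effects[condition][modality]
    logit_p = _response_logits(
        profile, modality, eff, block_index,
        np.asarray(is_target), np.asarray(is_lure), np.asarray(second_half),
    )
    responded = bool(rng.uniform() < expit(float(logit_p)))
    if not responded:
        return False, float("nan")
    loc = float(
        _rt_location(profile, modality, eff, block_index, np.asarray(second_half))
    )
    rt = min(trial_duration, math.exp(rng.normal(loc, profile.rt_scale[modality])))
    return True, rt


def _profile_row(profile: SubjectProfile) -> Dict[str, float]:
    row: Dict[str, float] = {}
    for key, value in asdict(profile).items():
        if isinstance(value, dict):
            for m, v in value.items():
                row[f"{key}__{m}"] = v
        else:
            row[key] = value
    return row


def simulate_cohort(
    design: CohortDesign,
    population: Optional[Population] = None,
    seed: int = 0,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the full crossover and return (trial_log, profiles).

    For each subject: a uniform random permutation assigns the conditions
    to time-block positions 1..k, each block gets freshly generated dual
    2-back sequences, and responses follow the subject's profile. Fully
    reproducible from ``seed``: every subject consumes an independent
    substream.

    The trial log has one row per (trial, modality) with columns
    subject_id, time_block, condition, modality, trial (1-based),
    stimulus, is_target, is_lure, responded, rt.
    """
    population = population or Population()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(design.n_subjects)
    width = max(2, len(str(design.n_subjects)))

    log_frames = []
    profile_rows = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        subject_id = f"S{i + 1:0{width}d}"
        profile = sample_profile(population, rng, subject_id)
        profile_rows.append(_profile_row(profile))
        order = list(rng.permutation(design.conditions))
        for block_index in range(1, design.blocks_per_session + 1):
            condition = order[block_index - 1]
            dual = generate_dual_block(
                design.block_specs["visuospatial"],
                design.block_specs["auditory_verbal"],
                rng,
                target_count_vs=design.target_count,
                target_count_av=design.target_count,
            )
            for modality in MODALITIES:
                seq = dual.sequence(modality)
                responded, rt = _simulate_modality_block(
                    profile, condition, design.condition_effects,
                    block_index, seq, rng,
                )
                log_frames.append(
                    pd.DataFrame(
                        {
                            "subject_id": subject_id,
                            "time_block": block_index,
                            "condition": condition,
                            "modality": modality,
                            "trial": np.arange(1, seq.spec.n_trials + 1),
                            "stimulus": seq.stimuli,
                            "is_target": seq.is_target,
                            "is_lure": seq.is_lure,
                            "responded": responded,
                            "rt": np.round(rt, 6),
                        }
                    )
                )
    trial_log = pd.concat(log_frames, ignore_index=True)
    profiles = pd.DataFrame(profile_rows)
    return trial_log, profiles
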