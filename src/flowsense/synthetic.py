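"""Synthetic study generator with known ground truth.

Real wrist-sensor study data of this kind are not public, so this module
generates complete synthetic studies -- physiological session recordings
plus Flow State Scale responses -- from a known generative model, making
every stage of the pipeline testable end to end.

Two designs are built in:

* the five-participant design: 5 participants x 2 activities, each
  activity a 5-minute baseline, six tasks of 1-17 minutes (mean ~6:15),
  and a closing 5-minute baseline; 60 tasks overall with roughly 22/60
  flow prevalence;
* the daily-use design: one participant, 10 single-task sessions of
  10-83 minutes.

Each task draws a latent flow intensity; the ground-truth label
thresholds that intensity at the configured prevalence.  Survey
responses are sampled from the Rating Scale Model at
beta = affine(intensity) with a difficulty hierarchy in which the
transformation of time is the hardest element, so the observed
"full flow" label (transformation of time rated agree+) agrees with the
truth only probabilistically, as with a real instrument.

Flow alters the signals with effect *directions* chosen to mirror the
known physiology: skin temperature drifts upward during flow
(vasodilation), giving a positive median shift and a left-skewed task
distribution; x-axis acceleration gains occasional positive bursts
(right skew); y-axis acceleration switches between two regimes (left
skew, platykurtic); heart rate and electrodermal level are dominated by
person-specific offsets, deliberately leaving little cross-person
signal.  Effect magnitudes are synthetic choices -- the physiology
motivates directions, not raw-signal sizes.

Sampling rates, trim windows and file dialects exactly match the device
conventions, and acceleration is quantised to the 1/64 g grid so writes
and reads roundtrip exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import (Channel, ChannelSeries, DEFAULT_ACC_SCALE, Segment,
                 SessionRecord, write_e4_session)
from .rasch import ITEM_NAMES, rsm_category_probs

__all__ = [
    "FlowEffectSpec",
    "GeneratorConfig",
    "StudyBundle",
    "study2_config",
    "generate_study",
    "generate_channel",
    "generate_fss_responses",
    "write_study",
]


@dataclass(frozen=True)
class FlowEffectSpec:
    """How flow perturbs each channel, plus noise and heterogeneity scales.

    Every segment also receives flow-independent task-to-task variation
    (level wander, a drift of either sign, occasional movement bursts and
    regime switches): physiological state moves between tasks for reasons
    unrelated to flow, and without that overlap any constant flow shift
    would separate the classes perfectly once the task mean averages away
    the sampling noise.  Flow effect magnitudes are additionally scaled
    per task by a lognormal gain (median 1), so effect strength varies
    across tasks as it would across real activities.
    """

    # flow effects.  Flow mostly biases the *direction* of excursions the
    # signals show anyway (drift sign, burst sign, regime side), so the
    # sign-sensitive features (median shift, skewness, kurtosis) carry the
    # signal while magnitude/variance features stay non-systematic.
    temp_median_shift: float = 0.15      # degC added to the drift ceiling
    temp_sign_bias: float = 0.42         # P(upward drift) = 0.5 + bias
    accx_sign_bias: float = 0.40         # P(positive burst) = 0.5 + bias
    accy_side_bias: float = 0.38         # P(low-side regime) = 0.5 + bias
    accy_extra_weight: float = 0.08      # extra regime time share under flow
    accy_regime_offset: float = 0.30     # g separation of the two regimes
    hr_flow_shift: float = 0.5           # bpm, deliberately weak
    eda_flow_shift: float = 0.05         # microsiemens, deliberately weak
    effect_gain_sigma: float = 0.4       # lognormal sigma of per-task gains

    # flow-independent task-to-task variation
    temp_task_sd: float = 0.10           # degC level wander per segment
    temp_drift_sd: float = 0.30          # degC drift amplitude, either sign
    hr_task_sd: float = 2.5              # bpm level wander per segment
    eda_task_sd: float = 0.35            # microsiemens level wander
    acc_task_sd: float = 0.06            # g posture wander per segment
    accx_burst_rate: float = 0.08        # bursts/s present in any task
    accx_burst_scale: float = 0.35       # g, exponential burst amplitude
    accy_base_weight: float = 0.22       # regime time share in any task

    # person-level heterogeneity and measurement noise
    hr_between_person_sd: float = 6.0    # bpm
    eda_between_person_sd: float = 1.0   # microsiemens
    temp_noise: float = 0.06             # degC
    eda_noise: float = 0.05              # microsiemens
    hr_noise: float = 2.5                # bpm
    acc_noise: float = 0.08              # g

    def __post_init__(self):
        for name in ("accy_extra_weight", "accy_base_weight"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("temp_sign_bias", "accx_sign_bias", "accy_side_bias"):
            if not 0.0 <= getattr(self, name) <= 0.5:
                raise ValueError(f"{name} must lie in [0, 0.5]")
        for name in ("temp_noise", "eda_noise", "hr_noise", "acc_noise"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


#: Difficulty hierarchy (logits, mean 0): clear goals easiest, the
#: transformation of time hardest.  Magnitudes are synthetic choices.
DEFAULT_ITEM_DIFFICULTIES = {
    "clear_goals": -1.2,
    "challenge_skill_balance": -0.8,
    "sense_of_control": -0.4,
    "autotelic_experience": -0.3,
    "concentration": 0.0,
    "unambiguous_feedback": 0.1,
    "loss_of_self_consciousness": 0.5,
    "action_awareness_merging": 0.8,
    "transformation_of_time": 1.3,
}

DEFAULT_THRESHOLDS = (-1.8, -0.6, 0.6, 1.8)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study design parameters (defaults = the five-participant design)."""

    n_participants: int = 5
    activities_per_participant: int = 2
    tasks_per_activity: int = 6
    baseline_s: float = 300.0
    task_duration_range: tuple = (60.0, 1020.0)     # 1-17 minutes
    task_duration_mean: float = 375.0               # 6 min 15 s
    flow_prevalence: float = 22.0 / 60.0
    rsm_item_difficulties: dict = field(
        default_factory=lambda: dict(DEFAULT_ITEM_DIFFICULTIES))
    rsm_thresholds: tuple = DEFAULT_THRESHOLDS
    # beta = a + b * (intensity - threshold); the intercept puts the
    # transformation-of-time item at its 50% endorsement point exactly at
    # the truth threshold, so the survey label tracks the truth label
    flow_to_beta: tuple = (1.91, 2.5)
    seed: int = 0

    def __post_init__(self):
        if min(self.n_participants, self.activities_per_participant,
               self.tasks_per_activity) < 1:
            raise ValueError("design counts must be >= 1")
        lo, hi = self.task_duration_range
        if not 0 < lo < hi:
            raise ValueError("task duration range must satisfy 0 < low < high")
        if not lo <= self.task_duration_mean <= hi:
            raise ValueError("mean task duration must lie in the duration range")
        if not 0 < self.flow_prevalence < 1:
            raise ValueError("flow prevalence must lie in (0, 1)")
        if set(self.rsm_item_difficulties) != set(ITEM_NAMES):
            raise ValueError("item difficulties must name exactly the nine flow elements")
        delta = self.rsm_item_difficulties
        if max(delta, key=delta.get) != "transformation_of_time":
            raise ValueError("transformation_of_time must be the hardest element")
        if abs(sum(self.rsm_thresholds)) > 1e-9:
            raise ValueError("rating-scale thresholds must sum to 0")

    @property
    def delta_vector(self) -> np.ndarray:
        return np.array([self.rsm_item_difficulties[name] for name in ITEM_NAMES])


def study2_config(seed: int = 0) -> GeneratorConfig:
    """The daily-use preset: 1 participant, 10 sessions of 10-83 minutes."""
    return GeneratorConfig(
        n_participants=1,
        activities_per_participant=10,
        tasks_per_activity=1,
        task_duration_range=(600.0, 4980.0),
        task_duration_mean=1800.0,
        flow_prevalence=0.6,
        seed=seed,
    )


@dataclass
class StudyBundle:
    """Generated sessions plus the generating truth, keyed per task."""

    sessions: list  # SessionRecord per (participant, activity)
    truth: pd.DataFrame  # participant_id, activity_id, task_id, intensity, ...
    config: GeneratorConfig
    effects: FlowEffectSpec

    def fss_matrix(self) -> pd.DataFrame:
        """N x 9 response matrix keyed by (participant, task)."""
        rows, keys = [], []
        for session in self.sessions:
            for seg in session.task_segments:
                rows.append(list(seg.fss_response))
                keys.append((session.participant_id, seg.task_id))
        return pd.DataFrame(rows, columns=list(ITEM_NAMES),
                            index=pd.MultiIndex.from_tuples(
                                keys, names=["participant_id", "task_id"]))


@dataclass(frozen=True)
class _Person:
    hr_level: float
    eda_level: float
    temp_level: float
    acc_mean: np.ndarray  # posture offset per axis, g


def _sample_person(effects: FlowEffectSpec, rng: np.random.Generator) -> _Person:
    return _Person(
        hr_level=70.0 + effects.hr_between_person_sd * rng.standard_normal(),
        eda_level=max(2.0 + effects.eda_between_person_sd * rng.standard_normal(), 0.3),
        temp_level=33.0 + 0.4 * rng.standard_normal(),
        acc_mean=np.array([0.05, -0.05, 0.98]) + 0.05 * rng.standard_normal(3),
    )


def _smooth(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return x
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="same")


def _quantize_acc(values: np.ndarray) -> np.ndarray:
    return np.rint(values / DEFAULT_ACC_SCALE) * DEFAULT_ACC_SCALE


def generate_channel(channel: Channel, duration_s: float, flow: int,
                     intensity: float, effects: FlowEffectSpec,
                     person: _Person, rng: np.random.Generator,
                     start_time: float = 0.0) -> ChannelSeries:
    """Synthesize one channel for one segment (task or baseline condition).

    ``flow=0`` with ``intensity=0`` gives the stationary baseline
    condition around the person's offsets; ``flow=1`` adds the
    flow-dependent distortions described in the module docstring.
    """
    channel = Channel(channel)
    rate = {Channel.HR: 1.0, Channel.TEMP: 4.0, Channel.EDA: 4.0, Channel.ACC: 32.0}[channel]
    n = int(round(duration_s * rate))
    if n < 2:
        raise ValueError(f"duration {duration_s}s too short for {channel.value}")
    t = np.arange(n) / rate
    gain = float(rng.lognormal(0.0, effects.effect_gain_sigma)) if flow else 0.0

    if channel is Channel.HR:
        # the device reports a 10 s trailing moving average, so smooth
        noise = _smooth(rng.standard_normal(n + 10), 10)[:n] * effects.hr_noise
        level = person.hr_level + effects.hr_task_sd * rng.standard_normal()
        values = level + noise + gain * effects.hr_flow_shift
    elif channel is Channel.TEMP:
        noise = _smooth(rng.standard_normal(n), 8) * effects.temp_noise
        level = person.temp_level + effects.temp_task_sd * rng.standard_normal()
        # every segment drifts, in either direction; flow biases the drift
        # upward (vasodilation), leaving the task distribution shifted at
        # the median and left-skewed near its ceiling
        magnitude = abs(effects.temp_drift_sd * rng.standard_normal())
        p_up = 0.5 + min(gain, 1.0) * effects.temp_sign_bias
        sign = 1.0 if rng.random() < p_up else -1.0
        drift_amp = sign * (magnitude + gain * effects.temp_median_shift)
        tau = max(duration_s / 6.0, 1.0)
        values = level + noise + drift_amp * (1.0 - np.exp(-t / tau))
    elif channel is Channel.EDA:
        noise = _smooth(rng.standard_normal(n), 16) * effects.eda_noise
        level = person.eda_level + effects.eda_task_sd * rng.standard_normal()
        drift = 0.02 * np.sin(2 * np.pi * t / max(duration_s, 1.0))
        values = np.maximum(level + noise + drift + gain * effects.eda_flow_shift,
                            0.01)
    elif channel is Channel.ACC:
        mean = person.acc_mean + effects.acc_task_sd * rng.standard_normal(3)
        # overall movement intensity swings from task to task for reasons
        # unrelated to flow, so variance-type features stay non-systematic
        movement = rng.lognormal(0.0, 0.5)
        values = mean[None, :] + movement * effects.acc_noise * rng.standard_normal((n, 3))

        g = min(gain, 1.0)
        # x: occasional movement bursts in any segment; flow biases their
        # direction positive -> right skew with no extra variance
        p_pos = 0.5 + g * effects.accx_sign_bias
        n_bursts = rng.poisson(movement * effects.accx_burst_rate * duration_s)
        for _ in range(n_bursts):
            at = rng.integers(0, n)
            width = int(rng.integers(rate // 4 + 1, 2 * rate))
            amp = rng.exponential(effects.accx_burst_scale)
            if rng.random() >= p_pos:
                amp = -amp
            values[at:min(at + width, n), 0] += amp
        # y: ~2 s regime excursions to either side in any segment; flow
        # biases them to the low side and adds a little regime time ->
        # left skew and a flatter (platykurtic) distribution
        weight = min(effects.accy_base_weight * rng.lognormal(0.0, 0.4)
                     + gain * effects.accy_extra_weight, 0.5)
        p_low = 0.5 + g * effects.accy_side_bias
        block = int(2 * rate)
        n_blocks = n // block + 1
        in_regime = rng.random(n_blocks) < weight
        side = np.where(rng.random(n_blocks) < p_low, -1.0, 1.0)
        offsets = np.repeat(in_regime * side * effects.accy_regime_offset,
                            block)[:n]
        values[:, 1] += offsets
        values = _quantize_acc(values)
    else:  # pragma: no cover
        raise ValueError(channel)
    return ChannelSeries(channel=channel, start_time=start_time, rate=rate,
                         values=values)


def generate_fss_responses(beta: float, delta, tau,
                           rng: np.random.Generator) -> np.ndarray:
    """Sample the nine item ratings from the Rating Scale Model."""
    delta = np.asarray(delta, dtype=float)
    tau = np.asarray(tau, dtype=float)
    if abs(tau.sum()) > 1e-9:
        raise ValueError("thresholds must sum to 0")
    probs = rsm_category_probs(np.array([beta]), delta, tau)[0]  # (I, M+1)
    cum = probs.cumsum(axis=1)
    u = rng.random(delta.size)
    return (u[:, None] > cum).sum(axis=1).astype(int)


def _concat_series(channel: Channel, parts: list, start_time: float) -> ChannelSeries:
    values = np.concatenate([p.values for p in parts], axis=0)
    return ChannelSeries(channel=channel, start_time=start_time,
                         rate=parts[0].rate, values=values)


def generate_study(config: Optional[GeneratorConfig] = None,
                   effects: Optional[FlowEffectSpec] = None,
                   seed: Optional[int] = None) -> StudyBundle:
    """Generate a complete study bundle, deterministic given the seed.

    Each (participant, activity) pair becomes one session: baseline,
    tasks, baseline, contiguous in time.  The truth table records each
    task's latent intensity, true label and survey measure beta.
    """
    config = config or GeneratorConfig()
    effects = effects or FlowEffectSpec()
    seed = config.seed if seed is None else seed
    root = np.random.default_rng(seed)

    lo, hi = config.task_duration_range
    span = hi - lo
    mean_frac = (config.task_duration_mean - lo) / span
    # Beta(a, b) on the duration range with the configured mean; a = 2
    # keeps a realistic right-skewed spread of task lengths
    a = 2.0
    b = a * (1.0 - mean_frac) / mean_frac
    flow_cut = float(sps.norm.ppf(1.0 - config.flow_prevalence))

    delta = config.delta_vector
    tau = np.asarray(config.rsm_thresholds)
    beta_a, beta_b = config.flow_to_beta

    sessions = []
    truth_rows = []
    session_epoch = 1_600_000_000.0
    for p in range(config.n_participants):
        pid = f"P{p + 1:02d}"
        person = _sample_person(effects, np.random.default_rng(root.integers(2**31)))
        for act in range(config.activities_per_participant):
            aid = f"A{act + 1:02d}"
            rng = np.random.default_rng(root.integers(2**31))
            segments = []
            parts = {c: [] for c in Channel}
            offset = 0.0

            def add_segment(kind, task_id, duration, flow, intensity, fss):
                nonlocal offset
                for channel in Channel:
                    parts[channel].append(
                        generate_channel(channel, duration, flow, intensity,
                                         effects, person, rng)
                    )
                segments.append(Segment(
                    kind=kind, task_id=task_id, start_offset=offset,
                    end_offset=offset + duration, fss_response=fss,
                ))
                offset += duration

            add_segment("baseline", "", config.baseline_s, 0, 0.0, None)
            for k in range(config.tasks_per_activity):
                tid = f"{aid}-T{k + 1}"
                duration = float(np.round(lo + span * rng.beta(a, b)))
                intensity = float(rng.standard_normal())
                flow = int(intensity > flow_cut)
                beta = beta_a + beta_b * (intensity - flow_cut)
                fss = tuple(generate_fss_responses(beta, delta, tau, rng))
                add_segment("task", tid, duration, flow, intensity, fss)
                truth_rows.append({
                    "participant_id": pid, "activity_id": aid, "task_id": tid,
                    "duration_s": duration, "intensity": intensity,
                    "flow_true": flow, "beta": beta,
                })
            add_segment("baseline", "", config.baseline_s, 0, 0.0, None)

            channels = {c: _concat_series(c, parts[c], session_epoch)
                        for c in Channel}
            sessions.append(SessionRecord(
                participant_id=pid, activity_id=aid,
                channels=channels, segments=segments,
            ))
            session_epoch += offset + 3600.0

    truth = pd.DataFrame(truth_rows)
    return StudyBundle(sessions=sessions, truth=truth, config=config,
                       effects=effects)


def write_study(bundle: StudyBundle, directory) -> Path:
    """Write a bundle to disk: one session directory per (participant,
    activity) plus the ground truth as JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for session in bundle.sessions:
        write_e4_session(
            session, directory / f"{session.participant_id}_{session.activity_id}"
        )
    truth_path = directory / "truth.json"
    truth_path.write_text(json.dumps({
        "seed": bundle.config.seed,
        "tasks": bundle.truth.to_dict(orient="records"),
    }, indent=1))
    return directory
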