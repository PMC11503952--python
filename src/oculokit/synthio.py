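"""Synthetic oculomotor cohort generator.

Emulates the data produced by a gap-paradigm prosaccade/antisaccade battery
plus a resting pupillometry recording, for a placebo-controlled crossover
study: a patient group tested twice (drug and placebo, block-randomized
visit order) and a control group tested once.  Every latent parameter is
recorded in a ground-truth table so downstream estimators can be checked by
parameter recovery.

The generative model, per subject:

* main sequence: peak velocity = V_true * sqrt(amplitude), with
  multiplicative Gaussian velocity noise (coefficient of variation
  ``velocity_noise_cv``);
* amplitude: gain * |target eccentricity| * (1 + noise) — gain < 1 models
  hypometric undershoot;
* latency: shifted lognormal (shift ``latency_shift_ms``), the shift acting
  as an absolute physiological floor;
* antisaccade errors: Bernoulli with logit = error_propensity
  - urgency_coupling * z(latency) (+ drug shift), so fast responses are
  more likely to be reflexive errors toward the target;
* velocity trace: raised-cosine profile whose peak equals the drawn peak
  velocity and whose time integral equals the drawn amplitude;
* pupil: baseline + slow sinusoidal drift + white noise, interrupted by
  Poisson blinks of 50-200 ms flagged invalid.

Determinism: one global integer seed; per-subject substreams derived by
CRC-32 hashing of the subject id so adding subjects never reshuffles the
draws of existing ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "DrugEffect",
    "GeneratorConfig",
    "SubjectParams",
    "PupilTrace",
    "SimulatedSession",
    "Cohort",
    "gen_subject_params",
    "gen_prosaccade_trials",
    "gen_antisaccade_trials",
    "gen_pupil_trace",
    "gen_cohort",
    "write_cohort",
]

Group = Literal["patient", "control"]
Condition = Literal["atomoxetine", "placebo", "control"]

#: raised-cosine identity: a profile with peak v and integral A lasts 2A/v.
RAISED_COSINE_DURATION_FACTOR = 2.0


@dataclass(frozen=True)
class DrugEffect:
    """Additive condition offsets applied on the active-drug session."""

    latency_shift_ms: float = -15.0
    v_shift: float = -10.0
    error_logit_shift: float = 0.6
    pupil_shift_au: float = 100.0


@dataclass(frozen=True)
class GeneratorConfig:
    """Task design constants and population distributions of the cohort.

    The task constants (trial counts, eccentricities, fixation and gap
    durations, sampling rate) reproduce the study design; population
    parameters are plausible for mild-moderate parkinsonian and older
    control oculomotor data and are the single place to change them.
    """

    n_patients: int = 19
    n_controls: int = 25
    trials_per_task: int = 24
    eccentricities: tuple[float, ...] = (-7.0, -5.0, -3.0, 3.0, 5.0, 7.0)
    fixation_duration_range: tuple[float, float] = (800.0, 1200.0)
    gap_duration: float = 200.0
    sampling_rate: float = 500.0

    # main-sequence coefficient V, deg/s per sqrt(deg)
    V_group_mean: float = 130.0
    V_group_sd: float = 13.0
    patient_v_offset: float = 10.0  # placebo-state elevation over controls

    # shifted-lognormal latency model (ms); between-subject spread on mu
    latency_mean_log: float = 4.70
    latency_sd_log: float = 0.35
    latency_shift: float = 90.0
    latency_between_sd_log: float = 0.15

    # saccade metrics
    amplitude_gain_mean: float = 0.9
    gain_sd: float = 0.05
    amplitude_noise_cv: float = 0.05
    velocity_noise_cv: float = 0.10
    start_position_sd: float = 0.3

    # antisaccade error model (logit units)
    error_propensity_mean: float = -1.5
    error_propensity_sd: float = 0.5
    urgency_coupling: float = 1.0

    # resting pupil model (arbitrary units)
    pupil_baseline_mean: float = 1500.0
    pupil_baseline_sd: float = 150.0
    pupil_noise_sd: float = 10.0
    pupil_drift_amplitude: float = 30.0
    pupil_drift_freq_hz: float = 0.05
    blink_rate: float = 15.0  # blinks per minute
    blink_duration_range_ms: tuple[float, float] = (50.0, 200.0)

    profile_samples: int = 51
    drug_effect: DrugEffect = field(default_factory=DrugEffect)
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_patients, self.n_controls, self.trials_per_task) <= 0:
            raise ValueError("counts must be positive")
        ecc = sorted(self.eccentricities)
        if sorted(-e for e in self.eccentricities) != ecc:
            raise ValueError("eccentricity set must be symmetric about 0")
        lo, hi = self.fixation_duration_range
        if not lo < hi:
            raise ValueError("fixation_duration_range must be (low, high) with low < high")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.trials_per_task % len(self.eccentricities) != 0:
            raise ValueError(
                f"trials_per_task={self.trials_per_task} not divisible by "
                f"{len(self.eccentricities)} eccentricities"
            )
        if self.urgency_coupling < 0:
            raise ValueError("urgency_coupling must be >= 0")


@dataclass(frozen=True)
class SubjectParams:
    """Latent per-subject parameters (the ground truth of the simulation)."""

    subject_id: str
    group: Group
    V_true: float
    latency_mu_log: float
    latency_sd_log: float
    gain: float
    error_propensity: float
    pupil_baseline: float

    def __post_init__(self) -> None:
        if self.V_true <= 0 or self.gain <= 0:
            raise ValueError("V_true and gain must be positive")


@dataclass
class PupilTrace:
    """Uniformly sampled pupil diameter trace with a validity mask."""

    time: np.ndarray  # ms
    diameter: np.ndarray  # arbitrary units
    valid: np.ndarray  # bool
    sampling_rate: float

    def __post_init__(self) -> None:
        if not (len(self.time) == len(self.diameter) == len(self.valid)):
            raise ValueError("time, diameter and valid must have equal length")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")


@dataclass
class SimulatedSession:
    subject_id: str
    group: Group
    condition: Condition
    visit_order: int | None  # 1 or 2 for patients, None for controls
    trials: pd.DataFrame  # one row per trial, saccade event columns inlined
    profiles: pd.DataFrame  # long-format velocity samples (prosaccades)
    pupil: PupilTrace


@dataclass
class Cohort:
    sessions: list[SimulatedSession]
    truth: pd.DataFrame
    config: GeneratorConfig


def _subject_rng(seed: int, subject_id: str, stream: str = "") -> np.random.Generator:
    """Deterministic substream keyed by subject id (and optional stream tag)."""
    key = zlib.crc32(f"{subject_id}/{stream}".encode())
    return np.random.default_rng(np.random.SeedSequence([seed, key]))


def gen_subject_params(
    config: GeneratorConfig, group: Group, rng: np.random.Generator, subject_id: str
) -> SubjectParams:
    config.validate()
    if group not in ("patient", "control"):
        raise ValueError(f"unknown group label {group!r}")
    v_mean = config.V_group_mean + (config.patient_v_offset if group == "patient" else 0.0)
    V_true = max(float(rng.normal(v_mean, config.V_group_sd)), 1e-6)
    gain = max(float(rng.normal(config.amplitude_gain_mean, config.gain_sd)), 1e-6)
    mu = float(rng.normal(config.latency_mean_log, config.latency_between_sd_log))
    prop = float(rng.normal(config.error_propensity_mean, config.error_propensity_sd))
    baseline = float(rng.normal(config.pupil_baseline_mean, config.pupil_baseline_sd))
    return SubjectParams(
        subject_id=subject_id,
        group=group,
        V_true=V_true,
        latency_mu_log=mu,
        latency_sd_log=config.latency_sd_log,
        gain=gain,
        error_propensity=prop,
        pupil_baseline=baseline,
    )


def _draw_latencies(
    subject: SubjectParams, config: GeneratorConfig, condition: Condition, n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    lat = config.latency_shift + rng.lognormal(subject.latency_mu_log, subject.latency_sd_log, n)
    if condition == "atomoxetine":
        lat = lat + config.drug_effect.latency_shift_ms
    return lat


def _effective_v(subject: SubjectParams, config: GeneratorConfig, condition: Condition) -> float:
    v = subject.V_true
    if condition == "atomoxetine":
        v = v + config.drug_effect.v_shift
    return max(v, 1e-6)


def _trial_frame(
    subject: SubjectParams,
    config: GeneratorConfig,
    condition: Condition,
    task: str,
    rng: np.random.Generator,
) -> pd.DataFrame:
    n = config.trials_per_task
    reps = n // len(config.eccentricities)
    ecc = np.repeat(np.asarray(config.eccentricities, dtype=float), reps)
    rng.shuffle(ecc)
    lo, hi = config.fixation_duration_range
    fixation = rng.uniform(lo, hi, n)
    return pd.DataFrame(
        {
            "subject_id": subject.subject_id,
            "group": subject.group,
            "condition": condition,
            "task": task,
            "trial_index": np.arange(n),
            "fixation_duration_ms": fixation,
            "target_onset_ms": fixation + config.gap_duration,
            "target_eccentricity_deg": ecc,
            "target_side": np.where(ecc > 0, "right", "left"),
        }
    )


def _saccade_kinematics(
    trials: pd.DataFrame,
    subject: SubjectParams,
    config: GeneratorConfig,
    v_eff: float,
    direction_sign: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    n = len(trials)
    ecc = trials["target_eccentricity_deg"].to_numpy()
    amp = subject.gain * np.abs(ecc) * (1.0 + rng.normal(0.0, config.amplitude_noise_cv, n))
    amp = np.maximum(amp, 1e-6)
    vpeak = v_eff * np.sqrt(amp) * (1.0 + rng.normal(0.0, config.velocity_noise_cv, n))
    vpeak = np.maximum(vpeak, 1e-6)
    # duration from the raised-cosine identity: integral(v) = vpeak*T/2 = amp
    dur_ms = 1000.0 * RAISED_COSINE_DURATION_FACTOR * amp / vpeak
    start_x = rng.normal(0.0, config.start_position_sd, n)
    out = trials.copy()
    out["amplitude_deg"] = amp
    out["peak_velocity_deg_s"] = vpeak
    out["sacc_duration_ms"] = dur_ms
    out["start_x_deg"] = start_x
    out["end_x_deg"] = start_x + direction_sign * amp
    return out


def _profiles_frame(trials: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """Raised-cosine velocity samples on a normalized time grid, long format."""
    t = np.linspace(0.0, 1.0, config.profile_samples)
    shape = 0.5 * (1.0 - np.cos(2.0 * np.pi * t))
    n, m = len(trials), len(t)
    return pd.DataFrame(
        {
            "subject_id": np.repeat(trials["subject_id"].to_numpy(), m),
            "condition": np.repeat(trials["condition"].to_numpy(), m),
            "task": np.repeat(trials["task"].to_numpy(), m),
            "trial_index": np.repeat(trials["trial_index"].to_numpy(), m),
            "t_norm": np.tile(t, n),
            "velocity_deg_s": np.outer(trials["peak_velocity_deg_s"].to_numpy(), shape).ravel(),
            "sacc_duration_ms": np.repeat(trials["sacc_duration_ms"].to_numpy(), m),
        }
    )


def gen_prosaccade_trials(
    subject: SubjectParams,
    config: GeneratorConfig,
    condition: Condition,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One block of prosaccade trials plus their velocity-sample profiles.

    Returns ``(trials, profiles)``; each trial carries exactly one saccade
    event (the response), directed at the target.
    """
    config.validate()
    trials = _trial_frame(subject, config, condition, "prosaccade", rng)
    trials["latency_ms"] = _draw_latencies(subject, config, condition, len(trials), rng)
    direction = np.sign(trials["target_eccentricity_deg"].to_numpy())
    trials = _saccade_kinematics(
        trials, subject, config, _effective_v(subject, config, condition), direction, rng
    )
    trials["sacc_onset_ms"] = trials["target_onset_ms"] + trials["latency_ms"]
    trials["is_error"] = False
    return trials, _profiles_frame(trials, config)


def gen_antisaccade_trials(
    subject: SubjectParams,
    config: GeneratorConfig,
    condition: Condition,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """One block of antisaccade trials with latency-coupled direction errors.

    The error probability is a logistic function of the subject's propensity
    minus ``urgency_coupling`` times the standardized (log-scale) latency,
    so reflexive, fast responses are the ones that go toward the target.
    """
    config.validate()
    trials = _trial_frame(subject, config, condition, "antisaccade", rng)
    n = len(trials)
    lat = _draw_latencies(subject, config, condition, n, rng)
    trials["latency_ms"] = lat
    # standardize on the log scale of the subject's own latency distribution
    drug_lat = config.drug_effect.latency_shift_ms if condition == "atomoxetine" else 0.0
    core = np.maximum(lat - config.latency_shift - drug_lat, 1e-9)
    z = (np.log(core) - subject.latency_mu_log) / subject.latency_sd_log
    logit = subject.error_propensity - config.urgency_coupling * z
    if condition == "atomoxetine":
        logit = logit + config.drug_effect.error_logit_shift
    p_err = 1.0 / (1.0 + np.exp(-logit))
    is_error = rng.random(n) < p_err
    target_sign = np.sign(trials["target_eccentricity_deg"].to_numpy())
    direction = np.where(is_error, target_sign, -target_sign)
    trials = _saccade_kinematics(
        trials, subject, config, _effective_v(subject, config, condition), direction, rng
    )
    trials["sacc_onset_ms"] = trials["target_onset_ms"] + trials["latency_ms"]
    trials["is_error"] = is_error
    return trials


def gen_pupil_trace(
    subject: SubjectParams,
    config: GeneratorConfig,
    condition: Condition,
    rng: np.random.Generator,
    duration: float = 180.0,
) -> PupilTrace:
    """Resting pupil trace: baseline + slow drift + noise, with blinks.

    Blink count is Poisson at ``blink_rate`` per minute; each blink is an
    invalid run of 50-200 ms during which the recorded diameter drops to 0,
    as pupil trackers report when the pupil is lost.
    """
    config.validate()
    if duration <= 0:
        raise ValueError("duration must be positive")
    fs = config.sampling_rate
    n = int(round(duration * fs))
    t_s = np.arange(n) / fs
    shift = config.drug_effect.pupil_shift_au if condition == "atomoxetine" else 0.0
    phase = rng.uniform(0.0, 2.0 * np.pi)
    diam = (
        subject.pupil_baseline
        + shift
        + config.pupil_drift_amplitude * np.sin(2.0 * np.pi * config.pupil_drift_freq_hz * t_s + phase)
        + rng.normal(0.0, config.pupil_noise_sd, n)
    )
    valid = np.ones(n, dtype=bool)
    n_blinks = rng.poisson(config.blink_rate * duration / 60.0)
    lo, hi = config.blink_duration_range_ms
    for _ in range(n_blinks):
        start = int(rng.uniform(0, n))
        length = int(round(rng.uniform(lo, hi) * fs / 1000.0))
        stop = min(start + length, n)
        valid[start:stop] = False
    diam[~valid] = 0.0
    return PupilTrace(time=t_s * 1000.0, diameter=diam, valid=valid, sampling_rate=fs)


def _session(
    subject: SubjectParams,
    config: GeneratorConfig,
    condition: Condition,
    visit_order: int | None,
    pupil_duration: float,
) -> SimulatedSession:
    rng = _subject_rng(config.seed, subject.subject_id, f"session/{condition}")
    pro, profiles = gen_prosaccade_trials(subject, config, condition, rng)
    anti = gen_antisaccade_trials(subject, config, condition, rng)
    pupil = gen_pupil_trace(subject, config, condition, rng, duration=pupil_duration)
    trials = pd.concat([pro, anti], ignore_index=True)
    trials.insert(4, "visit_order", visit_order if visit_order is not None else 0)
    profiles = profiles.copy()
    return SimulatedSession(
        subject_id=subject.subject_id,
        group=subject.group,
        condition=condition,
        visit_order=visit_order,
        trials=trials,
        profiles=profiles,
        pupil=pupil,
    )


def gen_cohort(config: GeneratorConfig, pupil_duration: float = 180.0) -> Cohort:
    """Full crossover cohort: patients twice (block-randomized order),
    controls once, plus the ground-truth parameter table."""
    config.validate()
    sessions: list[SimulatedSession] = []
    truth_rows = []

    order_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x0BDE7]))
    n_first = config.n_patients // 2 + config.n_patients % 2
    atx_first = np.array([True] * n_first + [False] * (config.n_patients - n_first))
    order_rng.shuffle(atx_first)

    for i in range(config.n_patients):
        sid = f"pd{i + 1:02d}"
        subj = gen_subject_params(config, "patient", _subject_rng(config.seed, sid, "params"), sid)
        conds: list[Condition] = (
            ["atomoxetine", "placebo"] if atx_first[i] else ["placebo", "atomoxetine"]
        )
        for visit, cond in enumerate(conds, start=1):
            sessions.append(_session(subj, config, cond, visit, pupil_duration))
        truth_rows.append(_truth_row(subj, conds[0]))

    for i in range(config.n_controls):
        sid = f"hc{i + 1:02d}"
        subj = gen_subject_params(config, "control", _subject_rng(config.seed, sid, "params"), sid)
        sessions.append(_session(subj, config, "control", None, pupil_duration))
        truth_rows.append(_truth_row(subj, None))

    truth = pd.DataFrame(truth_rows)
    return Cohort(sessions=sessions, truth=truth, config=config)


def _truth_row(subj: SubjectParams, first_condition: str | None) -> dict:
    return {
        "subject_id": subj.subject_id,
        "group": subj.group,
        "V_true": subj.V_true,
        "gain": subj.gain,
        "latency_mu_log": subj.latency_mu_log,
        "latency_sd_log": subj.latency_sd_log,
        "error_propensity": subj.error_propensity,
        "pupil_baseline": subj.pupil_baseline,
        "first_condition": first_condition if first_condition is not None else "",
    }


EVENT_COLUMNS = [
    "subject_id", "group", "condition", "visit_order", "task", "trial_index",
    "target_onset_ms", "target_side", "target_eccentricity_deg",
    "sacc_onset_ms", "sacc_duration_ms", "amplitude_deg",
    "peak_velocity_deg_s", "start_x_deg", "end_x_deg",
]

TRIAL_COLUMNS = [
    "subject_id", "group", "condition", "visit_order", "task", "trial_index",
    "target_side", "target_eccentricity_deg", "fixation_duration_ms",
    "target_onset_ms",
]


def cohort_events(cohort: Cohort) -> pd.DataFrame:
    """All saccade events of the cohort, one row per event."""
    return pd.concat([s.trials for s in cohort.sessions], ignore_index=True)[EVENT_COLUMNS]


def cohort_trials(cohort: Cohort) -> pd.DataFrame:
    return pd.concat([s.trials for s in cohort.sessions], ignore_index=True)[TRIAL_COLUMNS]


def cohort_profiles(cohort: Cohort) -> pd.DataFrame:
    return pd.concat([s.profiles for s in cohort.sessions], ignore_index=True)


def write_cohort(cohort: Cohort, out_dir: str | Path, write_pupil: bool = True) -> None:
    """Serialize a cohort to plain-text tables (TSV; pupil traces as CSV)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fmt = "%.6g"
    cohort_events(cohort).to_csv(out / "events.tsv", sep="\t", index=False, float_format=fmt)
    cohort_trials(cohort).to_csv(out / "trials.tsv", sep="\t", index=False, float_format=fmt)
    cohort_profiles(cohort).to_csv(
        out / "velocity_samples.tsv", sep="\t", index=False, float_format=fmt
    )
    cohort.truth.to_csv(out / "truth.tsv", sep="\t", index=False, float_format=fmt)
    if write_pupil:
        frames = []
        for s in cohort.sessions:
            frames.append(
                pd.DataFrame(
                    {
                        "subject_id": s.subject_id,
                        "condition": s.condition,
                        "time_ms": s.pupil.time,
                        "pupil_au": s.pupil.diameter,
                        "valid": s.pupil.valid.astype(int),
                    }
                )
            )
        pd.concat(frames, ignore_index=True).to_csv(out / "pupil.csv", index=False, float_format=fmt)
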