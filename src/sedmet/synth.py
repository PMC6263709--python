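"""Synthetic office-work study sessions.

No recordings from the original calibration protocol are publicly deposited,
so this module generates complete sessions with the statistical structure the
classifiers assume: 25 participants, a randomized block of 5-minute office
tasks (four desk tasks performed sitting and standing, plus walking; four of
the nine are mandatory and appear within the first six blocks), and a 10-min
supine lying block for the resting-metabolic-rate reference.

Per posture the thigh accelerometer behaves as:

* sitting/lying — quasi-static orientation with the thigh well past the
  39-deg sitting threshold (y ~ -cos(angle), quiet standing reads -1 g);
* standing — y near -1 g with small sway;
* walking — an oscillation at the participant's gait frequency whose
  per-step acceleration/deceleration drives the minute's 5th/95th
  percentiles out of the quiet-standing band.

EMG activity is a Poisson process of Gaussian-enveloped bursts whose rate
and amplitude both grow monotonically with the task MET excess over rest,
weighted per channel by the task's dominant muscles and scaled by
participant-specific gains (surface-EMG amplitude varies strongly between
people, which is why absolute-amplitude EMG features are avoided
downstream).  The calorimeter trace is rmr x MET multiplier plus noise, with
an exponential settling transient at the start of the lying block.

Everything is driven by one seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from . import io as sio
from .calorimetry import met_category
from .io import (
    ACCEL_AXES,
    DESK_TASKS,
    EMG_CHANNELS,
    AccelRecording,
    CalorimeterTrace,
    EMGRecording,
    TaskAnnotation,
)

MANDATORY_TASKS = (("typing", "sitting"), ("typing", "standing"),
                   ("video", "sitting"), ("walking", "walking"))

#: Median (IQR) MET per task, the distribution the generator is calibrated
#: to; one MET value is drawn per participant-task and shared by all its
#: minutes.
TASK_MET_TABLE: dict[tuple[str, str], tuple[float, float]] = {
    ("video", "sitting"): (1.09, 0.22),
    ("video", "standing"): (1.13, 0.20),
    ("mouse", "sitting"): (1.23, 0.23),
    ("mouse", "standing"): (1.29, 0.22),
    ("typing", "sitting"): (1.24, 0.26),
    ("typing", "standing"): (1.24, 0.23),
    ("deskwork", "sitting"): (1.46, 0.24),
    ("deskwork", "standing"): (1.47, 0.39),
    ("walking", "walking"): (2.87, 0.74),
}

#: Relative burst weight per electrode site for each task; bilateral, with
#: the mouse task lateralized to the right forearm.  Weight vectors are
#: normalized so every task distributes the same total activity across the
#: 8 channels — the MET excess, not the task identity, sets overall volume.
_SITE_WEIGHTS: dict[str, dict[str, float]] = {
    "video": {"forearm": 0.2, "upper_arm": 0.2, "shoulder": 0.2, "lower_back": 0.4},
    "mouse": {"forearm": 1.0, "upper_arm": 0.4, "shoulder": 0.3, "lower_back": 0.2},
    "typing": {"forearm": 1.0, "upper_arm": 0.4, "shoulder": 0.3, "lower_back": 0.2},
    "deskwork": {"forearm": 0.6, "upper_arm": 0.6, "shoulder": 0.5, "lower_back": 0.5},
    "walking": {"forearm": 0.2, "upper_arm": 0.3, "shoulder": 0.3, "lower_back": 1.0},
    "lying": {"forearm": 0.0, "upper_arm": 0.0, "shoulder": 0.0, "lower_back": 0.0},
}

_TOTAL_CHANNEL_WEIGHT = 3.0


@dataclass(frozen=True)
class TaskModel:
    """Statistical description of one task: MET law + channel weighting."""

    task: str
    posture: str
    met_median: float
    met_iqr: float
    channel_weights: dict[str, float]

    def __post_init__(self):
        if self.met_median < 1:
            raise ValueError("task MET median must be >= 1")


def default_task_models() -> dict[tuple[str, str], TaskModel]:
    models = {}
    for (task, posture), (median, iqr) in TASK_MET_TABLE.items():
        sites = _SITE_WEIGHTS[task]
        raw = {}
        for ch in EMG_CHANNELS:
            side, site = ch.split("_", 1)
            w = sites[site]
            if task == "mouse" and site == "forearm" and side == "left":
                w *= 0.15
            if posture == "standing" and site == "lower_back":
                w += 0.3
            raw[ch] = w
        total = sum(raw.values())
        weights = {ch: _TOTAL_CHANNEL_WEIGHT * w / total for ch, w in raw.items()}
        models[(task, posture)] = TaskModel(task, posture, median, iqr, weights)
    return models


@dataclass(frozen=True)
class ParticipantProfile:
    """Per-person latent parameters: RMR, per-channel EMG gain, gait rate."""

    participant_id: str
    rmr: float  # kcal/min
    gains: tuple[float, ...]  # one multiplicative amplitude gain per channel
    gait_freq: float  # Hz

    def __post_init__(self):
        if self.rmr <= 0:
            raise ValueError("rmr must be > 0")
        if any(g <= 0 for g in self.gains) or len(self.gains) != len(EMG_CHANNELS):
            raise ValueError("need 8 positive channel gains")


@dataclass
class GeneratorConfig:
    """All knobs of the study generator; ``seed`` fixes the full dataset.

    Orientation parameters implement the posture geometry (sitting thigh
    angle well past 39 deg from vertical, standing near 0 deg, walking
    oscillation at gait frequency); burst parameters set how strongly EMG
    activity encodes the MET excess over rest.  ``noise_preset='hard'``
    degrades the posture separation and the EMG signal-to-noise ratio so
    that the fixed posture tree no longer classifies perfectly.
    """

    seed: int = 0
    n_participants: int = 25
    n_tasks: int = 7  # 5-min task blocks per session (45-min budget incl. lying)
    task_duration: float = 300.0
    lying_duration: float = 600.0
    emg_rate: float = 30.0
    accel_rate: float = 30.0
    calorimeter_rate: float = 0.1
    raw_emg_rate: float = 1000.0
    # accelerometer / posture geometry (degrees, g)
    accel_noise: float = 0.02
    sitting_angle_mean: float = 75.0
    sitting_angle_sd: float = 8.0
    sitting_angle_min: float = 55.0
    sitting_angle_max: float = 100.0
    lying_angle_mean: float = 90.0
    lying_angle_sd: float = 3.0
    standing_sway: float = 0.02
    walking_amplitude: float = 0.8
    gait_freq_mean: float = 1.8
    gait_freq_sd: float = 0.15
    # EMG burst model
    emg_baseline: float = 0.05
    burst_rate_per_met: float = 2.0  # bursts/s per MET excess per unit weight
    burst_amp_per_met: float = 0.8
    burst_width_s: float = 0.15
    gain_sigma: float = 0.4  # lognormal sd of per-channel participant gains
    # calorimetry
    rmr_mean: float = 1.4  # kcal/min (~2000 kcal/day)
    rmr_sd: float = 0.2
    calorimeter_noise_frac: float = 0.03
    lying_settle_amp: float = 0.3
    lying_settle_tau: float = 60.0
    noise_preset: str = "default"

    def __post_init__(self):
        if self.noise_preset not in ("default", "hard"):
            raise ValueError("noise_preset must be 'default' or 'hard'")


def hard_preset(config: GeneratorConfig | None = None) -> GeneratorConfig:
    """A deliberately difficult variant: postures overlap and EMG is noisy.

    Guards test suites against trivially separable synthetic data — the
    fixed posture tree must *not* reach 100% accuracy here.
    """
    base = config or GeneratorConfig()
    return replace(
        base,
        accel_noise=0.25,
        sitting_angle_mean=48.0,
        sitting_angle_sd=12.0,
        sitting_angle_min=28.0,
        walking_amplitude=0.35,
        emg_baseline=0.4,
        burst_rate_per_met=0.6,
        noise_preset="hard",
    )


# ---------------------------------------------------------------------------
# Accelerometer


def simulate_accel(posture: str, duration: float, profile: ParticipantProfile,
                   config: GeneratorConfig, rng: np.random.Generator) -> AccelRecording:
    """One task block of 3-axis thigh accelerometer data for a posture."""
    n = int(round(duration * config.accel_rate))
    t = np.arange(n) / config.accel_rate
    noise = lambda: rng.normal(0.0, config.accel_noise, size=n)  # noqa: E731
    if posture in ("sitting", "lying"):
        if posture == "sitting":
            angle = np.clip(
                rng.normal(config.sitting_angle_mean, config.sitting_angle_sd),
                config.sitting_angle_min,
                config.sitting_angle_max,
            )
        else:
            angle = rng.normal(config.lying_angle_mean, config.lying_angle_sd)
        a = np.radians(angle)
        y = -np.cos(a) + noise()
        x = np.sin(a) + noise()
        z = noise()
    elif posture == "standing":
        y = -1.0 + noise()
        x = noise()
        z = noise()
    elif posture == "walking":
        amp = config.walking_amplitude
        phase = rng.uniform(0, 2 * np.pi)
        osc = amp * np.sin(2 * np.pi * profile.gait_freq * t + phase)
        y = -1.0 + osc + noise()
        x = 0.4 * amp * np.cos(2 * np.pi * profile.gait_freq * t + phase) + noise()
        z = 0.2 * amp * np.sin(4 * np.pi * profile.gait_freq * t + phase) + noise()
    else:
        raise ValueError(f"unknown posture {posture!r}")
    return AccelRecording(np.vstack([x, y, z]), sample_rate=config.accel_rate)


# ---------------------------------------------------------------------------
# EMG


def _burst_params(task_model: TaskModel, met: float, config: GeneratorConfig):
    excess = max(met - 1.0, 0.0)
    rates = {
        ch: config.burst_rate_per_met * excess * w
        for ch, w in task_model.channel_weights.items()
    }
    amp = config.burst_amp_per_met * (0.5 + excess)
    return rates, amp


def simulate_emg_envelope(task_model: TaskModel, met: float, duration: float,
                          profile: ParticipantProfile, config: GeneratorConfig,
                          rng: np.random.Generator) -> np.ndarray:
    """Rectified 30 Hz EMG envelope for one task block, shape (8, n).

    Baseline half-normal noise plus Poisson-arriving Gaussian-enveloped
    bursts; burst rate and amplitude are both strictly increasing in the MET
    excess over rest, channel weighting follows the task's dominant muscles,
    and amplitudes carry the participant's per-channel gain.
    """
    if met < 1:
        raise ValueError("met must be >= 1")
    rate = config.emg_rate
    n = int(round(duration * rate))
    rates, amp = _burst_params(task_model, met, config)
    width = max(1, int(round(config.burst_width_s * rate)))
    kernel = sps.windows.gaussian(6 * width + 1, std=width)
    out = np.empty((len(EMG_CHANNELS), n))
    for i, ch in enumerate(EMG_CHANNELS):
        baseline = np.abs(rng.normal(0.0, config.emg_baseline, size=n)) * profile.gains[i]
        n_bursts = rng.poisson(rates[ch] * duration)
        impulses = np.zeros(n)
        if n_bursts > 0:
            pos = rng.integers(0, n, size=n_bursts)
            amps = amp * profile.gains[i] * rng.lognormal(0.0, 0.3, size=n_bursts)
            np.add.at(impulses, pos, amps)
        out[i] = baseline + np.convolve(impulses, kernel, mode="same")
    return out


def simulate_emg_raw(task_model: TaskModel, met: float, duration: float,
                     profile: ParticipantProfile, config: GeneratorConfig,
                     rng: np.random.Generator) -> np.ndarray:
    """Raw (pre-front-end) zero-mean EMG at ``config.raw_emg_rate``, (8, n).

    The same burst process as the envelope path, expressed as amplitude-
    modulated broadband noise, for exercising the analog front end.
    """
    if met < 1:
        raise ValueError("met must be >= 1")
    rate = config.raw_emg_rate
    n = int(round(duration * rate))
    rates, amp = _burst_params(task_model, met, config)
    width = max(1, int(round(config.burst_width_s * rate)))
    kernel = sps.windows.gaussian(6 * width + 1, std=width)
    out = np.empty((len(EMG_CHANNELS), n))
    for i, ch in enumerate(EMG_CHANNELS):
        envelope = np.full(n, config.emg_baseline * profile.gains[i])
        n_bursts = rng.poisson(rates[ch] * duration)
        if n_bursts > 0:
            impulses = np.zeros(n)
            pos = rng.integers(0, n, size=n_bursts)
            amps = amp * profile.gains[i] * rng.lognormal(0.0, 0.3, size=n_bursts)
            np.add.at(impulses, pos, amps)
            envelope = envelope + np.convolve(impulses, kernel, mode="same")
        out[i] = envelope * rng.normal(0.0, 1.0, size=n)
    return out


def analog_frontend(raw: np.ndarray, raw_rate: float,
                    out_rate: float = 30.0) -> EMGRecording:
    """The device's analog pre-processing chain applied to raw EMG.

    High-pass at 1.8 Hz (removes electrode drift/DC), full-wave
    rectification, low-pass at 110 Hz, then resampling to the 30 Hz storage
    rate.  Requires the raw rate to be at least twice the 110 Hz cut-off.
    Output is clipped at 0: the stored envelope is non-negative by
    construction.
    """
    if raw_rate < 220:
        raise ValueError("raw sample rate must be >= 220 Hz (2 x 110 Hz cut-off)")
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    sos_hp = sps.butter(4, 1.8, btype="highpass", fs=raw_rate, output="sos")
    sos_lp = sps.butter(4, 110.0, btype="lowpass", fs=raw_rate, output="sos")
    x = sps.sosfiltfilt(sos_hp, raw, axis=-1)
    x = np.abs(x)
    x = sps.sosfiltfilt(sos_lp, x, axis=-1)
    from fractions import Fraction

    frac = Fraction(out_rate / raw_rate).limit_denominator(10000)
    x = sps.resample_poly(x, frac.numerator, frac.denominator, axis=-1)
    return EMGRecording(np.clip(x, 0.0, None), sample_rate=out_rate)


# ---------------------------------------------------------------------------
# Calorimeter


def simulate_calorimeter(profile: ParticipantProfile, schedule,
                         config: GeneratorConfig,
                         rng: np.random.Generator) -> CalorimeterTrace:
    """Energy-expenditure trace at 0.1 Hz for a full session schedule.

    ``schedule`` is a sequence of (task, posture, start, end, met) tuples;
    the lying segment has MET multiplier 1 plus an exponential settling
    transient.  Noise is Gaussian with sd = ``calorimeter_noise_frac`` x rmr.
    """
    total = max(end for _, _, _, end, _ in schedule)
    n = int(round(total * config.calorimeter_rate))
    t = np.arange(n) / config.calorimeter_rate
    values = np.full(n, profile.rmr)
    for task, posture, start, end, met in schedule:
        m = (t >= start) & (t < end)
        if task == "lying":
            settle = config.lying_settle_amp * np.exp(
                -(t[m] - start) / config.lying_settle_tau
            )
            values[m] = profile.rmr * (1.0 + settle)
        else:
            values[m] = profile.rmr * met
    noise = rng.normal(0.0, config.calorimeter_noise_frac * profile.rmr, size=n)
    return CalorimeterTrace(
        np.clip(values + noise, 1e-3, None), sample_rate=config.calorimeter_rate
    )


# ---------------------------------------------------------------------------
# Full study


@dataclass
class ParticipantSession:
    profile: ParticipantProfile
    emg: EMGRecording
    accel: AccelRecording
    calorimeter: CalorimeterTrace
    annotations: list[TaskAnnotation]
    task_truth: pd.DataFrame  # task, posture, start, end, met, met_category


@dataclass
class StudyDataset:
    config: GeneratorConfig
    sessions: list[ParticipantSession]

    def labeled_minutes(self, min_run: int = 30) -> list[sio.LabeledMinute]:
        """Epoch every session and attach the ground-truth MET labels."""
        minutes = []
        for s in self.sessions:
            truth = {
                (r.task, r.posture): (r.met, r.met_category)
                for r in s.task_truth.itertuples(index=False)
            }
            for m in sio.epoch_minutes(s.emg, s.accel, s.calorimeter,
                                       s.annotations, min_run=min_run):
                met, cat = truth[(m.task, m.posture)]
                m.met, m.met_category = met, cat
                minutes.append(m)
        return minutes

    def ground_truth_frame(self) -> pd.DataFrame:
        frames = []
        for s in self.sessions:
            df = s.task_truth.copy()
            df.insert(0, "participant_id", s.profile.participant_id)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def _draw_profile(pid: str, config: GeneratorConfig,
                  rng: np.random.Generator) -> ParticipantProfile:
    rmr = float(np.clip(rng.normal(config.rmr_mean, config.rmr_sd), 0.8, None))
    gains = tuple(rng.lognormal(0.0, config.gain_sigma, size=len(EMG_CHANNELS)))
    gait = float(np.clip(rng.normal(config.gait_freq_mean, config.gait_freq_sd), 1.2, 2.4))
    return ParticipantProfile(pid, rmr, gains, gait)


def _draw_task_order(config: GeneratorConfig, rng: np.random.Generator):
    """Randomized task order: mandatory tasks always within the first six."""
    optional = [k for k in TASK_MET_TABLE if k not in MANDATORY_TASKS]
    n_optional = config.n_tasks - len(MANDATORY_TASKS)
    chosen_optional = [
        optional[i] for i in rng.choice(len(optional), size=n_optional, replace=False)
    ]
    if config.n_tasks > 6:
        last = chosen_optional[int(rng.integers(len(chosen_optional)))]
        head = list(MANDATORY_TASKS) + [k for k in chosen_optional if k != last]
        rng.shuffle(head)
        return head + [last]
    order = list(MANDATORY_TASKS) + chosen_optional
    rng.shuffle(order)
    return order


def _draw_met(task: str, posture: str, rng: np.random.Generator) -> float:
    median, iqr = TASK_MET_TABLE[(task, posture)]
    met = rng.normal(median, iqr / 1.349)
    lower = 1.6 if task == "walking" else 1.0
    return float(np.clip(met, lower, None))


def generate_participant(pid: str, config: GeneratorConfig,
                         rng: np.random.Generator,
                         task_models=None) -> ParticipantSession:
    task_models = task_models or default_task_models()
    profile = _draw_profile(pid, config, rng)
    order = _draw_task_order(config, rng)

    annotations, truth_rows, schedule = [], [], []
    emg_parts, accel_parts = [], []
    t = 0.0
    for task, posture in order:
        model = task_models[(task, posture)]
        met = _draw_met(task, posture, rng)
        start, end = t, t + config.task_duration
        annotations.append(TaskAnnotation(pid, task, posture, start, end))
        truth_rows.append(
            {"task": task, "posture": posture, "start": start, "end": end,
             "met": met, "met_category": met_category(met)}
        )
        schedule.append((task, posture, start, end, met))
        accel_parts.append(simulate_accel(posture, config.task_duration, profile, config, rng))
        emg_parts.append(
            simulate_emg_envelope(model, met, config.task_duration, profile, config, rng)
        )
        t = end
    # lying block at the end (RMR measured after the office tasks)
    start, end = t, t + config.lying_duration
    annotations.append(TaskAnnotation(pid, "lying", "lying", start, end))
    truth_rows.append(
        {"task": "lying", "posture": "lying", "start": start, "end": end,
         "met": 1.0, "met_category": met_category(1.0)}
    )
    schedule.append(("lying", "lying", start, end, 1.0))
    accel_parts.append(simulate_accel("lying", config.lying_duration, profile, config, rng))
    lying_model = TaskModel("video", "lying", 1.0, 0.0,
                            {ch: 0.0 for ch in EMG_CHANNELS})
    emg_parts.append(
        simulate_emg_envelope(lying_model, 1.0, config.lying_duration, profile, config, rng)
    )

    emg = EMGRecording(np.hstack(emg_parts), sample_rate=config.emg_rate)
    accel = AccelRecording(
        np.hstack([a.data for a in accel_parts]), sample_rate=config.accel_rate
    )
    calorimeter = simulate_calorimeter(profile, schedule, config, rng)
    return ParticipantSession(
        profile=profile,
        emg=emg,
        accel=accel,
        calorimeter=calorimeter,
        annotations=annotations,
        task_truth=pd.DataFrame(truth_rows),
    )


def generate_study(config: GeneratorConfig | None = None) -> StudyDataset:
    """Generate the full synthetic study: one session per participant.

    The same seed always produces the identical dataset; participants use
    independent child streams of the master seed.
    """
    config = config or GeneratorConfig()
    children = np.random.SeedSequence(config.seed).spawn(config.n_participants)
    sessions = [
        generate_participant(f"P{i + 1:02d}", config, np.random.default_rng(child))
        for i, child in enumerate(children)
    ]
    return StudyDataset(config=config, sessions=sessions)


def write_study(dataset: StudyDataset, outdir) -> None:
    """Write a study in the device CSV formats plus a ground-truth CSV."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    all_annotations = []
    for s in dataset.sessions:
        pid = s.profile.participant_id
        sio.write_emg_csv(s.emg, outdir / f"{pid}_emg.csv")
        sio.write_accel_csv(s.accel, outdir / f"{pid}_accel.csv")
        sio.write_calorimeter_csv(s.calorimeter, outdir / f"{pid}_calorimeter.csv")
        all_annotations.extend(s.annotations)
    sio.write_annotations_csv(all_annotations, outdir / "annotations.csv")
    dataset.ground_truth_frame().to_csv(outdir / "ground_truth.csv", index=False)
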