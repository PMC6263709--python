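"""Device-style signal I/O and minute epoching.

The measurement system stores three CSV streams per session: an 8-channel
rectified surface-EMG envelope sampled at 30 Hz, a 3-axis thigh accelerometer
in g, and an indirect-calorimeter energy-expenditure trace at 0.1 Hz
(kcal/min).  Task annotations (who did what, in which posture, when) arrive as
a fourth CSV.  All timestamps are seconds since session start.

Channels that partially lose contact record runs of exact zeros; these are
flagged but never dropped or repaired — downstream feature selection is
expected to route around them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Electrode sites, bilateral: forearm (finger/wrist extensors), upper arm
#: (elbow flexors), shoulder (anterior deltoid), lower back (erector spinae).
EMG_CHANNELS: tuple[str, ...] = (
    "right_forearm",
    "right_upper_arm",
    "right_shoulder",
    "right_lower_back",
    "left_forearm",
    "left_upper_arm",
    "left_shoulder",
    "left_lower_back",
)

ACCEL_AXES: tuple[str, ...] = ("x", "y", "z")

POSTURES: tuple[str, ...] = ("sitting", "standing", "walking", "lying")

#: Closed task vocabulary: four desk tasks each done sitting and standing,
#: a walking task, and the supine lying block used for the RMR reference.
DESK_TASKS: tuple[str, ...] = ("video", "mouse", "typing", "deskwork")
TASKS: tuple[str, ...] = DESK_TASKS + ("walking", "lying")


class SignalParseError(ValueError):
    """A CSV row failed to parse; carries the 1-based line number."""

    def __init__(self, path, line_no: int, message: str):
        self.path = str(path)
        self.line_no = line_no
        super().__init__(f"{path}:{line_no}: {message}")


class SchemaError(ValueError):
    """The file structure does not match the declared stream schema."""


@dataclass
class SignalSchema:
    """Declared sample rates of the three device streams (Hz)."""

    emg_rate: float = 30.0
    accel_rate: float = 30.0
    calorimeter_rate: float = 0.1


@dataclass
class EMGRecording:
    """Rectified 8-channel EMG envelope in arbitrary device units.

    ``data`` has shape (8, n_samples); amplitudes are post-rectification and
    therefore non-negative.
    """

    data: np.ndarray
    sample_rate: float = 30.0
    start_time: float = 0.0
    channels: tuple[str, ...] = EMG_CHANNELS

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(EMG_CHANNELS):
            raise SchemaError(
                f"EMG data must have {len(EMG_CHANNELS)} channels, "
                f"got shape {self.data.shape}"
            )
        if len(self.channels) != len(EMG_CHANNELS):
            raise SchemaError("exactly 8 named EMG channels required")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        if np.any(self.data < 0):
            raise ValueError("EMG envelope amplitudes must be >= 0 (rectified)")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate


@dataclass
class AccelRecording:
    """3-axis accelerometer in g.

    Convention: the y axis lies along the thigh's longitudinal axis and points
    upwards while standing, so quiet standing reads y ~ -1 g and a horizontal
    thigh reads y ~ 0 g.
    """

    data: np.ndarray
    sample_rate: float = 30.0
    start_time: float = 0.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != 3:
            raise SchemaError(f"accelerometer needs 3 axes, got shape {self.data.shape}")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def y(self) -> np.ndarray:
        return self.data[1]


@dataclass
class CalorimeterTrace:
    """Indirect-calorimeter energy expenditure in kcal/min at 0.1 Hz."""

    values: np.ndarray
    sample_rate: float = 0.1
    start_time: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        if np.any(self.values <= 0):
            raise ValueError("energy expenditure values must be > 0")

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate


@dataclass
class TaskAnnotation:
    """One annotated task window: [start, end) seconds since session start."""

    participant_id: str
    task: str
    posture: str
    start: float
    end: float

    def __post_init__(self):
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}; expected one of {TASKS}")
        if self.posture not in POSTURES:
            raise ValueError(f"unknown posture {self.posture!r}")
        if not self.end > self.start:
            raise ValueError("annotation end must be after start")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class LabeledMinute:
    """One 60-s epoch with its signal slices and ground-truth labels.

    MET value and category are optional until the calorimetry stage labels the
    minute; the invariant category-defined-iff-met-defined is enforced.
    """

    minute_index: int
    participant_id: str
    task: str
    posture: str
    emg: np.ndarray  # (8, 60 * emg_rate)
    accel: np.ndarray  # (3, 60 * accel_rate)
    calorimeter: np.ndarray  # (60 * calorimeter_rate,)
    emg_rate: float = 30.0
    accel_rate: float = 30.0
    calorimeter_rate: float = 0.1
    met: float | None = None
    met_category: str | None = None
    missing: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self):
        for name, arr, rate in (
            ("emg", self.emg, self.emg_rate),
            ("accel", self.accel, self.accel_rate),
        ):
            expected = round(60 * rate)
            if arr.shape[-1] != expected:
                raise ValueError(
                    f"{name} slice must hold {expected} samples, got {arr.shape[-1]}"
                )
        if (self.met is None) != (self.met_category is None):
            raise ValueError("MET category is defined iff the MET value is defined")

    @property
    def accel_y(self) -> np.ndarray:
        return self.accel[1]


# ---------------------------------------------------------------------------
# CSV carriers.  Dialect: comma separator, dot decimal, one header row naming
# the columns.  Values are written with enough digits to round-trip floats.

_FLOAT_FMT = "%.10g"


def _read_numeric_csv(path, expected_columns: Sequence[str] | None = None) -> tuple[list[str], np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise SignalParseError(path, _bad_line_from_parser(exc), str(exc)) from exc
    if expected_columns is not None and list(df.columns) != list(expected_columns):
        raise SchemaError(
            f"{path}: expected columns {list(expected_columns)}, got {list(df.columns)}"
        )
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1) & ~df.isna().any(axis=1)
    bad |= df.isna().any(axis=1)
    if bad.any():
        # +2: one for the header line, one for 0- vs 1-based indexing
        line_no = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise SignalParseError(path, line_no, "malformed (non-numeric or missing) row")
    return list(df.columns), numeric.to_numpy(dtype=float)


def _bad_line_from_parser(exc) -> int:
    import re

    m = re.search(r"line (\d+)", str(exc))
    return int(m.group(1)) if m else -1


def write_emg_csv(recording: EMGRecording, path) -> None:
    pd.DataFrame(recording.data.T, columns=list(recording.channels)).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def write_accel_csv(recording: AccelRecording, path) -> None:
    pd.DataFrame(recording.data.T, columns=list(ACCEL_AXES)).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def write_calorimeter_csv(trace: CalorimeterTrace, path) -> None:
    pd.DataFrame({"ee_kcal_min": trace.values}).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def write_annotations_csv(annotations: Sequence[TaskAnnotation], path) -> None:
    pd.DataFrame(
        [
            {
                "participant_id": a.participant_id,
                "task": a.task,
                "posture": a.posture,
                "start_s": a.start,
                "end_s": a.end,
            }
            for a in annotations
        ]
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_emg_csv(path, sample_rate: float = 30.0, start_time: float = 0.0) -> EMGRecording:
    columns, values = _read_numeric_csv(path)
    if len(columns) != len(EMG_CHANNELS):
        raise SchemaError(
            f"{path}: EMG CSV must have {len(EMG_CHANNELS)} channel columns, got {len(columns)}"
        )
    return EMGRecording(values.T, sample_rate=sample_rate, start_time=start_time,
                        channels=tuple(columns))


def read_accel_csv(path, sample_rate: float = 30.0, start_time: float = 0.0) -> AccelRecording:
    columns, values = _read_numeric_csv(path, expected_columns=ACCEL_AXES)
    return AccelRecording(values.T, sample_rate=sample_rate, start_time=start_time)


def read_calorimeter_csv(path, sample_rate: float = 0.1, start_time: float = 0.0) -> CalorimeterTrace:
    columns, values = _read_numeric_csv(path, expected_columns=("ee_kcal_min",))
    return CalorimeterTrace(values[:, 0], sample_rate=sample_rate, start_time=start_time)


def read_annotations_csv(path) -> list[TaskAnnotation]:
    df = pd.read_csv(path)
    expected = ["participant_id", "task", "posture", "start_s", "end_s"]
    if list(df.columns) != expected:
        raise SchemaError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    return [
        TaskAnnotation(str(r.participant_id), r.task, r.posture, float(r.start_s), float(r.end_s))
        for r in df.itertuples(index=False)
    ]


def read_signals(paths: Mapping[str, object], schema: SignalSchema | None = None):
    """Read the three device streams declared in ``paths``.

    Parameters
    ----------
    paths
        Mapping with keys ``"emg"``, ``"accel"``, ``"calorimeter"``.
    schema
        Declared sample rates; defaults to the device values (30/30/0.1 Hz).

    Returns
    -------
    (EMGRecording, AccelRecording, CalorimeterTrace)
    """
    schema = schema or SignalSchema()
    emg = read_emg_csv(paths["emg"], sample_rate=schema.emg_rate)
    accel = read_accel_csv(paths["accel"], sample_rate=schema.accel_rate)
    cal = read_calorimeter_csv(paths["calorimeter"], sample_rate=schema.calorimeter_rate)
    return emg, accel, cal


# ---------------------------------------------------------------------------
# Epoching


def _slice_stream(data: np.ndarray, rate: float, stream_start: float,
                  t0: float, t1: float) -> np.ndarray:
    i0 = int(round((t0 - stream_start) * rate))
    i1 = int(round((t1 - stream_start) * rate))
    return data[..., i0:i1]


def epoch_minutes(
    emg: EMGRecording,
    accel: AccelRecording,
    calorimeter: CalorimeterTrace,
    annotations: Sequence[TaskAnnotation],
    min_run: int = 30,
) -> list[LabeledMinute]:
    """Cut each annotated task window into consecutive 60-s labeled epochs.

    Epochs start at the annotated window start (tasks come in timed blocks, so
    wall-clock minute boundaries are irrelevant); a trailing epoch shorter than
    60 s is dropped.  EMG channels containing >= ``min_run`` consecutive exact
    zeros are flagged as partially missing but left untouched.
    """
    minutes: list[LabeledMinute] = []
    idx = 0
    for ann in annotations:
        for stream, rec in (("emg", emg), ("accel", accel), ("calorimeter", calorimeter)):
            if ann.start < rec.start_time - 1e-9 or ann.end > rec.start_time + rec.duration + 1e-9:
                raise ValueError(
                    f"annotation [{ann.start}, {ann.end}) outside the {stream} "
                    f"recording span [{rec.start_time}, {rec.start_time + rec.duration})"
                )
        n_full = int(ann.duration // 60)
        for k in range(n_full):
            t0, t1 = ann.start + 60 * k, ann.start + 60 * (k + 1)
            minute = LabeledMinute(
                minute_index=idx,
                participant_id=ann.participant_id,
                task=ann.task,
                posture=ann.posture,
                emg=_slice_stream(emg.data, emg.sample_rate, emg.start_time, t0, t1),
                accel=_slice_stream(accel.data, accel.sample_rate, accel.start_time, t0, t1),
                calorimeter=_slice_stream(
                    calorimeter.values, calorimeter.sample_rate, calorimeter.start_time, t0, t1
                ),
                emg_rate=emg.sample_rate,
                accel_rate=accel.sample_rate,
                calorimeter_rate=calorimeter.sample_rate,
            )
            minute.missing = flag_missing(minute, min_run=min_run)
            minutes.append(minute)
            idx += 1
    return minutes


def has_zero_run(x: np.ndarray, min_run: int) -> bool:
    """True iff ``x`` contains >= ``min_run`` consecutive exact zeros."""
    if min_run <= 0:
        raise ValueError("min_run must be positive")
    z = np.concatenate(([0], (x == 0).astype(int), [0]))
    edges = np.diff(z)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return bool(starts.size) and int((ends - starts).max()) >= min_run


def flag_missing(minute: LabeledMinute, min_run: int = 30) -> dict[str, bool]:
    """Flag each EMG channel that contains a zero run of >= ``min_run`` samples.

    Purely diagnostic: signal values are never modified, and flagged channels
    keep contributing (numeric) features downstream.
    """
    return {
        ch: has_zero_run(minute.emg[i], min_run)
        for i, ch in enumerate(EMG_CHANNELS)
    }
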