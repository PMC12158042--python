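"""Domain types, channel file IO, and session assembly.

A recording session is one participant performing one assembly test while
wearing the sensor set: a resting baseline segment plus a test segment per
channel, an environment record, the static task table and the observed task
start/end annotations.  Channel files are plain two-column delimited text
(comma or tab, autodetected): ``time,<name>`` for numeric channels and
``time,event`` for gaze events.  Timestamps are seconds; task annotations
are offsets from test start.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Channel",
    "EnvironmentRecord",
    "TaskSpec",
    "TaskAnnotation",
    "Session",
    "REQUIRED_CHANNELS",
    "read_channel",
    "write_channel",
    "assemble_session",
    "save_session",
    "load_session",
]

NOISE_LEVELS = ("low", "medium", "high")
DIFFICULTY_LEVELS = ("low", "medium", "high")
GAZE_LABELS = ("fixation", "saccade", "other")
TEST_IDS = ("test1", "test2")
SCENARIOS = ("control", "dyslexia_support", "dyslexia_no_support")
ASSISTANCE = ("human", "robot")

#: Channels the fusion hierarchy requires in the test segment.
REQUIRED_CHANNELS = ("hr", "ecg", "hrv", "eda", "pupil_left", "pupil_right", "gaze_event")

#: Maximum test duration in seconds (each test capped at 15 minutes).
MAX_TEST_DURATION = 900.0


@dataclass
class Channel:
    """A single-signal time series, uniformly sampled or event-stamped."""

    name: str
    kind: str  # "numeric" | "event"
    samples: np.ndarray | None = None
    events: tuple[tuple[float, str], ...] = ()
    sampling_rate: float | None = None
    t0: float = 0.0
    units: str = ""

    def __post_init__(self) -> None:
        if self.kind == "numeric":
            self.samples = np.asarray(self.samples, dtype=float)
            if self.samples.ndim != 1 or self.samples.size == 0:
                raise ValueError(f"channel {self.name!r}: empty channel")
            if not np.all(np.isfinite(self.samples)):
                raise ValueError(f"channel {self.name!r}: non-finite samples")
            if self.sampling_rate is None or not self.sampling_rate > 0:
                raise ValueError(f"channel {self.name!r}: sampling_rate must be > 0")
        elif self.kind == "event":
            if not self.events:
                raise ValueError(f"channel {self.name!r}: empty channel")
            times = [t for t, _ in self.events]
            if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
                raise ValueError(f"channel {self.name!r}: unsorted event times")
        else:
            raise ValueError(f"channel {self.name!r}: unknown kind {self.kind!r}")

    @property
    def duration(self) -> float:
        """Span covered by the channel, in seconds."""
        if self.kind == "numeric":
            return self.samples.size / self.sampling_rate
        return self.events[-1][0] - self.events[0][0]


@dataclass(frozen=True)
class EnvironmentRecord:
    temperature: float  # degrees C
    humidity: float  # percent, 0-100
    noise: str  # low | medium | high

    def __post_init__(self) -> None:
        if not 0.0 <= self.humidity <= 100.0:
            raise ValueError("humidity must be in [0, 100] percent")
        if self.noise not in NOISE_LEVELS:
            raise ValueError(f"noise must be one of {NOISE_LEVELS}")


@dataclass(frozen=True)
class TaskSpec:
    index: int  # 1-based
    n_items: int
    n_operations: int
    difficulty: str

    def __post_init__(self) -> None:
        if self.n_items < 0 or self.n_operations < 0:
            raise ValueError("task counts must be non-negative")
        if self.difficulty not in DIFFICULTY_LEVELS:
            raise ValueError(f"difficulty must be one of {DIFFICULTY_LEVELS}")


@dataclass(frozen=True)
class TaskAnnotation:
    index: int
    start: float  # seconds from test start
    end: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"annotation {self.index}: start must precede end")


@dataclass
class Session:
    """One participant x one test: channels, environment, tasks, annotations."""

    participant_id: str
    test_id: str
    scenario: str
    assistance: str
    baseline: dict[str, Channel]
    test: dict[str, Channel]
    environment: EnvironmentRecord
    tasks: list[TaskSpec]
    annotations: list[TaskAnnotation]
    warnings: list[str] = field(default_factory=list)

    def validate(self) -> None:
        if self.test_id not in TEST_IDS:
            raise ValueError(f"test_id must be one of {TEST_IDS}")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if self.assistance not in ASSISTANCE:
            raise ValueError(f"assistance must be one of {ASSISTANCE}")
        for name in sorted(self.test):
            ch = self.test[name]
            if ch.kind == "numeric" and name not in self.baseline:
                raise ValueError(f"test channel {name!r} has no baseline counterpart")
        indices = [t.index for t in self.tasks]
        if indices != list(range(1, len(self.tasks) + 1)):
            raise ValueError("task indices must be consecutive from 1")
        known = set(indices)
        prev_end = -np.inf
        for k, ann in enumerate(self.annotations, start=1):
            if ann.index != k:
                raise ValueError("annotations must be an in-order prefix of the task list")
            if ann.index not in known:
                raise ValueError(f"annotation for task {ann.index} has no TaskSpec")
            if ann.start < prev_end:
                raise ValueError("annotations overlap")
            prev_end = ann.end
        for ch in self.test.values():
            if ch.kind == "numeric" and ch.duration > MAX_TEST_DURATION + 1e-9:
                raise ValueError(
                    f"test channel {ch.name!r} exceeds the {MAX_TEST_DURATION:.0f} s cap"
                )


def _sniff_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError("empty channel")
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, skipinitialspace=True)
    if df.shape[0] == 0:
        raise ValueError("empty channel")
    if df.shape[1] != 2:
        raise ValueError(f"malformed channel file: expected 2 columns, got {df.shape[1]}")
    return df


def read_channel(
    path,
    name: str | None = None,
    kind: str | None = None,
    sampling_rate: float | None = None,
    units: str = "",
) -> Channel:
    """Read a two-column delimited channel file.

    The second column decides the channel kind: all-numeric values give a
    numeric channel (rate declared or inferred from the median time step),
    all-text values give an event channel.  A mix is rejected as malformed.
    """
    df = _sniff_table(path)
    time_col, value_col = df.columns
    times = pd.to_numeric(df[time_col], errors="coerce").to_numpy()
    if np.any(np.isnan(times)):
        raise ValueError("malformed channel file: non-numeric time values")
    values = pd.to_numeric(df[value_col], errors="coerce").to_numpy()
    n_numeric = int(np.sum(~np.isnan(values)))
    inferred_kind = "numeric" if n_numeric == len(values) else "event"
    if 0 < n_numeric < len(values):
        raise ValueError("malformed channel file: mixed numeric and label values")
    if kind is not None and kind != inferred_kind:
        raise ValueError(f"channel file is {inferred_kind}, expected {kind}")
    cname = name or str(value_col)

    if inferred_kind == "event":
        if np.any(np.diff(times) <= 0):
            raise ValueError("unsorted: event times must be strictly increasing")
        events = tuple(zip(times.tolist(), df[value_col].astype(str).str.strip()))
        return Channel(cname, "event", events=events, t0=float(times[0]), units=units)

    if np.any(np.diff(times) < 0):
        raise ValueError("unsorted: time column must be monotone")
    if sampling_rate is None:
        if len(times) < 2:
            raise ValueError("cannot infer sampling rate from a single sample")
        dt = float(np.median(np.diff(times)))
        if dt <= 0:
            raise ValueError("unsorted: repeated timestamps")
        sampling_rate = 1.0 / dt
    return Channel(
        cname, "numeric", samples=values, sampling_rate=float(sampling_rate),
        t0=float(times[0]), units=units,
    )


def write_channel(channel: Channel, path) -> None:
    """Write a channel back to two-column CSV (values at 12 significant digits)."""
    path = Path(path)
    with open(path, "w") as fh:
        if channel.kind == "numeric":
            fh.write(f"time,{channel.name}\n")
            t = channel.t0 + np.arange(channel.samples.size) / channel.sampling_rate
            for ti, vi in zip(t, channel.samples):
                fh.write(f"{ti:.12g},{vi:.12g}\n")
        else:
            fh.write("time,event\n")
            for ti, lab in channel.events:
                fh.write(f"{ti:.12g},{lab}\n")


OPTIONAL_CHANNELS = ("gaze_duration",)


def assemble_session(
    channels: Mapping[str, Mapping[str, Channel]],
    environment: EnvironmentRecord,
    tasks: Sequence[TaskSpec],
    annotations: Sequence[TaskAnnotation],
    participant_id: str = "anonymous",
    test_id: str = "test1",
    scenario: str = "control",
    assistance: str = "human",
) -> Session:
    """Validate and assemble a Session from ``{"baseline": {...}, "test": {...}}``.

    Event channels need no baseline segment.  Missing optional channels are
    recorded in ``session.warnings``; missing required channels raise.
    """
    baseline = dict(channels.get("baseline", {}))
    test = dict(channels.get("test", {}))
    warnings: list[str] = []
    for name in REQUIRED_CHANNELS:
        if name not in test:
            raise ValueError(f"missing required channel {name!r}")
    for name in OPTIONAL_CHANNELS:
        if name not in test:
            warnings.append(f"optional channel {name!r} not provided")
    session = Session(
        participant_id=participant_id,
        test_id=test_id,
        scenario=scenario,
        assistance=assistance,
        baseline=baseline,
        test=test,
        environment=environment,
        tasks=list(tasks),
        annotations=sorted(annotations, key=lambda a: a.index),
        warnings=warnings,
    )
    session.validate()
    return session


def save_session(session: Session, outdir) -> Path:
    """Write a session directory: manifest.yaml + channel/task/annotation files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "participant_id": session.participant_id,
        "test_id": session.test_id,
        "scenario": session.scenario,
        "assistance": session.assistance,
        "environment": {
            "temperature": session.environment.temperature,
            "humidity": session.environment.humidity,
            "noise": session.environment.noise,
        },
        "channels": {"baseline": {}, "test": {}},
        "tasks": "tasks.csv",
        "annotations": "annotations.csv",
    }
    for segment, chans in (("baseline", session.baseline), ("test", session.test)):
        for name, ch in chans.items():
            fname = f"{segment}_{name}.csv"
            write_channel(ch, outdir / fname)
            manifest["channels"][segment][name] = {
                "path": fname,
                "kind": ch.kind,
                "sampling_rate": ch.sampling_rate,
                "units": ch.units,
            }
    pd.DataFrame(
        [
            {"task": t.index, "n_items": t.n_items, "n_operations": t.n_operations,
             "difficulty": t.difficulty}
            for t in session.tasks
        ]
    ).to_csv(outdir / "tasks.csv", index=False)
    pd.DataFrame(
        [{"task": a.index, "start": a.start, "end": a.end} for a in session.annotations]
    ).to_csv(outdir / "annotations.csv", index=False)
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return outdir / "manifest.yaml"


def load_session(manifest_path) -> Session:
    """Load a session directory written by :func:`save_session`."""
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / "manifest.yaml"
    root = manifest_path.parent
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    channels: dict[str, dict[str, Channel]] = {"baseline": {}, "test": {}}
    for segment in ("baseline", "test"):
        for name, meta in manifest["channels"].get(segment, {}).items():
            channels[segment][name] = read_channel(
                root / meta["path"],
                name=name,
                kind=meta.get("kind"),
                sampling_rate=meta.get("sampling_rate"),
                units=meta.get("units", ""),
            )
    tasks_df = pd.read_csv(root / manifest["tasks"])
    tasks = [
        TaskSpec(int(r.task), int(r.n_items), int(r.n_operations), str(r.difficulty))
        for r in tasks_df.itertuples()
    ]
    ann_df = pd.read_csv(root / manifest["annotations"])
    annotations = [
        TaskAnnotation(int(r.task), float(r.start), float(r.end))
        for r in ann_df.itertuples()
    ]
    env = EnvironmentRecord(**manifest["environment"])
    return assemble_session(
        channels, env, tasks, annotations,
        participant_id=manifest["participant_id"],
        test_id=manifest["test_id"],
        scenario=manifest["scenario"],
        assistance=manifest["assistance"],
    )
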