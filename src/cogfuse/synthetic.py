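"""Seeded generator of complete synthetic recording sessions.

No participant recordings are publicly deposited, so every pipeline stage is
exercised on synthetic sessions whose arousal structure is controlled by a
single latent scalar.  Arousal drives each channel in the direction the
psychophysiology literature associates with mental effort: heart rate,
tonic skin conductance, skin-conductance-response rate, pupil diameter and
the fixation share of gaze time all rise with arousal, while RMSSD falls.
Channels are emitted at the device rates of the acquisition protocol
(HR 1 Hz, ECG 1024 Hz, EDA 32 Hz, pupils and gaze 100 Hz) with a 3-minute
resting baseline preceding the test segment.

The ECG channel is a noisy sinusoid-plus-spike proxy with the correct beat
rate and an amplitude that scales with arousal — sufficient for the
amplitude-normalisation branch, with no claim to clinical waveform
morphology.  Gaze is an alternating fixation/saccade event stream.
Task annotations split the test duration proportionally to per-task
operation counts; an optional give-up task truncates them to emulate
participant dropout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from cogfuse.core_model import (
    Channel,
    EnvironmentRecord,
    Session,
    TaskAnnotation,
    TaskSpec,
    assemble_session,
)

__all__ = ["ScenarioParams", "generate_session", "default_task_tables"]

HR_HZ = 1.0
ECG_HZ = 1024.0
EDA_HZ = 32.0
EYE_HZ = 100.0

_DEFAULT_NOISE_SD = {
    "hr": 1.5,  # bpm
    "hrv": 2.0,  # ms
    "ecg": 0.05,  # arbitrary amplitude units
    "eda": 0.03,  # microsiemens
    "pupil": 0.08,  # mm
}


@dataclass(frozen=True)
class ScenarioParams:
    """Latent arousal level plus per-channel gains and noise scales.

    ``arousal`` in [0, 1] sets the test-phase shift of every channel mean
    relative to baseline: HR mean x (1 + hr_gain*arousal), RMSSD x
    (1 - rmssd_drop*arousal), tonic EDA x (1 + eda_gain*arousal), pupil x
    (1 + pupil_gain*arousal); phasic SCR events arrive at ``scr_rate`` x
    arousal per minute; the fixation share of gaze time rises by
    ``fixation_bias`` x arousal.
    """

    arousal: float = 0.0
    baseline_hr: float = 70.0  # bpm
    hr_gain: float = 0.3
    rmssd_base: float = 45.0  # ms
    rmssd_drop: float = 0.5
    eda_base: float = 2.0  # microsiemens
    eda_gain: float = 0.6
    scr_rate: float = 6.0  # events/min at arousal 1
    pupil_base: float = 3.5  # mm
    pupil_gain: float = 0.25
    fixation_bias: float = 0.3
    noise_sd: dict = field(default_factory=lambda: dict(_DEFAULT_NOISE_SD))
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.arousal <= 1.0:
            raise ValueError("arousal must be in [0, 1]")
        for name in ("hr_gain", "rmssd_drop", "eda_gain", "scr_rate", "pupil_gain",
                     "fixation_bias"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def default_task_tables() -> tuple[list[TaskSpec], list[TaskSpec]]:
    """The two assembly-test task tables (items, operations, difficulty)."""
    test1 = [
        TaskSpec(1, 3, 6, "low"),
        TaskSpec(2, 1, 2, "low"),
        TaskSpec(3, 1, 2, "low"),
        TaskSpec(4, 1, 2, "low"),
        TaskSpec(5, 1, 2, "low"),
        TaskSpec(6, 4, 8, "high"),
        TaskSpec(7, 3, 5, "medium"),
        TaskSpec(8, 0, 1, "low"),
        TaskSpec(9, 6, 10, "high"),
        TaskSpec(10, 0, 2, "medium"),
        TaskSpec(11, 1, 2, "low"),
        TaskSpec(12, 1, 2, "medium"),
    ]
    test2 = [
        TaskSpec(1, 4, 8, "low"),
        TaskSpec(2, 2, 4, "low"),
        TaskSpec(3, 4, 8, "high"),
        TaskSpec(4, 6, 12, "high"),
        TaskSpec(5, 4, 8, "high"),
        TaskSpec(6, 1, 2, "low"),
        TaskSpec(7, 1, 2, "low"),
        TaskSpec(8, 3, 5, "medium"),
        TaskSpec(9, 0, 1, "low"),
        TaskSpec(10, 2, 2, "medium"),
        TaskSpec(11, 3, 6, "low"),
    ]
    return test1, test2


def _slow_wander(rng: np.random.Generator, n: int, fs: float, sd: float) -> np.ndarray:
    """Band-limited (~0.02 Hz) random drift so channels are not white noise."""
    n_ctrl = max(int(np.ceil(n / fs * 0.02)) + 2, 4)
    ctrl = rng.normal(0.0, sd, n_ctrl)
    return np.interp(np.linspace(0, n_ctrl - 1, n), np.arange(n_ctrl), ctrl)


def _numeric_channel(
    rng: np.random.Generator, name: str, fs: float, duration: float,
    mean: float, noise: float, units: str, positive: bool = False,
) -> Channel:
    n = int(round(duration * fs))
    x = mean + _slow_wander(rng, n, fs, noise) + rng.normal(0.0, noise, n)
    if positive:
        x = np.maximum(x, 0.05 * abs(mean) if mean else 0.01)
    return Channel(name, "numeric", samples=x, sampling_rate=fs, units=units)


def _ecg_channel(
    rng: np.random.Generator, duration: float, hr_bpm: float, amplitude: float,
    noise: float,
) -> Channel:
    n = int(round(duration * ECG_HZ))
    t = np.arange(n) / ECG_HZ
    beat_hz = hr_bpm / 60.0
    phase = (t * beat_hz) % 1.0
    spikes = np.exp(-0.5 * ((phase - 0.5) / 0.02) ** 2)  # R-peak proxy
    x = amplitude * (0.15 * np.sin(2 * np.pi * beat_hz * t) + spikes)
    x += rng.normal(0.0, noise, n)
    return Channel("ecg", "numeric", samples=x, sampling_rate=ECG_HZ, units="a.u.")


def _eda_channel(
    rng: np.random.Generator, duration: float, tonic: float, scr_per_min: float,
    noise: float,
) -> Channel:
    n = int(round(duration * EDA_HZ))
    x = np.full(n, tonic) + _slow_wander(rng, n, EDA_HZ, 0.05)
    n_events = rng.poisson(scr_per_min * duration / 60.0)
    if n_events:
        onsets = rng.uniform(0.0, duration, n_events)
        amps = rng.exponential(0.3, n_events)  # microsiemens
        tk = np.arange(int(EDA_HZ * 15)) / EDA_HZ  # 15 s kernel support
        kernel = np.where(tk < 1.0, tk, np.exp(-(tk - 1.0) / 3.0))  # 1 s rise, tau 3 s
        for t0, a in zip(onsets, amps):
            i0 = int(t0 * EDA_HZ)
            seg = min(kernel.size, n - i0)
            if seg > 0:
                x[i0 : i0 + seg] += a * kernel[:seg]
    x += rng.normal(0.0, noise, n)
    return Channel(
        "eda", "numeric", samples=np.maximum(x, 0.01), sampling_rate=EDA_HZ, units="uS"
    )


def _gaze_channel(
    rng: np.random.Generator, duration: float, fixation_share: float
) -> Channel:
    """Alternating fixation/saccade events; durations set the fixation share."""
    sacc_mean = 0.08  # s
    fix_mean = sacc_mean * fixation_share / max(1.0 - fixation_share, 0.05)
    events: list[tuple[float, str]] = []
    t, fixating = 0.0, True
    while t < duration:
        events.append((t, "fixation" if fixating else "saccade"))
        mean = fix_mean if fixating else sacc_mean
        t += max(rng.exponential(mean), 1e-3)
        fixating = not fixating
    return Channel("gaze_event", "event", events=tuple(events), units="label")


def _annotations(
    tasks: list[TaskSpec], test_duration: float, give_up_task: int | None
) -> list[TaskAnnotation]:
    ops = np.array([max(t.n_operations, 1) for t in tasks], dtype=float)
    bounds = np.concatenate([[0.0], np.cumsum(ops)]) / ops.sum() * test_duration
    anns = [
        TaskAnnotation(t.index, float(bounds[i]), float(bounds[i + 1]))
        for i, t in enumerate(tasks)
    ]
    if give_up_task is not None:
        anns = anns[: max(give_up_task, 0)]
        if not anns:
            raise ValueError("give_up_task must leave at least one annotated task")
    return anns


def generate_session(
    params: ScenarioParams,
    test_id: str = "test1",
    tasks: list[TaskSpec] | None = None,
    baseline_duration: float = 180.0,
    test_duration: float = 300.0,
    environment: EnvironmentRecord | None = None,
    give_up_task: int | None = None,
    participant_id: str = "synthetic",
    scenario: str = "control",
    assistance: str = "human",
) -> Session:
    """Generate a full synthetic Session at the protocol device rates.

    Deterministic for fixed ``params`` (including ``params.seed``) and
    arguments.  ``give_up_task`` keeps only the first k task annotations to
    emulate a participant stopping early.
    """
    if baseline_duration <= 0 or test_duration <= 0:
        raise ValueError("inconsistent durations: must be positive")
    if test_duration > 900.0:
        raise ValueError("inconsistent durations: test capped at 900 s")
    if tasks is None:
        t1, t2 = default_task_tables()
        tasks = t1 if test_id == "test1" else t2
    rng = np.random.default_rng(params.seed)
    a = params.arousal
    sd = {**_DEFAULT_NOISE_SD, **params.noise_sd}

    hr_base = params.baseline_hr
    hr_test = hr_base * (1.0 + params.hr_gain * a)
    rmssd_base = params.rmssd_base
    rmssd_test = rmssd_base * (1.0 - params.rmssd_drop * a)
    eda_base = params.eda_base
    eda_test = eda_base * (1.0 + params.eda_gain * a)
    pupil_base = params.pupil_base
    pupil_test = pupil_base * (1.0 + params.pupil_gain * a)
    fix_base = 0.55
    fix_test = min(fix_base + params.fixation_bias * a, 0.95)

    def seg(duration, hr, rmssd, eda, pupil, fix, scr, ecg_amp):
        chans = {
            "hr": _numeric_channel(rng, "hr", HR_HZ, duration, hr, sd["hr"], "bpm", True),
            "hrv": _numeric_channel(
                rng, "hrv", HR_HZ, duration, rmssd, sd["hrv"], "ms", True
            ),
            "ecg": _ecg_channel(rng, duration, hr, ecg_amp, sd["ecg"]),
            "eda": _eda_channel(rng, duration, eda, scr, sd["eda"]),
            "pupil_left": _numeric_channel(
                rng, "pupil_left", EYE_HZ, duration, pupil, sd["pupil"], "mm", True
            ),
            "pupil_right": _numeric_channel(
                rng, "pupil_right", EYE_HZ, duration, pupil, sd["pupil"], "mm", True
            ),
            "gaze_event": _gaze_channel(rng, duration, fix),
        }
        return chans

    baseline = seg(
        baseline_duration, hr_base, rmssd_base, eda_base, pupil_base, fix_base,
        scr=1.0, ecg_amp=1.0,
    )
    test = seg(
        test_duration, hr_test, rmssd_test, eda_test, pupil_test, fix_test,
        scr=1.0 + params.scr_rate * a, ecg_amp=1.0 + params.hr_gain * a,
    )
    env = environment or EnvironmentRecord(22.0, 45.0, "low")
    anns = _annotations(tasks, test_duration, give_up_task)
    return assemble_session(
        {"baseline": baseline, "test": test},
        env, tasks, anns,
        participant_id=participant_id, test_id=test_id,
        scenario=scenario, assistance=assistance,
    )
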