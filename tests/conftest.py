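import numpy as np
import pytest

from cogfuse.core_model import (
    Channel,
    EnvironmentRecord,
    TaskAnnotation,
    TaskSpec,
    assemble_session,
)


def constant_session(
    duration=30.0,
    base=dict(hr=70.0, hrv=45.0, eda=2.0, pupil=3.5, gaze="saccade", ecg_amp=1.0),
    test=None,
    environment=EnvironmentRecord(22.0, 50.0, "low"),
    tasks=(TaskSpec(1, 0, 1, "low"), TaskSpec(2, 6, 10, "high")),
    annotations=(TaskAnnotation(1, 0.0, 30.0),),
):
    """Deterministic session with channels held at fixed values.

    The ECG channel is a beat-rate sinusoid-plus-spike waveform whose
    amplitude scales with ``ecg_amp``; all other channels are constants.
    """
    test = {**base, **(test or {})}

    def segment(vals):
        n = lambda fs: int(round(duration * fs))
        t = np.arange(n(1024)) / 1024.0
        beat = vals["hr"] / 60.0
        ecg = vals["ecg_amp"] * (
            0.15 * np.sin(2 * np.pi * beat * t)
            + np.exp(-0.5 * (((t * beat) % 1.0 - 0.5) / 0.02) ** 2)
        ) + 0.01
        events = tuple((tt, vals["gaze"]) for tt in np.arange(0.0, duration, 0.25))
        return {
            "hr": Channel("hr", "numeric", samples=np.full(n(1), vals["hr"]),
                          sampling_rate=1.0, units="bpm"),
            "hrv": Channel("hrv", "numeric", samples=np.full(n(1), vals["hrv"]),
                           sampling_rate=1.0, units="ms"),
            "ecg": Channel("ecg", "numeric", samples=ecg, sampling_rate=1024.0),
            "eda": Channel("eda", "numeric", samples=np.full(n(32), vals["eda"]),
                           sampling_rate=32.0, units="uS"),
            "pupil_left": Channel("pupil_left", "numeric",
                                  samples=np.full(n(100), vals["pupil"]),
                                  sampling_rate=100.0, units="mm"),
            "pupil_right": Channel("pupil_right", "numeric",
                                   samples=np.full(n(100), vals["pupil"]),
                                   sampling_rate=100.0, units="mm"),
            "gaze_event": Channel("gaze_event", "event", events=events),
        }

    return assemble_session(
        {"baseline": segment(base), "test": segment(test)},
        environment, list(tasks), list(annotations),
    )


@pytest.fixture(scope="session")
def frozen_session():
    """Test channels identical to baseline; a single low-load task annotated."""
    return constant_session()


@pytest.fixture(scope="session")
def aroused_session():
    """All channels near their normalised range tops, harsh environment,
    maximum-difficulty task."""
    return constant_session(
        test=dict(hr=140.0, hrv=18.0, eda=4.5, pupil=7.2, gaze="fixation", ecg_amp=2.2),
        environment=EnvironmentRecord(28.0, 90.0, "high"),
        tasks=(TaskSpec(1, 6, 10, "high"),),
        annotations=(TaskAnnotation(1, 0.0, 30.0),),
    )
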