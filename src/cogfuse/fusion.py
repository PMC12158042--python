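"""The four-layer fusion hierarchy and the end-to-end session pipeline.

Layer 2 fuses the normalised channels into five cluster loads (heart, eye,
electrical activity, working environment, manufacturing process); layer 3
fuses clusters into two cognitive-load factors — Extraneous Demands (heart +
manufacturing + environment) and Inconsistent Information Coding (eye +
electrical + manufacturing + environment); layer 4 fuses the two factors into
the Reading dimension.  All nodes are Mamdani systems built here with the
membership geometry of the assessment protocol:

* HR / ECG amplitude on [0, 2], five Gaussians at 0, 0.5, 1, 1.5, 2 with a
  symmetric load reading (1 = at baseline = low load; deviation in either
  direction raises load);
* HRV on [0, 2] with a Pi-shaped "low" set (plateau near 0) plus Gaussian
  medium/high, load-inverted (suppressed HRV = high load);
* pupil / gaze-code / skin conductance on [1, 2], monotone;
* temperature with five Gaussians at 15/19/22/25/28 degC and humidity at
  0.1..0.9, both U-shaped about the comfort center; noise on its 0/0.5/1 codes;
* task items / operations / difficulty on [0, 1], monotone;
* every layer-3/4 input on [0, 1] with three Gaussians at 0.1/0.5/0.9.

The heart branch runs at the ECG rate (1024 Hz), the eye + electrodermal
branch at 32 Hz; the Inconsistent Information Coding signal is upsampled to
1024 Hz before the Reading node.

The eight further layer-3 factors and five layer-4 dimensions of the full
framework have no computational definition here and are deliberate extension
points: any FISConfig wired into an extended LayerGraph slots in unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from cogfuse.core_model import Channel, Session
from cogfuse.fuzzy_engine import (
    FISConfig,
    FuzzyVariable,
    auto_sigma,
    build_monotone_rulebase,
    evaluate_fis,
    evaluate_fis_batch,
    gaussmf,
    output_load_variable,
    pimf,
)
from cogfuse.preprocess import (
    RANGE_CARDIAC,
    RANGE_EYE_EDA,
    NormalizationSpec,
    butter_lowpass,
    encode_difficulty,
    encode_humidity,
    encode_noise,
    gaze_events_to_signal,
    normalize_baseline,
    normalize_task_counts,
    notch_filter,
)

__all__ = [
    "HEART_RATE_HZ",
    "EYE_BRANCH_HZ",
    "LoadSignal",
    "LayerGraph",
    "EyeModel",
    "FusionResult",
    "build_heart_fis",
    "build_eye_fis",
    "build_electrical_fis",
    "build_environment_fis",
    "build_manufacturing_fis",
    "build_layer3_fis",
    "build_reading_fis",
    "build_layer_graph",
    "run_session",
]

HEART_RATE_HZ = 1024.0  # ECG device rate; heart branch and layers 3-4 run here
EYE_BRANCH_HZ = 32.0  # EDA device rate; eye + electrical branch runs here
SMOOTHING_HZ = 0.05  # final low-pass applied to every normalised input
ECG_LOWPASS_HZ = 110.0
EDA_LOWPASS_HZ = 1.0
NOTCH_HZ = 50.0

U_SHAPED_5 = (1.0, 0.5, 0.0, 0.5, 1.0)  # deviation from the center raises load
INVERTED_3 = (1.0, 0.5, 0.0)  # low raw value = high load (HRV)


@dataclass
class LoadSignal:
    """A [0, 1]-bounded load time series emitted by one fusion node."""

    source: str
    sampling_rate: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size and (
            self.samples.min() < -1e-9 or self.samples.max() > 1 + 1e-9
        ):
            raise ValueError(f"load signal {self.source!r} leaves [0, 1]")
        np.clip(self.samples, 0.0, 1.0, out=self.samples)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate

    def mean(self) -> float:
        return float(self.samples.mean())


_L2 = ("heart", "eye", "electrical", "environment", "manufacturing")
_GRAPH_EDGES = {
    "extraneous_demands": ("heart", "manufacturing", "environment"),
    "inconsistent_information_coding": ("eye", "electrical", "manufacturing", "environment"),
    "reading": ("extraneous_demands", "inconsistent_information_coding"),
}


@dataclass(frozen=True)
class LayerGraph:
    """Wiring of the hierarchy; construction asserts the expected topology."""

    layer2: tuple[str, ...] = _L2
    edges: dict = field(default_factory=lambda: dict(_GRAPH_EDGES))

    def __post_init__(self) -> None:
        if set(self.edges["extraneous_demands"]) != {"heart", "manufacturing", "environment"}:
            raise ValueError("Extraneous Demands must fuse heart, manufacturing, environment")
        if set(self.edges["inconsistent_information_coding"]) != {
            "eye", "electrical", "manufacturing", "environment",
        }:
            raise ValueError(
                "Inconsistent Information Coding must fuse eye, electrical, "
                "manufacturing, environment"
            )
        if set(self.edges["reading"]) != {
            "extraneous_demands", "inconsistent_information_coding",
        }:
            raise ValueError("Reading must fuse the two layer-3 factors")


def build_layer_graph() -> LayerGraph:
    return LayerGraph()


def _gauss_bank(labels, centers) -> tuple:
    sigmas = auto_sigma(centers)
    return tuple(gaussmf(l, c, s) for l, c, s in zip(labels, centers, sigmas))


_FIVE = ("very_low", "low", "baseline", "high", "very_high")
_THREE = ("low", "medium", "high")


def build_heart_fis(grid_n: int = 2001) -> FISConfig:
    """Heart cluster: HR + ECG amplitude (symmetric about baseline) + HRV (inverted)."""
    hr = FuzzyVariable(
        "hr", RANGE_CARDIAC, _gauss_bank(_FIVE, [0.0, 0.5, 1.0, 1.5, 2.0]), U_SHAPED_5
    )
    ecg = FuzzyVariable(
        "ecg", RANGE_CARDIAC, _gauss_bank(_FIVE, [0.0, 0.5, 1.0, 1.5, 2.0]), U_SHAPED_5
    )
    # HRV "low" is a Pi plateau hugging zero; "high" peaks at the baseline
    # level 1.0 so resting HRV reads as low load and a suppressed-HRV test
    # value (around half the baseline) fires the high-load rule.
    sig = 0.4 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    hrv = FuzzyVariable(
        "hrv",
        RANGE_CARDIAC,
        (pimf("low", 0.0, 0.0, 0.3, 0.7), gaussmf("medium", 0.7, sig), gaussmf("high", 1.1, sig)),
        INVERTED_3,
    )
    rules = build_monotone_rulebase([U_SHAPED_5, U_SHAPED_5, INVERTED_3])
    return FISConfig("heart", (hr, ecg, hrv), output_load_variable(), rules, grid_n=grid_n)


@dataclass(frozen=True)
class EyeModel:
    """Per-eye FIS pair; the cluster load is the mean of the two eye outputs."""

    left: FISConfig
    right: FISConfig

    def combine(self, left_out: np.ndarray, right_out: np.ndarray | None) -> np.ndarray:
        if right_out is None:
            return np.asarray(left_out, dtype=float)
        return 0.5 * (np.asarray(left_out, dtype=float) + np.asarray(right_out, dtype=float))


def _single_eye_fis(side: str, grid_n: int) -> FISConfig:
    pupil = FuzzyVariable(
        f"pupil_{side}", RANGE_EYE_EDA, _gauss_bank(_THREE, [1.1, 1.5, 1.9])
    )
    gaze = FuzzyVariable(
        "gaze", RANGE_EYE_EDA, _gauss_bank(("saccade", "fixation"), [1.0, 2.0])
    )
    rules = build_monotone_rulebase([3, 2])
    return FISConfig(f"eye_{side}", (pupil, gaze), output_load_variable(), rules, grid_n=grid_n)


def build_eye_fis(grid_n: int = 2001) -> EyeModel:
    """Eye cluster: pupil diameter + gaze-event code per eye, outputs averaged."""
    return EyeModel(_single_eye_fis("left", grid_n), _single_eye_fis("right", grid_n))


def build_electrical_fis(grid_n: int = 2001) -> FISConfig:
    """Electrical-activity cluster: normalised skin conductance on [1, 2]."""
    eda = FuzzyVariable("eda", RANGE_EYE_EDA, _gauss_bank(_THREE, [1.1, 1.5, 1.9]))
    rules = build_monotone_rulebase([[0.0, 0.5, 1.0]])
    return FISConfig("electrical", (eda,), output_load_variable(), rules, grid_n=grid_n)


def build_environment_fis(grid_n: int = 2001) -> FISConfig:
    """Working-environment cluster: temperature and humidity U-shaped about
    the comfort point (22 degC, 50 %), noise monotone on its 0/0.5/1 codes."""
    temperature = FuzzyVariable(
        "temperature", (10.0, 33.0),
        _gauss_bank(("cold", "cool", "comfort", "warm", "hot"), [15.0, 19.0, 22.0, 25.0, 28.0]),
        U_SHAPED_5,
    )
    humidity = FuzzyVariable(
        "humidity", (0.0, 1.0),
        _gauss_bank(("very_dry", "dry", "comfort", "humid", "very_humid"),
                    [0.1, 0.3, 0.5, 0.7, 0.9]),
        U_SHAPED_5,
    )
    noise = FuzzyVariable("noise", (0.0, 1.0), _gauss_bank(_THREE, [0.0, 0.5, 1.0]))
    rules = build_monotone_rulebase([U_SHAPED_5, U_SHAPED_5, [0.0, 0.5, 1.0]])
    return FISConfig(
        "environment", (temperature, humidity, noise), output_load_variable(), rules,
        grid_n=grid_n,
    )


def build_manufacturing_fis(grid_n: int = 2001) -> FISConfig:
    """Manufacturing-process cluster: normalised items, operations, difficulty."""
    mk = lambda name: FuzzyVariable(name, (0.0, 1.0), _gauss_bank(_THREE, [0.1, 0.5, 0.9]))
    rules = build_monotone_rulebase([3, 3, 3])
    return FISConfig(
        "manufacturing", (mk("items"), mk("operations"), mk("difficulty")),
        output_load_variable(), rules, grid_n=grid_n,
    )


def _unit_var(name: str) -> FuzzyVariable:
    """Input bank for a variable that is itself an upstream load signal.

    Uses the same 0.1/0.5/0.9 bank with half-maximum-crossing sigmas as the
    output sets.  Because centroid defuzzification concentrates a node's
    attainable outputs in roughly [0.15, 0.85], successive layers contract
    extreme loads somewhat toward 0.5; sharper fuzzifiers would undo that
    but flatten the gradient around medium load, where most real sessions
    operate, so the half-maximum crossing is kept for sensitivity.
    """
    return FuzzyVariable(name, (0.0, 1.0), _gauss_bank(_THREE, [0.1, 0.5, 0.9]))


def build_layer3_fis(name: str, grid_n: int = 2001) -> FISConfig:
    """Layer-3 factor: Extraneous Demands or Inconsistent Information Coding."""
    graph = build_layer_graph()
    if name not in ("extraneous_demands", "inconsistent_information_coding"):
        raise ValueError(f"unknown layer-3 factor {name!r}")
    inputs = tuple(_unit_var(src) for src in graph.edges[name])
    rules = build_monotone_rulebase([3] * len(inputs))
    return FISConfig(name, inputs, output_load_variable(), rules, grid_n=grid_n)


def build_reading_fis(grid_n: int = 2001) -> FISConfig:
    """Layer-4 Reading dimension fusing the two layer-3 factor loads."""
    inputs = (_unit_var("extraneous_demands"), _unit_var("inconsistent_information_coding"))
    rules = build_monotone_rulebase([3, 3])
    return FISConfig("reading", inputs, output_load_variable(), rules, grid_n=grid_n)


# ---------------------------------------------------------------------------
# End-to-end session pipeline
# ---------------------------------------------------------------------------


@dataclass
class FusionResult:
    reading: LoadSignal
    intermediates: dict[str, LoadSignal]
    config_log: dict


def _fit_length(x: np.ndarray, n: int, what: str) -> np.ndarray:
    if x.size >= n:
        return x[:n]
    if n - x.size <= 1:  # off-by-one from rate rounding
        return np.concatenate([x, np.repeat(x[-1], n - x.size)])
    raise ValueError(f"truncated channel: {what} shorter than the test window")


def _to_grid(x: np.ndarray, fs_in: float, fs_out: float, n_out: int, what: str) -> np.ndarray:
    """Interpolate onto the target sample grid, holding the last value over
    the sub-period tail between the final input sample and the window end."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("cannot resample a single-sample signal")
    span = (x.size - 1) / fs_in
    if span + 1.0 / fs_in + 1e-9 < (n_out - 1) / fs_out:
        raise ValueError(f"truncated channel: {what} shorter than the test window")
    t_in = np.arange(x.size) / fs_in
    t_out = np.arange(n_out) / fs_out
    return np.interp(t_out, t_in, x)


def _smooth(x: np.ndarray, fs: float) -> np.ndarray:
    return butter_lowpass(x, fs, SMOOTHING_HZ)


def _norm_clip(x: np.ndarray, mean: float, rng: tuple[float, float]) -> np.ndarray:
    return normalize_baseline(x, NormalizationSpec(mean, rng))


def _cardiac_input(ch: Channel, base: Channel, n_out: int) -> np.ndarray:
    """HR or RMSSD stream: upsample to 1024 Hz, normalise, smooth, clip."""
    x = _to_grid(ch.samples, ch.sampling_rate, HEART_RATE_HZ, n_out, ch.name)
    x = _norm_clip(x, float(np.mean(base.samples)), RANGE_CARDIAC)
    return np.clip(_smooth(x, HEART_RATE_HZ), *RANGE_CARDIAC)


def _ecg_amplitude(ch: Channel, base: Channel, n_out: int) -> np.ndarray:
    """ECG: notch + 110 Hz low-pass, rectify, extract the slow amplitude
    envelope, normalise by the baseline envelope mean, clip to [0, 2].

    The envelope is taken before dividing by the baseline mean (the two
    commute exactly for a scalar divisor) so that saturation acts on the
    slow amplitude trend rather than on individual beat peaks — a resting
    recording then normalises to 1 like every other channel.
    """

    def envelope(sig: Channel) -> np.ndarray:
        y = notch_filter(sig.samples, sig.sampling_rate, NOTCH_HZ)
        y = butter_lowpass(y, sig.sampling_rate, min(ECG_LOWPASS_HZ, sig.sampling_rate / 2 * 0.99))
        return _smooth(np.abs(y), sig.sampling_rate)

    x = _to_grid(envelope(ch), ch.sampling_rate, HEART_RATE_HZ, n_out, "ecg")
    x = _norm_clip(x, float(np.mean(envelope(base))), RANGE_CARDIAC)
    return x


def _eda_input(ch: Channel, base: Channel, n_out: int) -> np.ndarray:
    x = butter_lowpass(ch.samples, ch.sampling_rate, EDA_LOWPASS_HZ)
    x = _to_grid(x, ch.sampling_rate, EYE_BRANCH_HZ, n_out, "eda")
    x = _norm_clip(x, float(np.mean(base.samples)), RANGE_EYE_EDA)
    return np.clip(_smooth(x, EYE_BRANCH_HZ), *RANGE_EYE_EDA)


def _pupil_input(ch: Channel, base: Channel, n_out: int) -> np.ndarray:
    x = _norm_clip(ch.samples, float(np.mean(base.samples)), RANGE_EYE_EDA)
    x = np.clip(_smooth(x, ch.sampling_rate), *RANGE_EYE_EDA)
    return _to_grid(x, ch.sampling_rate, EYE_BRANCH_HZ, n_out, ch.name)


def _gaze_input(ch: Channel, duration: float, native_fs: float, n_out: int) -> np.ndarray:
    x = gaze_events_to_signal(ch.events, native_fs, duration, t0=ch.events[0][0])
    x = np.clip(_smooth(x, native_fs), *RANGE_EYE_EDA)
    return _to_grid(x, native_fs, EYE_BRANCH_HZ, n_out, "gaze_event")


def _task_step_signal(
    per_task_load: np.ndarray, annotations, fs: float, n_out: int
) -> np.ndarray:
    """Piecewise-constant load over task annotations; holds across gaps and
    before the first task, and keeps the last value after the final task."""
    t = np.arange(n_out) / fs
    starts = np.array([a.start for a in annotations])
    idx = np.searchsorted(starts, t, side="right") - 1
    idx = np.clip(idx, 0, len(annotations) - 1)
    return per_task_load[idx]


def normalized_inputs(session: Session) -> dict[str, tuple[float, np.ndarray]]:
    """Condition every test channel into its fuzzification-ready form.

    Returns ``{name: (sampling_rate, samples)}`` with the cardiac inputs on
    [0, 2] at 1024 Hz and the eye/electrodermal inputs on [1, 2] at 32 Hz.
    """
    session.validate()
    test = session.test
    numeric = [ch for ch in test.values() if ch.kind == "numeric"]
    duration = min(ch.duration for ch in numeric)
    n_hi = int(round(duration * HEART_RATE_HZ))
    n_lo = int(round(duration * EYE_BRANCH_HZ))
    out = {
        "hr": (HEART_RATE_HZ, _cardiac_input(test["hr"], session.baseline["hr"], n_hi)),
        "hrv": (HEART_RATE_HZ, _cardiac_input(test["hrv"], session.baseline["hrv"], n_hi)),
        "ecg": (HEART_RATE_HZ, _ecg_amplitude(test["ecg"], session.baseline["ecg"], n_hi)),
        "eda": (EYE_BRANCH_HZ, _eda_input(test["eda"], session.baseline["eda"], n_lo)),
        "gaze_event": (
            EYE_BRANCH_HZ,
            _gaze_input(test["gaze_event"], duration, test["pupil_left"].sampling_rate, n_lo),
        ),
        "pupil_left": (
            EYE_BRANCH_HZ,
            _pupil_input(test["pupil_left"], session.baseline["pupil_left"], n_lo),
        ),
    }
    if "pupil_right" in test:
        out["pupil_right"] = (
            EYE_BRANCH_HZ,
            _pupil_input(test["pupil_right"], session.baseline["pupil_right"], n_lo),
        )
    return out


def run_session(session: Session, grid_n: int = 2001) -> FusionResult:
    """Run a validated Session through the full hierarchy.

    Returns the Reading load at 1024 Hz plus every intermediate cluster and
    factor signal, and a log of the configuration actually used.
    """
    session.validate()
    test = session.test
    if not session.annotations:
        raise ValueError("manufacturing branch requires task annotations")

    numeric = [ch for ch in test.values() if ch.kind == "numeric"]
    duration = min(ch.duration for ch in numeric)
    ann_end = max(a.end for a in session.annotations)
    if ann_end > duration + 1.0 / EYE_BRANCH_HZ:
        raise ValueError("truncated channel: annotations extend beyond the recorded test")
    n_hi = int(round(duration * HEART_RATE_HZ))
    n_lo = int(round(duration * EYE_BRANCH_HZ))

    heart_fis = build_heart_fis(grid_n)
    eye_model = build_eye_fis(grid_n)
    electrical_fis = build_electrical_fis(grid_n)
    environment_fis = build_environment_fis(grid_n)
    manufacturing_fis = build_manufacturing_fis(grid_n)
    ed_fis = build_layer3_fis("extraneous_demands", grid_n)
    iic_fis = build_layer3_fis("inconsistent_information_coding", grid_n)
    reading_fis = build_reading_fis(grid_n)
    build_layer_graph()  # asserts topology

    inputs = normalized_inputs(session)

    # --- layer 2: heart branch (1024 Hz) ---
    hr_n, hrv_n, ecg_n = inputs["hr"][1], inputs["hrv"][1], inputs["ecg"][1]
    heart = evaluate_fis_batch(heart_fis, np.column_stack([hr_n, ecg_n, hrv_n]))

    # --- layer 2: eye + electrical branch (32 Hz) ---
    eda_n = inputs["eda"][1]
    gaze_n = inputs["gaze_event"][1]
    pl = inputs["pupil_left"][1]
    eye_left = evaluate_fis_batch(eye_model.left, np.column_stack([pl, gaze_n]))
    if "pupil_right" in inputs:
        pr = inputs["pupil_right"][1]
        eye_right = evaluate_fis_batch(eye_model.right, np.column_stack([pr, gaze_n]))
    else:
        eye_right = None
    eye = eye_model.combine(eye_left, eye_right)
    electrical = evaluate_fis_batch(electrical_fis, eda_n[:, None])

    # --- layer 2: manufacturing + environment ---
    items = normalize_task_counts([t.n_items for t in session.tasks])
    ops = normalize_task_counts([t.n_operations for t in session.tasks])
    diff = np.array([encode_difficulty(t.difficulty) for t in session.tasks])
    attempted = [a.index - 1 for a in session.annotations]
    per_task = evaluate_fis_batch(
        manufacturing_fis,
        np.column_stack([items[attempted], ops[attempted], diff[attempted]]),
    )
    manuf_hi = _task_step_signal(per_task, session.annotations, HEART_RATE_HZ, n_hi)
    manuf_lo = _task_step_signal(per_task, session.annotations, EYE_BRANCH_HZ, n_lo)
    env = session.environment
    env_load = evaluate_fis(
        environment_fis,
        [env.temperature, encode_humidity(env.humidity), encode_noise(env.noise)],
    )

    # --- layer 3 ---
    ed = evaluate_fis_batch(
        ed_fis, np.column_stack([heart, manuf_hi, np.full(n_hi, env_load)])
    )
    iic = evaluate_fis_batch(
        iic_fis,
        np.column_stack([eye, electrical, manuf_lo, np.full(n_lo, env_load)]),
    )
    iic_hi = _to_grid(iic, EYE_BRANCH_HZ, HEART_RATE_HZ, n_hi, "iic")
    np.clip(iic_hi, 0.0, 1.0, out=iic_hi)

    # --- layer 4 ---
    reading = evaluate_fis_batch(reading_fis, np.column_stack([ed, iic_hi]))

    intermediates = {
        "heart": LoadSignal("heart", HEART_RATE_HZ, heart),
        "eye_left": LoadSignal("eye_left", EYE_BRANCH_HZ, eye_left),
        "eye": LoadSignal("eye", EYE_BRANCH_HZ, eye),
        "electrical": LoadSignal("electrical", EYE_BRANCH_HZ, electrical),
        "manufacturing": LoadSignal("manufacturing", HEART_RATE_HZ, manuf_hi),
        "environment": LoadSignal("environment", HEART_RATE_HZ, np.full(n_hi, env_load)),
        "extraneous_demands": LoadSignal("extraneous_demands", HEART_RATE_HZ, ed),
        "inconsistent_information_coding": LoadSignal(
            "inconsistent_information_coding", HEART_RATE_HZ, iic_hi
        ),
    }
    if eye_right is not None:
        intermediates["eye_right"] = LoadSignal("eye_right", EYE_BRANCH_HZ, eye_right)

    config_log = {
        "grid_n": grid_n,
        "rates": {"heart_branch_hz": HEART_RATE_HZ, "eye_branch_hz": EYE_BRANCH_HZ},
        "smoothing_hz": SMOOTHING_HZ,
        "fis": {
            cfg.name: cfg.to_dict()
            for cfg in (
                heart_fis, eye_model.left, eye_model.right, electrical_fis,
                environment_fis, manufacturing_fis, ed_fis, iic_fis, reading_fis,
            )
        },
    }
    return FusionResult(
        reading=LoadSignal("reading", HEART_RATE_HZ, reading),
        intermediates=intermediates,
        config_log=config_log,
    )


def all_layer_configs(grid_n: int = 2001) -> dict[str, FISConfig]:
    """Every FIS node in the hierarchy, keyed by name (eye split per side)."""
    eye = build_eye_fis(grid_n)
    return {
        "heart": build_heart_fis(grid_n),
        "eye_left": eye.left,
        "eye_right": eye.right,
        "electrical": build_electrical_fis(grid_n),
        "environment": build_environment_fis(grid_n),
        "manufacturing": build_manufacturing_fis(grid_n),
        "extraneous_demands": build_layer3_fis("extraneous_demands", grid_n),
        "inconsistent_information_coding": build_layer3_fis(
            "inconsistent_information_coding", grid_n
        ),
        "reading": build_reading_fis(grid_n),
    }
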