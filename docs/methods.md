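# Methods

## Model

Cognitive load is estimated by a four-layer hierarchy of Mamdani fuzzy
inference systems (FIS). Each node fuzzifies its crisp inputs through
Gaussian membership functions μ(x) = exp(−(x−c)²/2σ²) or a Pi-shaped spline
(unit plateau with quadratic S-shoulders), fires every rule with the min
t-norm, clips the fired output set with min implication, aggregates with
max, and defuzzifies by the centroid of the aggregate on a uniform grid of
the [0, 1] load domain. The anchors are fixed: 0 = low load (resting
level), 0.5 = medium, 1 = high.

The hierarchy is: five layer-2 clusters (heart, eye, electrical activity,
working environment, manufacturing process) → two layer-3 factors
(Extraneous Demands ← heart + manufacturing + environment; Inconsistent
Information Coding ← eye + electrical + manufacturing + environment) → the
layer-4 Reading dimension ← both factors. The wiring is asserted at build
time; the remaining factors and dimensions of the broader framework are
extension points with no computational definition here.

### Membership geometry

| variable | domain | sets | load reading |
|---|---|---|---|
| HR, ECG amplitude | [0, 2] | 5 Gaussians at 0, 0.5, 1, 1.5, 2 | symmetric: 1 = baseline = low; deviation either way loads |
| HRV (RMSSD) | [0, 2] | Pi low (plateau 0–0.3, foot 0.7), Gaussians at 0.7, 1.1 | inverted: suppressed HRV = high load |
| pupil, EDA | [1, 2] | 3 Gaussians at 1.1, 1.5, 1.9 | monotone |
| gaze code | [1, 2] | Gaussians at 1 (saccade), 2 (fixation) | fixation = higher load |
| temperature | [10, 33] °C | 5 Gaussians at 15, 19, 22, 25, 28 | U-shaped about 22 °C comfort |
| humidity | [0, 1] | 5 Gaussians at 0.1 … 0.9 | U-shaped about 0.5 |
| noise | [0, 1] | Gaussians at its 0 / 0.5 / 1 codes | monotone |
| task items, operations, difficulty | [0, 1] | 3 Gaussians at 0.1, 0.5, 0.9 | monotone |
| all layer-3/4 inputs and every output | [0, 1] | 3 Gaussians at 0.1, 0.5, 0.9 | monotone |

Widths are never free parameters: σ = g / (2√(2 ln 2)), where g is the
distance to the nearest neighbouring center, so adjacent sets cross exactly
at degree 0.5 (the gap is one full width at half maximum). The HRV bank
places "high HRV" at the baseline level 1.0 so that resting HRV reads as
low load and the classic mental-effort signature — RMSSD around half its
baseline — lands on the Pi plateau's shoulder and fires the high-load rule.

### Rule bases

Rules are generated from per-level *load scores*: the default monotone ramp
i/(n−1), a symmetric pattern (1, ½, 0, ½, 1) for baseline-anchored cardiac
variables and the two comfort-centred environment variables, and the
inverted ramp for HRV. A combination of input levels maps to the output
level whose anchor is nearest the mean score; exact ties resolve upward —
conservative for an assistive system. The table is total and provably
monotone in load; monotonicity is re-checked at construction. The policy is
an explicit, replaceable stand-in — each node serialises to YAML (centers,
sigmas, scores, full table) and can be overridden without code changes.

## Preprocessing

Per-channel conditioning, in order:

* **ECG** (1024 Hz): 50 Hz notch (Q = 30, bandwidth ≈ 1.7 Hz) →
  second-order Butterworth low-pass at 110 Hz → rectification and 0.05 Hz
  low-pass, yielding a slow amplitude envelope → division by the baseline
  envelope mean → clip to [0, 2]. The envelope is extracted *before* the
  baseline division (the two commute exactly for a scalar divisor) so
  saturation acts on the amplitude trend rather than on individual beat
  peaks; a resting recording then normalises to 1 like every other channel.
* **HR, RMSSD** (1 Hz): linear upsampling to 1024 Hz → division by the
  baseline mean → clip [0, 2] → 0.05 Hz low-pass.
* **EDA** (32 Hz): 1 Hz second-order Butterworth low-pass → baseline
  division → clip [1, 2] → 0.05 Hz low-pass.
* **Pupils** (100 Hz): baseline division → clip [1, 2] → 0.05 Hz low-pass →
  interpolation to 32 Hz.
* **Gaze events**: event stream → step signal at the pupil rate holding the
  last fixation (2) / saccade (1) code, other labels holding the previous
  value → 0.05 Hz low-pass → 32 Hz.

All filters are applied forward–backward (zero phase) so channels stay
time-aligned across the hierarchy; padding reflects the signal evenly over
at least three filter time constants, without which the 0.05 Hz stage —
whose transient spans many seconds — is dominated by edge artifacts.
Baseline-division clipping saturates rather than rescales: 1 always means
"at the participant's resting level". RMSSD can alternatively be computed
from an RR-interval stream with a sliding window (intervals assigned by
onset time; windows with fewer than two intervals yield a missing marker).

Manufacturing-process inputs are per-test: item and operation counts are
divided by their column maximum, difficulty coded 0/0.5/1. The per-task
load is a step signal over the observed task annotations (half-open
[start, end) windows; the value holds across gaps and before the first
task). Environment is measured once per session and broadcast.

## Numerical choices

* Defuzzification grid: 2001 points on [0, 1]. The centroid's grid error
  converges only linearly (the min/max kinks move with the grid);
  2001 → 4001 changes outputs by < 1e-4, which is the package's target.
* Centroid defuzzification cannot reach the anchors: a fully-fired edge set
  defuzzifies to ≈ 0.16 / 0.84, so each node's outputs live in roughly
  [0.15, 0.85] and successive layers contract extremes somewhat toward 0.5.
  Sharper downstream fuzzifiers would undo the contraction but flatten the
  gradient around medium load, where real sessions operate, and were
  rejected (they made session means saturate at exactly 0.5).
* Mamdani + centroid is monotone only up to a small wrinkle: on random
  ordered input pairs, fewer than 1 % show dips, all below 5e-3, where rule
  dominance switches. This is a property of the method, not a bug.
* The per-eye node has a two-level gaze input, so no "all-medium" prototype
  exists for it; at the gaze midpoint the upward tie-break makes the node
  deliberately asymmetric (≈ 0.59 rather than 0.5).
* Inputs are clipped to their variable domains before fuzzification;
  normalisation has already clipped, so the second clip is idempotent.

## Synthetic sessions

The generator emulates the acquisition protocol: a 3-minute resting
baseline followed by a test segment (≤ 15 min), channels at the device
rates above, and task annotations splitting the test duration
proportionally to per-task operation counts (an optional give-up task
truncates them to emulate drop-out). A single latent arousal scalar
a ∈ [0, 1] shifts the test-phase means: HR × (1 + 0.3a) from 70 bpm,
RMSSD × (1 − 0.5a) from 45 ms, tonic EDA × (1 + 0.6a) from 2 µS plus
Poisson skin-conductance responses (6a per minute, amplitude ~ Exp(0.3 µS),
1 s rise, 3 s exponential decay), pupil × (1 + 0.25a) from 3.5 mm, and the
fixation share of gaze time rising from 0.55 by 0.3a. Channels carry slow
band-limited drift plus white observation noise. The ECG is a
sinusoid-plus-spike proxy with the correct beat rate and an
arousal-scaled amplitude — sufficient for the amplitude-normalisation
branch, with no claim to clinical waveform morphology.

What passing tests therefore show: the pipeline recovers a monotone
arousal → load relationship under controlled, single-factor arousal
structure. What they do not show: robustness to motion artifacts, sensor
drop-out, individual differences in baseline reactivity, or real reading
behaviour — none of which the generator emulates.

Test suites and examples run sessions of 30–120 s (durations are explicit
arguments); the generator's signal-level defaults are the protocol
conditions and are not scaled.

## Known limitations

* The rule policy is literature-agnostic: it encodes only monotonicity in
  load and the 0/0.5/1 anchors, not any empirically fitted interaction.
* The Reading output compresses toward the middle of the scale for deep
  cascades (see above); comparisons between conditions are meaningful,
  absolute values near 0 or 1 are not attainable.
* Only the Reading dimension is computed; the other factors and dimensions
  of the broader framework are named extension points.
* Gaze duration enters only through the event coding; a separate duration
  input is not wired into the eye cluster by default.
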