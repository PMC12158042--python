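"""Inspect a single fusion node: the heart cluster's Mamdani system.

Evaluates the heart fuzzy inference system at interpretable prototypes:
baseline-normalised HR/ECG of 1.0 means "at the participant's resting
level"; HRV (RMSSD) near half its baseline is the classic mental-effort
signature.
"""

from cogfuse import build_heart_fis, evaluate_fis

fis = build_heart_fis()

cases = [
    ("everything at resting baseline", [1.0, 1.0, 1.1]),
    ("HR slightly raised", [1.3, 1.0, 1.1]),
    ("HR raised, HRV halved", [1.3, 1.0, 0.5]),
    ("tachycardia, HRV collapsed", [2.0, 2.0, 0.2]),
    ("bradycardia (deviation also loads)", [0.2, 1.0, 1.1]),
]
for label, x in cases:
    print(f"{label:40s} (hr={x[0]}, ecg={x[1]}, hrv={x[2]}) -> "
          f"load {evaluate_fis(fis, x):.3f}")

print(
    "\nHR and ECG amplitude are symmetric about 1 (any deviation from "
    "baseline raises load); HRV is inverted (suppressed HRV = high load)."
)
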