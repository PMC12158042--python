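"""Task segmentation of load signals and group-level summaries.

The Reading load signal is cut into per-task segments using the observed
task annotations (half-open [start, end) windows, so a boundary sample
belongs to the later task), averaged per task, and aggregated over
participants by experimental scenario or assistance condition.  Completion
rates report, per task index, the fraction of a group's participants whose
annotations reach that task; because tasks are attempted in order the curve
is non-increasing.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from cogfuse.core_model import TaskAnnotation
from cogfuse.fusion import LoadSignal

__all__ = ["segment_by_tasks", "task_means", "group_aggregate", "completion_rate"]


def segment_by_tasks(
    signal: LoadSignal, annotations: Sequence[TaskAnnotation]
) -> list[tuple[int, np.ndarray]]:
    """Cut a load signal into one sub-array per annotated task.

    Sample k (at time k / fs) belongs to task i when start_i <= k/fs < end_i.
    """
    if not annotations:
        raise ValueError("empty annotations: nothing to segment")
    fs = signal.sampling_rate
    n = signal.samples.size
    duration = n / fs
    segments: list[tuple[int, np.ndarray]] = []
    for ann in annotations:
        if ann.end > duration + 0.5 / fs:
            raise ValueError(
                f"annotation out of range: task {ann.index} ends at {ann.end:.3f} s "
                f"but the signal covers {duration:.3f} s"
            )
        i0 = int(np.ceil(ann.start * fs - 1e-9))
        i1 = int(np.ceil(ann.end * fs - 1e-9))
        segments.append((ann.index, signal.samples[i0:min(i1, n)]))
    return segments


def task_means(
    segments: Sequence[tuple[int, np.ndarray]],
    participant_id: str = "anonymous",
    scenario: str = "control",
    assistance: str = "human",
    test_id: str = "test1",
) -> pd.DataFrame:
    """Per-task mean load rows (participant, scenario, assistance, test, task)."""
    rows = []
    for idx, seg in segments:
        seg = np.asarray(seg, dtype=float)
        rows.append(
            {
                "participant_id": participant_id,
                "scenario": scenario,
                "assistance": assistance,
                "test_id": test_id,
                "task_index": idx,
                "mean_load": float(seg.mean()) if seg.size else np.nan,
                "n_samples": int(seg.size),
            }
        )
    return pd.DataFrame(rows)


def group_aggregate(table: pd.DataFrame, by: str = "scenario") -> pd.DataFrame:
    """Per-(group, test, task) mean and sample SD of participant task means.

    Cells with a single contributing participant report SD = 0 and are
    flagged (``single_participant``); empty groups simply do not appear.
    """
    if by not in ("scenario", "assistance"):
        raise ValueError("by must be 'scenario' or 'assistance'")
    rows = []
    for (grp, test, task), sub in table.groupby([by, "test_id", "task_index"], sort=True):
        vals = sub["mean_load"].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            continue
        rows.append(
            {
                by: grp,
                "test_id": test,
                "task_index": task,
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                "n": int(vals.size),
                "single_participant": vals.size == 1,
            }
        )
    return pd.DataFrame(rows)


def completion_rate(
    annotations_by_participant: Mapping[str, Sequence[TaskAnnotation]],
    n_tasks: int,
    group_labels: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Fraction of each group's participants reaching each task index."""
    if n_tasks < 1:
        raise ValueError("n_tasks must be at least 1")
    group_labels = group_labels or {p: "all" for p in annotations_by_participant}
    rows = []
    groups = sorted(set(group_labels.values()))
    for grp in groups:
        members = [p for p in annotations_by_participant if group_labels[p] == grp]
        if not members:
            continue
        for task in range(1, n_tasks + 1):
            done = sum(
                any(a.index == task for a in annotations_by_participant[p])
                for p in members
            )
            rows.append(
                {"group": grp, "task_index": task, "rate": done / len(members),
                 "n_participants": len(members)}
            )
    return pd.DataFrame(rows)
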