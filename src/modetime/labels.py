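"""Turn trajectories into labelled regression data and ensemble statistics.

Dissociation is declared at the first frame whose C-C distance exceeds the
threshold (2.4 A by default); times are resolved at frame resolution, not
interpolated.  Censored trajectories (never crossing within the simulated
window) are marked with ``CENSORED`` (+inf) and yield no training frames.

Frame labels are the time *remaining* until dissociation, so that every frame
acts as an initial condition for the prediction; a switch selects the total
trajectory dissociation time instead.

The ensemble half-time is the ceil(n/2)-th smallest dissociation time — the
first time at which half of the trajectories have dissociated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from modetime.dynamics import DISSOCIATION_THRESHOLD, Trajectory

__all__ = [
    "CENSORED",
    "LabeledFrame",
    "FrustrationCount",
    "dissociation_time",
    "count_frustrated",
    "frustration_summary",
    "extract_frames",
    "label_study",
    "frames_to_dataframe",
    "half_time",
]

CENSORED = math.inf
"""Marker for a trajectory that never crossed the dissociation threshold."""


@dataclass
class LabeledFrame:
    """One regression example: mode-space features and time-to-dissociation."""

    features: np.ndarray
    label: float  # fs remaining until dissociation (or total time; see extract_frames)
    trajectory_id: int
    frame_time: float


@dataclass
class FrustrationCount:
    """Per-trajectory frustrated-dissociation counts and their ensemble mean."""

    counts: np.ndarray
    mean: float


def dissociation_time(
    trajectory: Trajectory, threshold: float = DISSOCIATION_THRESHOLD
) -> float:
    """Time (fs) of the first frame whose C-C distance exceeds ``threshold``.

    Returns ``CENSORED`` if the threshold is never exceeded.
    """
    cc = np.asarray(trajectory.cc_distance)
    if cc.size == 0:
        raise ValueError("empty trajectory")
    above = np.flatnonzero(cc > threshold)
    if above.size == 0:
        return CENSORED
    return float(trajectory.times[above[0]])


def _compress_plateaus(cc: np.ndarray) -> np.ndarray:
    """Drop consecutive duplicates so local extrema are strict."""
    if cc.size == 0:
        return cc
    keep = np.ones(cc.size, dtype=bool)
    keep[1:] = cc[1:] != cc[:-1]
    return cc[keep]


def count_frustrated(
    trajectory: Trajectory,
    attempt_threshold: float = 2.0,
    recede_delta: float = 0.1,
    threshold: float = DISSOCIATION_THRESHOLD,
) -> int:
    """Count frustrated dissociations before the first successful crossing.

    A frustrated dissociation is a local maximum of the C-C distance that
    (i) exceeds ``attempt_threshold``, (ii) stays at or below the dissociation
    ``threshold`` and (iii) recedes by at least ``recede_delta`` A before the
    next rise (or the end of the pre-crossing series).
    """
    if attempt_threshold >= threshold:
        raise ValueError(
            f"attempt_threshold ({attempt_threshold}) must be below the "
            f"dissociation threshold ({threshold})"
        )
    cc = np.asarray(trajectory.cc_distance, dtype=float)
    if cc.size == 0:
        raise ValueError("empty trajectory")
    above = np.flatnonzero(cc > threshold)
    if above.size:
        cc = cc[: above[0]]  # events strictly before the successful crossing
    cc = _compress_plateaus(cc)
    count = 0
    i = 1
    while i < cc.size:
        is_peak = i < cc.size - 1 and cc[i] > cc[i - 1] and cc[i] > cc[i + 1]
        if is_peak and cc[i] > attempt_threshold:
            # walk down to the following local minimum (or series end)
            j = i + 1
            while j + 1 < cc.size and cc[j + 1] < cc[j]:
                j += 1
            if cc[i] - cc[j] >= recede_delta:
                count += 1
            i = j
        else:
            i += 1
    return count


def frustration_summary(
    trajectories: Sequence[Trajectory],
    attempt_threshold: float = 2.0,
    recede_delta: float = 0.1,
    threshold: float = DISSOCIATION_THRESHOLD,
) -> FrustrationCount:
    """Per-trajectory frustrated-dissociation counts and their mean."""
    counts = np.array(
        [
            count_frustrated(t, attempt_threshold, recede_delta, threshold)
            for t in trajectories
        ]
    )
    return FrustrationCount(counts=counts, mean=float(counts.mean()))


def extract_frames(
    trajectory: Trajectory,
    stride: int = 5,
    with_velocities: bool = False,
    trajectory_id: int = 0,
    threshold: float = DISSOCIATION_THRESHOLD,
    label_mode: str = "remaining",
) -> list[LabeledFrame]:
    """Extract every ``stride``-th frame strictly before dissociation.

    ``label_mode='remaining'`` labels each frame with the time left until the
    dissociation frame; ``'total'`` labels every frame with the trajectory's
    dissociation time.  Censored trajectories yield no frames.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if label_mode not in ("remaining", "total"):
        raise ValueError(f"unknown label_mode {label_mode!r}")
    cc = np.asarray(trajectory.cc_distance)
    above = np.flatnonzero(cc > threshold)
    if above.size == 0:
        return []
    k_diss = int(above[0])
    t_diss = float(trajectory.times[k_diss])
    frames = []
    for k in range(0, k_diss, stride):
        if with_velocities:
            feats = np.concatenate([trajectory.r_frames[k], trajectory.v_frames[k]])
        else:
            feats = trajectory.r_frames[k].copy()
        t_k = float(trajectory.times[k])
        label = t_diss - t_k if label_mode == "remaining" else t_diss
        frames.append(
            LabeledFrame(
                features=feats,
                label=label,
                trajectory_id=trajectory_id,
                frame_time=t_k,
            )
        )
    return frames


def label_study(
    trajectories: Iterable[Trajectory],
    stride: int = 5,
    with_velocities: bool = False,
    threshold: float = DISSOCIATION_THRESHOLD,
    label_mode: str = "remaining",
) -> pd.DataFrame:
    """Extract labelled frames from every trajectory into one DataFrame."""
    all_frames: list[LabeledFrame] = []
    n_modes = None
    for tid, traj in enumerate(trajectories):
        n_modes = traj.r_frames.shape[1]
        all_frames.extend(
            extract_frames(
                traj, stride, with_velocities, trajectory_id=tid,
                threshold=threshold, label_mode=label_mode,
            )
        )
    if n_modes is None:
        raise ValueError("no trajectories given")
    return frames_to_dataframe(all_frames, n_modes, with_velocities)


def frames_to_dataframe(
    frames: Sequence[LabeledFrame], n_modes: int, with_velocities: bool
) -> pd.DataFrame:
    """Tabulate labelled frames: id, time, label, then r_0.. (and v_0..) columns."""
    cols = [f"r_{i}" for i in range(n_modes)]
    if with_velocities:
        cols += [f"v_{i}" for i in range(n_modes)]
    feats = np.array([f.features for f in frames]).reshape(len(frames), len(cols))
    df = pd.DataFrame(feats, columns=cols)
    df.insert(0, "trajectory_id", [f.trajectory_id for f in frames])
    df.insert(1, "frame_time", [f.frame_time for f in frames])
    df.insert(2, "label", [f.label for f in frames])
    return df


def half_time(times: Iterable[float]) -> float:
    """The ceil(n/2)-th smallest dissociation time (fs).

    Censored entries (``CENSORED`` = +inf) sort last; if more than half of the
    ensemble is censored the half-time itself is censored and ``CENSORED`` is
    returned.
    """
    arr = np.sort(np.asarray(list(times), dtype=float))
    if arr.size == 0:
        raise ValueError("half_time of an empty collection")
    k = (arr.size + 1) // 2  # ceil(n/2)
    return float(arr[k - 1])
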