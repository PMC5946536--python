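"""Training-session labelling protocol and the rehabilitation MAV-grid analysis.

Classifier training follows the prompted protocol: the five motions are held
back to back, about 7 s each (~35 s total); the first 4 s of every segment
is discarded to keep transient onsets out of the training set and the last
3 s is windowed and labelled.

The rehabilitation assessment summarizes weekly recordings as a motions x
channels grid of average MAV: entry (m, c) is the mean, over sessions, of
channel c's MAV while motion m was held. With independent signals the grid
is diagonally dominant column-wise; the per-motion independence score
quantifies that dominance (score > 1 means the intended motion produces the
largest amplitude on its own channel).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ParameterError, ProtocolError
from .features import DEFAULT_EPS, feature_matrix, mav
from .signal_io import (DEFAULT_BAND, DEFAULT_OVERLAP, DEFAULT_WINDOW_MS,
                        AnalysisWindow, EMGRecording, bandpass, window_params)

#: the five prosthesis motions, in channel order Ch1..Ch5
DEFAULT_MOTIONS = ("hand close", "hand open", "wrist rotation",
                   "elbow flexion", "elbow extension")


@dataclass
class SessionPlan:
    """Prompted training-session layout: motion order and per-motion timing."""

    motion_order: tuple[str, ...] = DEFAULT_MOTIONS
    per_motion_s: float = 7.0
    trim_head_s: float = 4.0
    keep_s: float = 3.0

    def __post_init__(self) -> None:
        self.motion_order = tuple(self.motion_order)
        if len(set(self.motion_order)) != len(self.motion_order):
            raise ParameterError("motion_order contains duplicates")
        if self.trim_head_s + self.keep_s > self.per_motion_s + 1e-9:
            raise ParameterError(
                f"trim {self.trim_head_s}s + keep {self.keep_s}s exceeds the "
                f"{self.per_motion_s}s motion segment"
            )

    @property
    def total_s(self) -> float:
        return self.per_motion_s * len(self.motion_order)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SessionPlan":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(tuple(data.get("motion_order", DEFAULT_MOTIONS)),
                   float(data.get("per_motion_s", 7.0)),
                   float(data.get("trim_head_s", 4.0)),
                   float(data.get("keep_s", 3.0)))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"motion_order": list(self.motion_order),
                            "per_motion_s": self.per_motion_s,
                            "trim_head_s": self.trim_head_s,
                            "keep_s": self.keep_s}, fh)


def extract_training_set(rec: EMGRecording, plan: SessionPlan,
                         window_ms: float = DEFAULT_WINDOW_MS,
                         overlap_frac: float = DEFAULT_OVERLAP,
                         eps: float = DEFAULT_EPS,
                         band: tuple[float, float] | None = DEFAULT_BAND,
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Labelled feature matrix from a prompted training-session recording.

    For each motion segment the head is discarded, the kept tail is windowed
    and featured, and every window inherits the segment's motion label.
    Returns (X, y) ready for :func:`emgpr.lda.fit_lda`.
    """
    needed = int(round(plan.total_s * rec.fs))
    if rec.n_samples < needed:
        raise ProtocolError(
            f"recording has {rec.n_samples} samples but the plan needs {needed}"
        )
    filtered = bandpass(rec, *band) if band is not None else rec
    length, step = window_params(rec.fs, window_ms, overlap_frac)
    X_parts, y_parts = [], []
    for k, motion in enumerate(plan.motion_order):
        seg_start = int(round(k * plan.per_motion_s * rec.fs))
        keep_start = seg_start + int(round(plan.trim_head_s * rec.fs))
        keep_end = keep_start + int(round(plan.keep_s * rec.fs))
        segment = filtered.samples[keep_start:keep_end]
        windows = [AnalysisWindow(segment[s:s + length], keep_start + s, rec.fs)
                   for s in range(0, segment.shape[0] - length + 1, step)]
        Xm, _ = feature_matrix(windows, eps)
        X_parts.append(Xm)
        y_parts.append(np.full(Xm.shape[0], motion, dtype=object))
    return np.vstack(X_parts), np.concatenate(y_parts)


@dataclass
class MAVGrid:
    """Motions x channels matrix of session-averaged MAV, in mV."""

    values: np.ndarray
    n_sessions: int
    motion_order: tuple[str, ...]
    channel_order: tuple[str, ...]
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.motion_order),
                            columns=list(self.channel_order))

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, float_format="%.6g")


def mav_grid(recordings: Sequence[EMGRecording],
             motions: Sequence[str] = DEFAULT_MOTIONS,
             window_ms: float = DEFAULT_WINDOW_MS,
             overlap_frac: float = DEFAULT_OVERLAP) -> MAVGrid:
    """Average-MAV grid over annotated assessment sessions.

    Each session must annotate one held contraction per motion; entry (m, c)
    averages channel c's windowed MAV over motion m's hold, then over
    sessions. Rest gaps between holds are not annotated and do not enter the
    grid. Amplitudes are taken from the recording as stored (the acquisition
    hardware is already band-limited).
    """
    if not recordings:
        raise ProtocolError("mav_grid needs at least one session recording")
    channels = tuple(recordings[0].channel_labels)
    grids = []
    for rec in recordings:
        by_motion = {a.motion: a for a in rec.annotations}
        length, step = window_params(rec.fs, window_ms, overlap_frac)
        session = np.empty((len(motions), len(channels)))
        for i, motion in enumerate(motions):
            if motion not in by_motion:
                raise ProtocolError(f"session is missing a hold for {motion!r}")
            a = by_motion[motion]
            segment = rec.samples[a.start:a.end]
            starts = range(0, segment.shape[0] - length + 1, step)
            if not starts:
                raise ProtocolError(f"hold for {motion!r} shorter than one window")
            window_mavs = np.array(
                [[mav(segment[s:s + length, c]) for c in range(len(channels))]
                 for s in starts]
            )
            session[i] = window_mavs.mean(axis=0)
        grids.append(session)
    values = np.mean(grids, axis=0)
    return MAVGrid(values, len(recordings), tuple(motions), channels,
                   meta={"normalization": "none (mV); plots normalize per grid"})


def independence_score(g: MAVGrid,
                       target_channel: dict[str, str] | None = None,
                       ) -> dict[str, float]:
    """Per-motion dominance of the intended motion on its own channel.

    For motion m with designated channel c(m):
    ``g[m, c(m)] / max over other motions m' of g[m', c(m)]``. A score > 1
    means amplitude-based control can separate that motion on its channel;
    coupled signals push the score toward (or below) 1. Degenerate columns:
    +inf when only the intended motion activates the channel, NaN when the
    whole column is zero.
    """
    if target_channel is None:
        target_channel = dict(zip(g.motion_order, g.channel_order))
    scores: dict[str, float] = {}
    for i, motion in enumerate(g.motion_order):
        c = g.channel_order.index(target_channel[motion])
        column = g.values[:, c]
        own = column[i]
        others = np.delete(column, i)
        best_other = others.max() if others.size else 0.0
        if own == 0.0 and best_other == 0.0:
            scores[motion] = float("nan")
        elif best_other == 0.0:
            scores[motion] = float("inf")
        else:
            scores[motion] = float(own / best_other)
    return scores


def plot_grid(g: MAVGrid, path: str | Path) -> None:
    """Grey-scale block plot of the grid (normalized per grid), saved to file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    vmax = g.values.max() or 1.0
    ax.imshow(g.values / vmax, cmap="gray_r", vmin=0, vmax=1)
    ax.set_xticks(range(len(g.channel_order)), g.channel_order)
    ax.set_yticks(range(len(g.motion_order)), g.motion_order)
    ax.set_title(f"Average MAV over {g.n_sessions} session(s)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
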