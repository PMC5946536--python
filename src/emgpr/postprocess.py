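"""Decision-stream post-processing: majority vote and MAV threshold switches.

A raw classifier emits one motion per analysis window, including during
contraction onsets/offsets where its features match no trained class —
exactly where real-time control misfires. Two smoothers are provided:

* **Majority vote** replaces each decision with the modal label of the last
  L decisions (queue lengths 3, 5 and 10 in the functional tests).
* **MAV-based threshold switch**: emit the classified motion only if the MAV
  of that motion's designated channel exceeds its per-motion threshold
  (D_i = V_i - T_i > 0); otherwise the prosthesis stays STILL. Because the
  transient state has low amplitude, this suppresses onset misfires without
  adding a vote queue's latency.

STILL is an output token only — the classifier is never trained on a rest
class.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, ParameterError
from .features import DEFAULT_EPS, feature_matrix
from .lda import LDAModel, predict
from .signal_io import (DEFAULT_BAND, DEFAULT_OVERLAP, DEFAULT_WINDOW_MS,
                        EMGRecording, bandpass, window_iter, window_params)

#: output token for "prosthesis stays still"; never a classifier class
STILL = "STILL"

#: the standard per-motion threshold set (mV) that worked well in practice:
#: 0.2 mV on every channel except the lower-amplitude wrist-rotation
#: (deltoid) channel at 0.1 mV
STANDARD_THRESHOLDS = {
    "hand close": 0.2,
    "hand open": 0.2,
    "wrist rotation": 0.1,
    "elbow flexion": 0.2,
    "elbow extension": 0.2,
}


@dataclass
class ThresholdConfig:
    """Per-motion MAV thresholds T_i in mV."""

    thresholds: dict[str, float]
    name: str = "custom"

    def __post_init__(self) -> None:
        for motion, t in self.thresholds.items():
            if not t > 0:
                raise ParameterError(f"threshold for {motion!r} must be > 0, got {t}")

    def __getitem__(self, motion: str) -> float:
        try:
            return self.thresholds[motion]
        except KeyError:
            raise ConfigError(f"no threshold configured for motion {motion!r}")

    @classmethod
    def standard(cls) -> "ThresholdConfig":
        return cls(dict(STANDARD_THRESHOLDS), name="ST")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ThresholdConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if isinstance(data, dict) and "thresholds" in data:
            return cls({m: float(t) for m, t in data["thresholds"].items()},
                       name=data.get("name", "custom"))
        return cls({m: float(t) for m, t in data.items()})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"name": self.name, "thresholds": self.thresholds}, fh)


def derive_thresholds(st: ThresholdConfig, factor: float,
                      name: str | None = None) -> ThresholdConfig:
    """Scale every threshold by `factor` (0.8 -> LT, 1.2 -> HT)."""
    if not factor > 0:
        raise ParameterError(f"scale factor must be > 0, got {factor}")
    if name is None:
        name = {0.8: "LT", 1.2: "HT"}.get(factor, f"{st.name}x{factor:g}")
    return ThresholdConfig({m: t * factor for m, t in st.thresholds.items()}, name)


@dataclass
class Decision:
    """One post-processed window decision.

    ``raw_class`` is the classifier output C_i, ``mav`` the MAV V_i (mV) of
    the classified motion's channel, ``output`` the final command M_i — the
    raw class, a vote-smoothed class, or STILL.
    """

    window_start: int
    raw_class: str
    mav: float
    output: str


@dataclass
class DecisionStream:
    """Per-window decisions with the window grid they live on."""

    decisions: list[Decision]
    fs: float
    window_len: int
    step: int
    mode: str = "none"

    @property
    def outputs(self) -> list[str]:
        return [d.output for d in self.decisions]

    @property
    def raw(self) -> list[str]:
        return [d.raw_class for d in self.decisions]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "window_start": [d.window_start for d in self.decisions],
                "raw_class": [d.raw_class for d in self.decisions],
                "mav_mv": [d.mav for d in self.decisions],
                "output": [d.output for d in self.decisions],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# fs_hz={self.fs:.9g} window_len={self.window_len} "
                     f"step={self.step} mode={self.mode}\n")
            self.to_frame().to_csv(fh, index=False, float_format="%.9g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "DecisionStream":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("#"):
                raise ConfigError(f"{path} is missing the stream metadata line")
            meta = dict(tok.split("=", 1) for tok in header[1:].split())
            frame = pd.read_csv(fh)
        decisions = [
            Decision(int(r.window_start), str(r.raw_class), float(r.mav_mv),
                     str(r.output))
            for r in frame.itertuples()
        ]
        return cls(decisions, float(meta["fs_hz"]), int(meta["window_len"]),
                   int(meta["step"]), meta.get("mode", "none"))


def threshold_switch(c: str, mav_by_motion: Mapping[str, float],
                     cfg: ThresholdConfig, window_start: int = 0) -> Decision:
    """Gate one raw decision on the classified motion's channel MAV.

    D_i = V_i - T_i; the motion is emitted only for strictly positive D_i
    ("higher than" the threshold), so V_i == T_i stays STILL.
    """
    if c not in mav_by_motion:
        raise ConfigError(f"no MAV available for classified motion {c!r}")
    v = float(mav_by_motion[c])
    t = cfg[c]
    return Decision(window_start, c, v, c if v - t > 0 else STILL)


def majority_vote(stream: Sequence[str], L: int,
                  labels: Sequence[str] | None = None) -> list[str]:
    """Smooth a decision stream with a length-L modal queue.

    Output t is the modal label of the last min(t+1, L) raw decisions,
    current included. Ties go to the previous output if it is among the
    modes, else to the earliest mode in label order (sorted order when no
    label order is given).
    """
    if L < 1:
        raise ParameterError(f"queue length must be >= 1, got {L}")
    order = {lab: i for i, lab in enumerate(labels)} if labels is not None else None
    queue: deque[str] = deque(maxlen=L)
    out: list[str] = []
    prev: str | None = None
    for c in stream:
        queue.append(c)
        counts: dict[str, int] = {}
        for lab in queue:
            counts[lab] = counts.get(lab, 0) + 1
        top = max(counts.values())
        modes = [lab for lab, n in counts.items() if n == top]
        if prev is not None and prev in modes:
            choice = prev
        elif order is not None:
            choice = min(modes, key=lambda lab: order.get(lab, len(order)))
        else:
            choice = min(modes)
        out.append(choice)
        prev = choice
    return out


def run_pipeline(rec: EMGRecording, model: LDAModel, mode: str = "none",
                 vote_len: int | None = None,
                 thresholds: ThresholdConfig | None = None,
                 window_ms: float = DEFAULT_WINDOW_MS,
                 overlap_frac: float = DEFAULT_OVERLAP,
                 eps: float = DEFAULT_EPS,
                 band: tuple[float, float] | None = DEFAULT_BAND) -> DecisionStream:
    """Full offline pipeline: filter -> window -> features -> LDA -> post-process.

    mode is one of "none" (raw classifier output), "vote" (majority vote of
    length `vote_len`) or "threshold" (MAV threshold switches with
    `thresholds`). V_i is measured on the same band-passed window the
    features came from.
    """
    if model.n_features != 4 * rec.n_channels:
        raise ConfigError(
            f"model expects {model.n_features} features but recording has "
            f"{rec.n_channels} channels (-> {4 * rec.n_channels})"
        )
    model_channels = model.layout.get("channel_labels")
    if model_channels is not None and list(model_channels) != rec.channel_labels:
        raise ConfigError("model feature layout does not match recording channels")
    if mode not in ("none", "vote", "threshold"):
        raise ParameterError(f"unknown mode {mode!r}")
    if mode == "vote" and (vote_len is None or vote_len < 1):
        raise ParameterError("mode='vote' needs a queue length vote_len >= 1")
    if mode == "threshold" and thresholds is None:
        raise ParameterError("mode='threshold' needs a ThresholdConfig")

    filtered = bandpass(rec, *band) if band is not None else rec
    X, fvs = feature_matrix(window_iter(filtered, window_ms, overlap_frac), eps)
    length, step = window_params(rec.fs, window_ms, overlap_frac)
    if not fvs:
        return DecisionStream([], rec.fs, length, step, mode)
    raw = predict(model, X)
    channel_of = {m: rec.channel_index(rec.motion_channel(m)) for m in model.labels}

    decisions: list[Decision] = []
    if mode == "threshold":
        for c, fv in zip(raw, fvs):
            mav_by_motion = {m: fv.mav_by_channel[idx]
                             for m, idx in channel_of.items()}
            decisions.append(
                threshold_switch(c, mav_by_motion, thresholds, fv.window_start)
            )
    else:
        outputs = raw if mode == "none" else majority_vote(raw, vote_len,
                                                           labels=model.labels)
        for c, o, fv in zip(raw, outputs, fvs):
            v = float(fv.mav_by_channel[channel_of[c]])
            decisions.append(Decision(fv.window_start, c, v, o))
    if mode == "vote":
        label = f"vote:{vote_len}"
    elif mode == "threshold":
        label = f"threshold:{thresholds.name}"
    else:
        label = "none"
    return DecisionStream(decisions, rec.fs, length, step, label)
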