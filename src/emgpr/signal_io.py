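"""Reading, writing, filtering and windowing of multichannel sEMG recordings.

A recording is a dense (n_samples, n_channels) array of amplitudes in mV with
a sampling rate, ordered channel labels, a bijective channel->motion map (the
five reinnervated sites each drive one prosthesis motion), and optional
ground-truth annotations. On disk it is a plain CSV (one column per channel,
header row = channel labels) plus a JSON sidecar carrying the metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import ConfigError, FormatError, ParameterError

#: analysis window length used throughout, in milliseconds
DEFAULT_WINDOW_MS = 137.6
#: fraction of each window shared with its successor
DEFAULT_OVERLAP = 0.5
#: band retained for the real-time control path, Hz
DEFAULT_BAND = (80.0, 400.0)


class Annotation(NamedTuple):
    """Half-open ground-truth interval ``[start, end)`` in samples."""

    motion: str
    start: int
    end: int


@dataclass
class EMGRecording:
    """Multichannel surface-EMG recording in mV.

    Parameters
    ----------
    samples
        Array of shape (n_samples, n_channels).
    fs
        Sampling rate in Hz.
    channel_labels
        Ordered channel names, e.g. ``["Ch1", ..., "Ch5"]``.
    motion_map
        Bijection channel label -> motion name. Channel k's amplitude gates
        motion k in amplitude-based control and in threshold switching.
    annotations
        Optional non-overlapping intervals labelling intended motions.
    """

    samples: np.ndarray
    fs: float
    channel_labels: list[str]
    motion_map: dict[str, str]
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise FormatError("samples must be a 2-D (n_samples, n_channels) array")
        if self.fs <= 0:
            raise ConfigError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channel_labels) != self.samples.shape[1]:
            raise FormatError(
                f"{len(self.channel_labels)} channel labels for "
                f"{self.samples.shape[1]} data columns"
            )
        if set(self.motion_map) != set(self.channel_labels):
            raise ConfigError("motion_map keys must equal the channel labels")
        motions = list(self.motion_map.values())
        if len(set(motions)) != len(motions):
            raise ConfigError("motion_map must be a bijection (duplicate motion)")
        self.annotations = [Annotation(*a) for a in self.annotations]
        n = self.samples.shape[0]
        prev_end = None
        for ann in sorted(self.annotations, key=lambda a: a.start):
            if not (0 <= ann.start < ann.end <= n):
                raise ConfigError(f"annotation {ann} outside recording of {n} samples")
            if prev_end is not None and ann.start < prev_end:
                raise ConfigError(f"annotation {ann} overlaps its predecessor")
            prev_end = ann.end

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, label: str) -> int:
        return self.channel_labels.index(label)

    def motion_channel(self, motion: str) -> str:
        """Label of the channel that gates `motion` (inverse of motion_map)."""
        for ch, m in self.motion_map.items():
            if m == motion:
                return ch
        raise ConfigError(f"motion {motion!r} not present in motion_map")


@dataclass
class AnalysisWindow:
    """One analysis window: (length, n_channels) segment plus provenance."""

    data: np.ndarray
    start_sample: int
    fs: float

    @property
    def length_samples(self) -> int:
        return self.data.shape[0]


def window_params(fs: float, window_ms: float = DEFAULT_WINDOW_MS,
                  overlap_frac: float = DEFAULT_OVERLAP) -> tuple[int, int]:
    """Window length and hop in samples.

    Length = round(window_ms * fs / 1000); hop = round(length * (1 - overlap)).
    At the embedded controller's 1860 Hz the 137.6 ms window is exactly 256
    samples with a 128-sample hop.
    """
    if not 0 <= overlap_frac < 1:
        raise ParameterError(f"overlap_frac must be in [0, 1), got {overlap_frac}")
    length = int(round(window_ms * fs / 1000.0))
    step = int(round(length * (1.0 - overlap_frac)))
    if length < 1 or step < 1:
        raise ParameterError("window too short for this sampling rate")
    return length, step


def window_iter(rec: EMGRecording, window_ms: float = DEFAULT_WINDOW_MS,
                overlap_frac: float = DEFAULT_OVERLAP) -> Iterator[AnalysisWindow]:
    """Yield overlapping analysis windows; a trailing partial window is dropped.

    A recording shorter than one window yields nothing (empty stream, not an
    error): the controller simply has no decision yet.
    """
    length, step = window_params(rec.fs, window_ms, overlap_frac)
    for start in range(0, rec.n_samples - length + 1, step):
        yield AnalysisWindow(rec.samples[start:start + length], start, rec.fs)


def bandpass(rec: EMGRecording, low_hz: float = DEFAULT_BAND[0],
             high_hz: float = DEFAULT_BAND[1], order: int = 4,
             zero_phase: bool = True) -> EMGRecording:
    """Band-pass filter every channel with a Butterworth filter.

    Offline analysis uses the zero-phase forward-backward pass (no group
    delay); ``zero_phase=False`` gives the causal single-pass realization a
    streaming controller would run.
    """
    filtered = bandpass_array(rec.samples, rec.fs, low_hz, high_hz,
                              order=order, zero_phase=zero_phase)
    return EMGRecording(filtered, rec.fs, list(rec.channel_labels),
                        dict(rec.motion_map), list(rec.annotations))


def bandpass_array(x: np.ndarray, fs: float, low_hz: float, high_hz: float,
                   order: int = 4, zero_phase: bool = True) -> np.ndarray:
    """Butterworth band-pass along axis 0 of `x`."""
    nyq = fs / 2.0
    if not 0 < low_hz < high_hz < nyq:
        raise ParameterError(
            f"band ({low_hz}, {high_hz}) Hz invalid for Nyquist {nyq} Hz"
        )
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    if zero_phase:
        return sps.sosfiltfilt(sos, x, axis=0)
    return sps.sosfilt(sos, x, axis=0)


# ---------------------------------------------------------------------------
# file I/O: CSV samples + JSON sidecar


def read_recording(path: str | Path, sidecar: str | Path) -> EMGRecording:
    """Load a recording from a CSV sample file and its JSON sidecar.

    The CSV has one header row of channel labels and one row per sample;
    amplitudes are interpreted as mV. The sidecar supplies ``fs_hz``,
    ``motion_map``, optionally ``channel_labels`` (must then match the CSV
    header) and ``annotations`` (list of {motion, start, end}, 0-based,
    half-open).
    """
    try:
        frame = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse recording file {path}: {exc}") from exc
    if frame.isna().any().any():
        raise FormatError(f"recording file {path} has missing/ragged values")
    with open(sidecar) as fh:
        meta = json.load(fh)
    fs = meta.get("fs_hz")
    if fs is None or not fs > 0:
        raise ConfigError(f"sidecar {sidecar} must define a positive fs_hz")
    labels = list(meta.get("channel_labels", frame.columns))
    if list(frame.columns) != labels:
        raise FormatError(
            f"sidecar channel_labels {labels} do not match CSV header "
            f"{list(frame.columns)}"
        )
    annotations = [Annotation(a["motion"], int(a["start"]), int(a["end"]))
                   for a in meta.get("annotations", [])]
    return EMGRecording(frame.to_numpy(dtype=float), float(fs), labels,
                        dict(meta["motion_map"]), annotations)


def write_recording(rec: EMGRecording, path: str | Path,
                    sidecar: str | Path) -> None:
    """Write the CSV sample file and JSON sidecar read back by read_recording."""
    frame = pd.DataFrame(rec.samples, columns=rec.channel_labels)
    frame.to_csv(path, index=False, float_format="%.9g")
    meta = {
        "fs_hz": rec.fs,
        "channel_labels": rec.channel_labels,
        "motion_map": rec.motion_map,
        "annotations": [
            {"motion": a.motion, "start": a.start, "end": a.end}
            for a in rec.annotations
        ],
    }
    with open(sidecar, "w") as fh:
        json.dump(meta, fh, indent=1)
        fh.write("\n")
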