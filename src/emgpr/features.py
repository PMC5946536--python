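"""The four time-domain features driving the motion classifier.

Per channel and analysis window: mean absolute value (MAV), waveform length
(WL), zero-crossing count (ZC) and slope-sign-change count (SSC) — the
classic low-cost feature set for embedded myoelectric control. A feature
vector concatenates the four features channel by channel, and keeps the MAV
components addressable by channel because the threshold-switch
post-processing gates decisions on the classified motion's channel MAV.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .signal_io import AnalysisWindow

FEATURE_NAMES = ("MAV", "WL", "ZC", "SSC")

#: default deadband for ZC/SSC, mV. Suppresses noise-floor crossings; 0
#: recovers the plain textbook definitions.
DEFAULT_EPS = 0.01


def mav(x: Sequence[float] | np.ndarray) -> float:
    """Mean absolute value of a window, in mV."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ParameterError("mav of an empty window is undefined")
    return float(np.mean(np.abs(x)))


def waveform_length(x: Sequence[float] | np.ndarray) -> float:
    """Sum of absolute first differences, in mV."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ParameterError("waveform_length needs at least 2 samples")
    return float(np.sum(np.abs(np.diff(x))))


def zero_crossings(x: Sequence[float] | np.ndarray, eps: float = DEFAULT_EPS) -> int:
    """Count of sign changes between adjacent samples.

    A crossing at k requires a strict sign flip (x[k]*x[k+1] < 0, so exact
    zeros never count) and an amplitude swing |x[k] - x[k+1]| >= eps.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ParameterError("zero_crossings needs at least 2 samples")
    if eps < 0:
        raise ParameterError(f"deadband eps must be >= 0, got {eps}")
    flip = x[:-1] * x[1:] < 0
    big = np.abs(np.diff(x)) >= eps
    return int(np.count_nonzero(flip & big))


def slope_sign_changes(x: Sequence[float] | np.ndarray,
                       eps: float = DEFAULT_EPS) -> int:
    """Count of local extrema (slope sign reversals) exceeding the deadband.

    Sample k is counted when (x[k]-x[k-1])*(x[k]-x[k+1]) > 0 and the larger
    of the two adjacent steps is at least eps.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ParameterError("slope_sign_changes needs at least 3 samples")
    if eps < 0:
        raise ParameterError(f"deadband eps must be >= 0, got {eps}")
    left = x[1:-1] - x[:-2]
    right = x[1:-1] - x[2:]
    peak = left * right > 0
    big = np.maximum(np.abs(left), np.abs(right)) >= eps
    return int(np.count_nonzero(peak & big))


@dataclass
class FeatureVector:
    """Per-window classifier input.

    ``values`` has length 4 x n_channels, laid out channel-major:
    [Ch1 MAV, Ch1 WL, Ch1 ZC, Ch1 SSC, Ch2 MAV, ...]. ``mav_by_channel``
    re-exposes the MAV components in channel order for post-processing.
    """

    values: np.ndarray
    window_start: int
    mav_by_channel: np.ndarray


def extract_features(w: AnalysisWindow, eps: float = DEFAULT_EPS) -> FeatureVector:
    """Compute the 4 x n_channels feature vector of one analysis window."""
    data = np.asarray(w.data, dtype=float)
    n_ch = data.shape[1]
    values = np.empty(4 * n_ch)
    mavs = np.empty(n_ch)
    for c in range(n_ch):
        x = data[:, c]
        mavs[c] = mav(x)
        values[4 * c:4 * c + 4] = (
            mavs[c],
            waveform_length(x),
            zero_crossings(x, eps),
            slope_sign_changes(x, eps),
        )
    return FeatureVector(values, w.start_sample, mavs)


def feature_matrix(windows: Iterable[AnalysisWindow],
                   eps: float = DEFAULT_EPS) -> tuple[np.ndarray, list[FeatureVector]]:
    """Stack feature vectors of a window stream into an (n_windows, 4C) matrix."""
    fvs = [extract_features(w, eps) for w in windows]
    if not fvs:
        return np.empty((0, 0)), []
    return np.vstack([fv.values for fv in fvs]), fvs


def feature_frame(fvs: Sequence[FeatureVector],
                  channel_labels: Sequence[str]) -> pd.DataFrame:
    """Feature vectors as a DataFrame (columns ChK_MAV ... plus window_start)."""
    cols = [f"{ch}_{name}" for ch in channel_labels for name in FEATURE_NAMES]
    frame = pd.DataFrame([fv.values for fv in fvs], columns=cols)
    frame.insert(0, "window_start", [fv.window_start for fv in fvs])
    return frame
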