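"""Offline evaluation: decision-stream metrics and ARAT score arithmetic.

Real-time misclassification concentrates in the transient state — the
onset/offset ramps excluded from classifier training — so stream metrics
split windows by ground truth into steady, transient and rest before
scoring. ARAT (Action Research Arm Test) task scores are human observer
ratings (0-3 per task); only their aggregation and percent-increase
arithmetic is computed here, with the case study's printed per-condition
totals shipped as reference data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ParameterError
from .postprocess import STILL, DecisionStream
from .synthetic import REST, MotionSchedule

#: total modified-ARAT scores measured in the functional tests of the
#: transhumeral-TMR case study this package models: plain pattern
#: recognition (Control), majority vote with queues 3/5/10, and MAV
#: threshold switches at the lower/standard/higher threshold sets.
CASE_STUDY_TOTALS: dict[str, float] = {
    "Control": 9.3,
    "L3": 11.0,
    "L5": 11.0,
    "L10": 13.0,
    "LT": 14.7,
    "ST": 16.0,
    "HT": 14.7,
}

VOTE_CONDITIONS = ("L3", "L5", "L10")
THRESHOLD_CONDITIONS = ("LT", "ST", "HT")


@dataclass
class StreamMetrics:
    """Per-stream summary split by ground-truth state.

    steady_accuracy counts a steady window correct only when the output
    equals the held motion (STILL is wrong during a hold).
    transient_error_rate is the fraction of transient windows emitting a
    motion outside the transitioning motion set (STILL is not an error);
    still_rate_transient the fraction of transient windows kept STILL.
    confusion rows are true steady motions, columns the emitted outputs.
    """

    steady_accuracy: float
    transient_error_rate: float
    still_rate_transient: float
    confusion: pd.DataFrame
    n_steady: int
    n_transient: int
    n_rest: int

    def to_dict(self) -> dict:
        return {
            "steady_accuracy": self.steady_accuracy,
            "transient_error_rate": self.transient_error_rate,
            "still_rate_transient": self.still_rate_transient,
            "n_steady": self.n_steady,
            "n_transient": self.n_transient,
            "n_rest": self.n_rest,
            "confusion": {m: self.confusion.loc[m].to_dict()
                          for m in self.confusion.index},
        }


def score_stream(ds: DecisionStream, truth: MotionSchedule,
                 default_transient_s: float = 0.4) -> StreamMetrics:
    """Score a decision stream against its generating schedule.

    Every window [start, start+L) in seconds is assigned to exactly one
    state: *steady* when it lies entirely inside one hold, *rest* when it
    touches no motion footprint, *transient* otherwise (ramps, decays and
    any boundary-straddling window — the conservative choice, since those
    windows mix states).
    """
    if ds.fs <= 0 or ds.window_len < 1:
        raise ParameterError("decision stream lacks a valid time base")
    entries = truth.resolved(default_transient_s)
    motions = sorted({e.motion for e in entries if e.motion != REST})
    steady, footprint = [], []
    for e in entries:
        if e.motion == REST:
            continue
        up_end = e.onset_s + e.transient_s
        hold_end = up_end + e.hold_s
        steady.append((e.motion, up_end, hold_end))
        footprint.append((e.motion, e.onset_s, hold_end + e.transient_s))

    out_labels = sorted(set(ds.outputs) - {STILL} - set(motions))
    columns = motions + out_labels + [STILL]
    confusion = pd.DataFrame(0, index=motions, columns=columns, dtype=int)
    n_steady = n_transient = n_rest = 0
    steady_correct = 0
    transient_wrong = 0
    transient_still = 0
    for d in ds.decisions:
        t0 = d.window_start / ds.fs
        t1 = (d.window_start + ds.window_len) / ds.fs
        inside = [m for m, a, b in steady if t0 >= a and t1 <= b]
        touching = {m for m, a, b in footprint if t0 < b and t1 > a}
        if inside:
            n_steady += 1
            confusion.loc[inside[0], d.output] += 1
            if d.output == inside[0]:
                steady_correct += 1
        elif touching:
            n_transient += 1
            if d.output == STILL:
                transient_still += 1
            elif d.output not in touching:
                transient_wrong += 1
        else:
            n_rest += 1
    return StreamMetrics(
        steady_accuracy=steady_correct / n_steady if n_steady else 0.0,
        transient_error_rate=transient_wrong / n_transient if n_transient else 0.0,
        still_rate_transient=transient_still / n_transient if n_transient else 0.0,
        confusion=confusion,
        n_steady=n_steady,
        n_transient=n_transient,
        n_rest=n_rest,
    )


def percent_increase(scores: Mapping[str, float],
                     baseline: str = "Control") -> dict[str, float]:
    """Percent change of each condition's total over the baseline total.

    100 * (total - baseline_total) / baseline_total for every non-baseline
    condition.
    """
    if baseline not in scores:
        raise ParameterError(f"baseline condition {baseline!r} not in scores")
    base = scores[baseline]
    if not base > 0:
        raise ParameterError(f"baseline total must be > 0, got {base}")
    return {cond: 100.0 * (total - base) / base
            for cond, total in scores.items() if cond != baseline}


def arat_totals(trials: pd.DataFrame) -> dict[str, float]:
    """Aggregate per-trial ARAT scores into per-condition totals.

    `trials` columns: condition, task, trial, score with score in {0,1,2,3}.
    A task's final score is the mean of its trials; a condition's total is
    the sum of task final scores.
    """
    required = {"condition", "task", "trial", "score"}
    if not required.issubset(trials.columns):
        raise ParameterError(f"ARAT table needs columns {sorted(required)}")
    if not trials["score"].isin([0, 1, 2, 3]).all():
        raise ParameterError("ARAT task scores must be integers in 0..3")
    per_task = trials.groupby(["condition", "task"])["score"].mean()
    totals = per_task.groupby("condition").sum()
    return {str(c): float(v) for c, v in totals.items()}
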