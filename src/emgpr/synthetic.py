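"""Synthetic coupled-sEMG generator: the test bed replacing patient recordings.

Surface EMG during a steady contraction is well approximated by band-limited
zero-mean Gaussian noise whose envelope tracks contraction intensity. Each
simulated channel is

    x_c(t) = E_c(t) * carrier_c(t) + noise_c(t)

where carrier_c is unit-variance Gaussian noise band-passed to the
configured band, noise_c is the white baseline, and the envelope E_c sums
the trapezoidal activation of every scheduled motion weighted by a motions x
channels coupling matrix (in mV). Because a Gaussian of scale sigma has
E|x| = sigma * sqrt(2/pi), the coupling entries directly set steady-state
channel amplitudes.

Coupling is multiplicative on envelopes only — channels co-activate, they do
not share carriers — modelling the post-TMR co-contraction problem (one
motion attempt drives several reinnervated sites) rather than electrode
cross-talk. The default matrix encodes the clinical picture this package
targets: hand open drives the elbow-extension channel at 80% of its own
amplitude, elbow extension drives the hand-open channel (two heads of the
same triceps), the two biceps-head channels (hand close / elbow flexion)
couple moderately, and the wrist-rotation (deltoid) channel is weaker
overall.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import yaml

from .errors import ParameterError
from .protocol import DEFAULT_MOTIONS, SessionPlan
from .signal_io import Annotation, EMGRecording, bandpass_array

DEFAULT_CHANNELS = ("Ch1", "Ch2", "Ch3", "Ch4", "Ch5")
DEFAULT_MOTION_MAP = dict(zip(DEFAULT_CHANNELS, DEFAULT_MOTIONS))

#: schedule token for a rest gap
REST = "REST"


def default_coupling() -> np.ndarray:
    """Default coupled steady-state envelope matrix (motions x channels, mV).

    Moderate-effort steady amplitudes sit at roughly twice the standard
    per-motion thresholds (0.45 mV vs 0.2 mV; the weaker deltoid channel
    0.25 mV vs 0.1 mV), the operating point at which amplitude gating is
    reliable during holds. Off-diagonal entries encode the co-contraction
    couplings described in the module docstring.
    """
    return np.array([
        # Ch1    Ch2    Ch3    Ch4    Ch5
        [0.45, 0.03, 0.03, 0.18, 0.03],   # hand close
        [0.03, 0.45, 0.03, 0.03, 0.36],   # hand open
        [0.03, 0.03, 0.25, 0.03, 0.03],   # wrist rotation
        [0.18, 0.03, 0.03, 0.45, 0.08],   # elbow flexion
        [0.03, 0.30, 0.03, 0.08, 0.45],   # elbow extension
    ])


def identity_coupling(diag_mv: float = 0.3, n: int = 5) -> np.ndarray:
    """Fully independent channels: each motion drives only its own channel."""
    return np.eye(n) * diag_mv


@dataclass
class SimConfig:
    """Simulator parameters.

    fs defaults to the embedded controller's 1860 Hz; transient_s is the
    onset/offset ramp duration; noise_mv the baseline white-noise RMS;
    carrier_band the sEMG energy band in Hz.
    """

    fs: float = 1860.0
    channel_labels: tuple[str, ...] = DEFAULT_CHANNELS
    motions: tuple[str, ...] = DEFAULT_MOTIONS
    coupling: np.ndarray = field(default_factory=default_coupling)
    transient_s: float = 0.4
    noise_mv: float = 0.02
    carrier_band: tuple[float, float] = (80.0, 400.0)
    seed: int = 0

    def __post_init__(self) -> None:
        self.coupling = np.asarray(self.coupling, dtype=float)
        if self.coupling.shape != (len(self.motions), len(self.channel_labels)):
            raise ParameterError(
                f"coupling must be {len(self.motions)}x{len(self.channel_labels)}"
            )
        if np.any(self.coupling < 0):
            raise ParameterError("coupling entries must be >= 0")
        if self.transient_s < 0:
            raise ParameterError("transient_s must be >= 0")
        if not self.noise_mv > 0:
            raise ParameterError("noise_mv must be > 0")

    @property
    def motion_map(self) -> dict[str, str]:
        return dict(zip(self.channel_labels, self.motions))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        kwargs = {}
        if "fs_hz" in d:
            kwargs["fs"] = float(d["fs_hz"])
        if "channel_labels" in d:
            kwargs["channel_labels"] = tuple(d["channel_labels"])
        if "motions" in d:
            kwargs["motions"] = tuple(d["motions"])
        if "coupling" in d:
            kwargs["coupling"] = np.asarray(d["coupling"], dtype=float)
        for key in ("transient_s", "noise_mv", "seed"):
            if key in d:
                kwargs[key] = d[key]
        if "carrier_band" in d:
            kwargs["carrier_band"] = tuple(d["carrier_band"])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({
                "fs_hz": self.fs,
                "channel_labels": list(self.channel_labels),
                "motions": list(self.motions),
                "coupling": self.coupling.tolist(),
                "transient_s": self.transient_s,
                "noise_mv": self.noise_mv,
                "carrier_band": list(self.carrier_band),
                "seed": self.seed,
            }, fh)


class ScheduleEntry(NamedTuple):
    """One scheduled contraction: ramp up, hold, ramp down.

    ``transient_s=None`` means "use the config default". ``level`` scales
    the coupling row (1.0 = moderate effort).
    """

    motion: str
    onset_s: float
    hold_s: float
    level: float = 1.0
    transient_s: float | None = None


@dataclass
class MotionSchedule:
    """Chronological, non-overlapping ground-truth schedule.

    An entry's *core* interval [onset, onset + transient + hold) must not
    overlap the next core; the offset-decay tail may cross-fade into the
    next entry's onset ramp, as real back-to-back motion switches do.
    """

    entries: list[ScheduleEntry]

    def __post_init__(self) -> None:
        self.entries = [ScheduleEntry(*e) for e in self.entries]
        for e in self.entries:
            if e.level < 0:
                raise ParameterError(f"negative effort level in {e}")
            if e.hold_s < 0 or e.onset_s < 0:
                raise ParameterError(f"negative timing in {e}")

    def resolved(self, default_transient_s: float) -> list[ScheduleEntry]:
        """Entries with transient_s filled in, validated for core overlap."""
        out = [e._replace(transient_s=e.transient_s if e.transient_s is not None
                          else default_transient_s)
               for e in self.entries]
        out.sort(key=lambda e: e.onset_s)
        prev_core_end = -np.inf
        for e in out:
            if e.onset_s < prev_core_end - 1e-9:
                raise ParameterError(f"entry {e} overlaps the previous core")
            prev_core_end = e.onset_s + e.transient_s + e.hold_s
        return out

    def end_s(self, default_transient_s: float) -> float:
        """End of the last decay tail."""
        ends = [e.onset_s + 2 * e.transient_s + e.hold_s
                for e in self.resolved(default_transient_s)]
        return max(ends) if ends else 0.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MotionSchedule":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        entries = [ScheduleEntry(e["motion"], float(e["onset_s"]),
                                 float(e["hold_s"]), float(e.get("level", 1.0)),
                                 e.get("transient_s"))
                   for e in d["entries"]]
        return cls(entries)

    def to_yaml(self, path: str | Path,
                default_transient_s: float | None = None) -> None:
        entries = (self.resolved(default_transient_s)
                   if default_transient_s is not None else self.entries)
        with open(path, "w") as fh:
            yaml.safe_dump({"entries": [
                {"motion": e.motion, "onset_s": e.onset_s, "hold_s": e.hold_s,
                 "level": e.level, "transient_s": e.transient_s}
                for e in entries
            ]}, fh)


def _trapezoid(t: np.ndarray, e: ScheduleEntry) -> np.ndarray:
    """Activation envelope of one entry on the time grid, peak = level."""
    tr = e.transient_s
    up_end = e.onset_s + tr
    hold_end = up_end + e.hold_s
    down_end = hold_end + tr
    a = np.zeros_like(t)
    if tr > 0:
        rising = (t >= e.onset_s) & (t < up_end)
        a[rising] = (t[rising] - e.onset_s) / tr
        falling = (t >= hold_end) & (t < down_end)
        a[falling] = 1.0 - (t[falling] - hold_end) / tr
    holding = (t >= up_end) & (t < hold_end)
    a[holding] = 1.0
    return a * e.level


def simulate(cfg: SimConfig, sched: MotionSchedule,
             duration_s: float | None = None) -> EMGRecording:
    """Render a schedule into an annotated multichannel recording.

    Fully reproducible from cfg.seed. Annotations mark each steady hold with
    its motion; the schedule itself carries the transient intervals for
    evaluation.
    """
    entries = sched.resolved(cfg.transient_s)
    if duration_s is None:
        duration_s = sched.end_s(cfg.transient_s)
    n = int(round(duration_s * cfg.fs))
    if n < 1:
        raise ParameterError("simulation duration must cover at least one sample")
    t = np.arange(n) / cfg.fs
    motion_idx = {m: i for i, m in enumerate(cfg.motions)}

    activation = np.zeros((n, len(cfg.motions)))
    for e in entries:
        if e.motion == REST:
            continue
        if e.motion not in motion_idx:
            raise ParameterError(f"unknown motion {e.motion!r} in schedule")
        activation[:, motion_idx[e.motion]] += _trapezoid(t, e)
    envelope = activation @ cfg.coupling          # (n, channels), mV

    rng = np.random.default_rng(cfg.seed)
    carrier = rng.standard_normal((n, len(cfg.channel_labels)))
    carrier = bandpass_array(carrier, cfg.fs, *cfg.carrier_band)
    carrier /= carrier.std(axis=0)
    noise = rng.standard_normal((n, len(cfg.channel_labels))) * cfg.noise_mv
    samples = envelope * carrier + noise

    annotations = []
    for e in entries:
        if e.motion == REST:
            continue
        start = int(round((e.onset_s + e.transient_s) * cfg.fs))
        end = int(round((e.onset_s + e.transient_s + e.hold_s) * cfg.fs))
        start, end = max(start, 0), min(end, n)
        if end > start:
            annotations.append(Annotation(e.motion, start, end))
    return EMGRecording(samples, cfg.fs, list(cfg.channel_labels),
                        cfg.motion_map, annotations)


def training_schedule(cfg: SimConfig, plan: SessionPlan) -> MotionSchedule:
    """Schedule realizing a back-to-back prompted training session.

    Each motion ramps up at its segment start and holds to the segment end,
    so the trimmed tail the protocol keeps is fully steady; its decay
    cross-fades into the next segment's onset.
    """
    entries = [
        ScheduleEntry(m, k * plan.per_motion_s,
                      plan.per_motion_s - cfg.transient_s, 1.0, cfg.transient_s)
        for k, m in enumerate(plan.motion_order)
    ]
    return MotionSchedule(entries)


def make_training_session(cfg: SimConfig, plan: SessionPlan) -> EMGRecording:
    """Simulate one prompted training session, annotated for extract_training_set."""
    sched = training_schedule(cfg, plan)
    return simulate(cfg, sched, duration_s=plan.total_s)


def assessment_schedule(cfg: SimConfig, hold_s: float = 5.0, rest_s: float = 1.0,
                        lead_in_s: float = 1.0, level: float = 1.0,
                        motions: Sequence[str] | None = None) -> MotionSchedule:
    """One ~5 s hold per motion, separated by rest gaps — the weekly assessment."""
    motions = tuple(motions) if motions is not None else cfg.motions
    entries = []
    onset = lead_in_s
    for m in motions:
        entries.append(ScheduleEntry(m, onset, hold_s, level, cfg.transient_s))
        onset += 2 * cfg.transient_s + hold_s + rest_s
    return MotionSchedule(entries)
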