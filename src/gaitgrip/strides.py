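"""Raw trial signals -> normalized stride matrices and gait parameters.

Each trial is segmented into strides at heel strikes (HS), split into
stance/swing at toe-off (TO), temporally normalized onto a 100-column %GC
grid (stance 1-60, swing 61-100), bias-corrected against the 21-25%GC
neutral window, and amplitude-normalized by the maximum instantaneous
walking velocity.  Twenty spatiotemporal gait parameters (GP01-GP20) are
computed per stride before temporal normalization; strides are averaged
within each trial and across the two feet.

Operational definitions deliberately simplified relative to published
device-specific algorithms (validated against the generator's ground truth):

* HS: peaks of the superior acceleration channel with a 0.4 s refractory
  period;
* TO: first downward zero-crossing of the sagittal angular velocity after
  mid-stance, validated by a dorsiflexion (negative) swing that follows;
* foot-flat bounds: sustained sub-threshold |G_x|;
* stride outliers: duration or v_max beyond 3 SD of the trial mean, after
  dropping the first and last three strides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .spm import CHANNELS
from .synthetic import FS_HZ, Cohort

__all__ = [
    "RawTrial",
    "StrideEvents",
    "NormalizedStride",
    "StrideData",
    "TrialAverage",
    "EmptyEventsError",
    "EventOrderError",
    "InsufficientStridesError",
    "DegenerateStrideError",
    "detect_heel_strikes",
    "normalize_stride",
    "compute_gait_parameters",
    "filter_strides",
    "average_trial",
    "process_trial",
    "process_cohort",
    "grid_columns",
    "GP_NAMES",
]

log = logging.getLogger(__name__)

GP_NAMES = tuple(f"gp{i:02d}" for i in range(1, 21))

#: neutral-posture window on the %GC grid (closed, 1-based)
NEUTRAL_GC = (21, 25)


class EmptyEventsError(ValueError):
    """No strides could be detected in the trial."""


class EventOrderError(ValueError):
    """Detected events violate the HS/TO interleaving invariants."""


class InsufficientStridesError(ValueError):
    """Fewer strides than the edge-exclusion rule requires."""


class DegenerateStrideError(ValueError):
    """Stride with (near-)zero maximum instantaneous velocity."""


@dataclass(frozen=True)
class RawTrial:
    """One trial's raw 9-channel signal at 100 Hz."""

    samples: np.ndarray        # (T, 9) in CHANNELS order
    side: str
    subject_id: str
    trial_id: int
    fs_hz: float = FS_HZ

    def __post_init__(self) -> None:
        s = np.asarray(self.samples)
        if s.ndim != 2 or s.shape[1] != len(CHANNELS):
            raise ValueError("samples must be (T, 9)")
        if s.shape[0] < 200:
            raise ValueError("trial too short: need T >= 200 samples")
        if not np.all(np.isfinite(s)):
            raise ValueError("non-finite samples")
        if self.fs_hz != FS_HZ:
            raise ValueError(f"sampling rate must be {FS_HZ} Hz")
        if self.side not in ("left", "right"):
            raise ValueError(f"unknown side {self.side!r}")

    def channel(self, name: str) -> np.ndarray:
        return self.samples[:, CHANNELS.index(name)]


@dataclass(frozen=True)
class StrideEvents:
    hs: np.ndarray   # ordered HS sample indices, (S+1,)
    to: np.ndarray   # ordered TO sample indices, (S,)

    def __post_init__(self) -> None:
        hs, to = np.asarray(self.hs), np.asarray(self.to)
        if hs.size < 2 or to.size != hs.size - 1:
            raise EventOrderError("need S+1 heel strikes and S toe-offs")
        if np.any(np.diff(hs) <= 0) or (to.size > 1 and np.any(np.diff(to) <= 0)):
            raise EventOrderError("event indices must be strictly increasing")
        if np.any(to <= hs[:-1]) or np.any(to >= hs[1:]):
            raise EventOrderError("events must interleave hs[i] < to[i] < hs[i+1]")

    @property
    def n_strides(self) -> int:
        return len(self.to)


@dataclass(frozen=True)
class NormalizedStride:
    """9 x 100 %GC-normalized, bias-removed, velocity-normalized stride."""

    grid: np.ndarray           # (9, 100)
    v_max: float               # m/s, maximum instantaneous walking velocity
    bias_removed: bool = True
    velocity_normalized: bool = True


@dataclass(frozen=True)
class StrideData:
    """One processed stride: normalized grid plus raw-timescale parameters."""

    stride: NormalizedStride
    gps: np.ndarray            # (20,)
    duration_s: float


@dataclass(frozen=True)
class TrialAverage:
    """Within-trial average over retained strides and both feet."""

    grid: np.ndarray           # (9, 100)
    gps: np.ndarray            # (20,)
    subject_id: str
    trial_id: int
    n_strides_left: int
    n_strides_right: int


def detect_heel_strikes(raw: RawTrial) -> StrideEvents:
    """Detect HS (superior-acceleration peaks) and TO (G_x zero crossing).

    Raises :class:`EmptyEventsError` when no strides are found and
    :class:`EventOrderError` when the detected events are inconsistent
    (e.g. a time-reversed signal with no dorsiflexion swing after TO).
    """
    az = raw.channel("Az")
    amp = float(az.max())
    if amp <= 1e-9 or az.std() <= 1e-12:
        raise EmptyEventsError("no heel-strike peaks in a flat signal")
    refractory = int(0.4 * raw.fs_hz)
    peaks, _ = find_peaks(az, height=0.7 * amp, distance=refractory)
    if peaks.size < 2:
        raise EmptyEventsError(f"found {peaks.size} heel strikes; need >= 2")

    gx = raw.channel("Gx")
    tos = []
    for a, b in zip(peaks[:-1], peaks[1:]):
        gap = b - a
        start = a + int(0.5 * gap)
        seg = gx[start:b]
        crossings = np.flatnonzero((seg[:-1] > 0) & (seg[1:] <= 0))
        if crossings.size == 0:
            raise EventOrderError(
                f"no toe-off zero crossing between heel strikes {a} and {b}")
        to = start + int(crossings[0]) + 1
        # a genuine toe-off is followed by a dorsiflexion (negative) swing
        tail = gx[to:to + max(int(0.2 * gap), 2)]
        if tail.size == 0 or tail.mean() >= 0:
            raise EventOrderError(
                f"no dorsiflexion swing after candidate toe-off at {to}")
        stance_frac = (to - a) / gap
        if not 0.35 <= stance_frac <= 0.85:
            raise EventOrderError(
                f"implausible stance fraction {stance_frac:.2f} at stride {a}")
        tos.append(to)
    return StrideEvents(hs=peaks, to=np.asarray(tos))


def _resample_stride(samples: np.ndarray, hs: int, to: int, hs2: int) -> np.ndarray:
    """Linear resampling: stance -> 60 columns, swing -> 40 columns."""
    pos_stance = hs + np.arange(60) * (to - hs) / 60.0
    pos_swing = to + np.arange(40) * (hs2 - to) / 40.0
    pos = np.concatenate([pos_stance, pos_swing])
    idx = np.arange(samples.shape[0])
    return np.vstack([np.interp(pos, idx, samples[:, c])
                      for c in range(samples.shape[1])])


def _neutral_slice(hs: int, to: int) -> tuple[int, int]:
    """Raw-sample bounds of the 21-25%GC neutral window."""
    lo = hs + int(round((NEUTRAL_GC[0] - 1) / 60.0 * (to - hs)))
    hi = hs + int(round(NEUTRAL_GC[1] / 60.0 * (to - hs)))
    return lo, max(hi, lo + 1)


def _forward_velocity(samples: np.ndarray, hs: int, to: int, hs2: int,
                      fs: float) -> np.ndarray:
    """Instantaneous forward velocity from the neutral window to stride end.

    Forward acceleration is -A_y (posterior is positive); velocity is
    integrated from the start of the neutral window, where the foot is
    taken to be at rest.
    """
    n0, _ = _neutral_slice(hs, to)
    a_f = -samples[n0:hs2 + 1, CHANNELS.index("Ay")]
    v = np.concatenate([[0.0], np.cumsum((a_f[1:] + a_f[:-1]) / 2.0)]) / fs
    return v


def normalize_stride(samples: np.ndarray, hs: int, to: int, hs2: int,
                     fs: float = FS_HZ) -> NormalizedStride:
    """Temporal + amplitude normalization of one stride.

    Stance is resampled to columns 1-60, swing to 61-100; the 21-25%GC
    per-channel mean is subtracted; the six inertial channels are divided
    by the maximum instantaneous velocity magnitude ``v_max``.
    """
    if not (0 <= hs < to < hs2 < samples.shape[0]):
        raise ValueError("invalid event triple")
    grid = _resample_stride(samples, hs, to, hs2)
    bias = grid[:, NEUTRAL_GC[0] - 1:NEUTRAL_GC[1]].mean(axis=1, keepdims=True)
    grid = grid - bias
    v = _forward_velocity(samples, hs, to, hs2, fs)
    v_max = float(np.max(np.abs(v)))
    if v_max <= 1e-6:
        raise DegenerateStrideError("zero maximum instantaneous velocity")
    grid[:6] /= v_max
    return NormalizedStride(grid=grid, v_max=v_max)


def _flat_bounds(gx: np.ndarray, hs: int, to: int, rel_threshold: float,
                 sustain: int = 5) -> tuple[int, int]:
    """First sustained sub-threshold |G_x| run in stance: (onset, offset)."""
    seg = np.abs(gx[hs:to])
    thr = rel_threshold * max(seg.max(), 1e-12)
    below = (seg < thr).astype(np.int8)
    runs = np.convolve(below, np.ones(sustain, dtype=np.int8), mode="valid")
    starts = np.flatnonzero(runs == sustain)
    if starts.size == 0:
        onset = int(np.argmin(seg))
        return hs + onset, hs + onset
    onset = int(starts[0])
    above = np.convolve(1 - below[onset:], np.ones(3, dtype=np.int8),
                        mode="valid")
    breaks = np.flatnonzero(above == 3)
    if breaks.size == 0:
        off = len(below) - 1
    else:
        tail = below[onset:onset + breaks[0] + 1]
        off = onset + int(np.flatnonzero(tail)[-1])
    return hs + onset, hs + off


def compute_gait_parameters(samples: np.ndarray, hs: int, to: int, hs2: int,
                            height_m: float, fs: float = FS_HZ) -> np.ndarray:
    """The 20 spatiotemporal gait parameters of one stride.

    Computed on the raw (pre-normalization) timescale.  GP01/GP05/GP06 are
    height-normalized; GP11-GP14, GP19, GP20 are normalized by stride
    duration; GP15, GP16, GP18 by the maximum instantaneous velocity.
    """
    if height_m is None or height_m <= 0:
        raise ValueError("subject height required for GP01/GP05/GP06")
    d = (hs2 - hs) / fs
    stance_t = (to - hs) / fs
    swing_t = d - stance_t

    v = _forward_velocity(samples, hs, to, hs2, fs)
    v_max = float(np.max(np.abs(v)))
    if v_max <= 1e-6:
        raise DegenerateStrideError("zero maximum instantaneous velocity")
    stride_len = float(np.trapezoid(v) / fs)

    ex = samples[hs:hs2 + 1, CHANNELS.index("Ex")]
    ey = samples[:, CHANNELS.index("Ey")]
    ez = samples[hs:to, CHANNELS.index("Ez")]
    gx = samples[:, CHANNELS.index("Gx")]
    ax = samples[hs:hs2 + 1, CHANNELS.index("Ax")]
    az = samples[hs:hs2 + 1, CHANNELS.index("Az")]

    def _lindetrend(x: np.ndarray) -> np.ndarray:
        t = np.arange(x.size) - (x.size - 1) / 2.0
        return x - x.mean() - (t @ x) / (t @ t) * t

    def _excursion(acc: np.ndarray) -> float:
        # double integration with per-stride linear drift removal
        vel = _lindetrend(np.cumsum(acc) / fs)
        disp = _lindetrend(np.cumsum(vel) / fs)
        return float(np.max(np.abs(disp)))

    flat_on13, flat_off = _flat_bounds(gx, hs, to, rel_threshold=0.08)
    flat_on19, _ = _flat_bounds(gx, hs, to, rel_threshold=0.04)

    gx_swing = gx[to:hs2 + 1]
    az_swing = az[to - hs:]

    gp = np.empty(20)
    gp[0] = stride_len / height_m                        # GP01
    gp[1] = stride_len / d                               # GP02
    gp[2] = float(np.max(-ex))                           # GP03
    gp[3] = float(np.max(ex))                            # GP04
    gp[4] = _excursion(ax) / height_m                    # GP05
    gp[5] = _excursion(az) / height_m                    # GP06
    gp[6] = float(np.mean(ez))                           # GP07
    gp[7] = float(ey[hs])                                # GP08
    gp[8] = float(ey[to])                                # GP09
    gp[9] = 120.0 / d                                    # GP10 (2 steps/stride)
    gp[10] = stance_t / d                                # GP11
    gp[11] = swing_t / d                                 # GP12
    gp[12] = ((flat_on13 - hs) / fs) / d                 # GP13
    gp[13] = ((to - flat_off) / fs) / d                  # GP14
    gp[14] = float(np.max(gx_swing)) / v_max             # GP15
    gp[15] = float(np.min(gx_swing)) / v_max             # GP16
    gp[16] = v_max                                       # GP17
    gp[17] = float(np.max(az_swing)) / v_max             # GP18
    gp[18] = ((flat_on19 - hs) / fs) / d                 # GP19
    gp[19] = ((flat_off - flat_on13) / fs) / d           # GP20
    if not np.all(np.isfinite(gp)):
        raise ValueError("non-finite gait parameter")
    return gp


def _process_strides(raw: RawTrial, height_m: float,
                     events: StrideEvents | None = None) -> list[StrideData]:
    events = events or detect_heel_strikes(raw)
    out = []
    for i in range(events.n_strides):
        hs, to, hs2 = int(events.hs[i]), int(events.to[i]), int(events.hs[i + 1])
        stride = normalize_stride(raw.samples, hs, to, hs2, raw.fs_hz)
        gps = compute_gait_parameters(raw.samples, hs, to, hs2, height_m,
                                      raw.fs_hz)
        out.append(StrideData(stride=stride, gps=gps,
                              duration_s=(hs2 - hs) / raw.fs_hz))
    return out


def filter_strides(strides: list[StrideData]) -> list[StrideData]:
    """Drop the first/last three strides, then 3-SD outliers.

    Outliers are strides whose duration or v_max deviates more than 3 SD
    from the trial mean; mean and SD are taken leave-one-out (over the
    other post-edge-drop strides) so a single gross outlier cannot mask
    itself in a short trial.
    """
    if len(strides) < 7:
        raise InsufficientStridesError(
            f"need >= 7 strides to drop the first/last 3; got {len(strides)}")
    kept = strides[3:-3]
    keep = np.ones(len(kept), dtype=bool)
    for vals in (np.array([s.duration_s for s in kept]),
                 np.array([s.stride.v_max for s in kept])):
        scale = max(np.abs(vals).max(), 1e-12)
        for i, x in enumerate(vals):
            rest = np.delete(vals, i)
            m, sd = rest.mean(), rest.std(ddof=0)
            dev = abs(x - m)
            if dev > 3.0 * sd + 1e-9 * scale:
                keep[i] = False
    return [s for s, k in zip(kept, keep) if k]


def average_trial(left: list[StrideData], right: list[StrideData],
                  subject_id: str = "", trial_id: int = 0) -> TrialAverage:
    """Mean stride grid and GPs per foot, then across the two feet."""
    if not left and not right:
        raise ValueError("no retained strides on either foot")
    feet = []
    for name, strides in (("left", left), ("right", right)):
        if not strides:
            log.warning("subject %s trial %s: no retained %s-foot strides; "
                        "falling back to single-foot average",
                        subject_id, trial_id, name)
            continue
        feet.append((
            np.mean([s.stride.grid for s in strides], axis=0),
            np.mean([s.gps for s in strides], axis=0),
        ))
    grid = np.mean([f[0] for f in feet], axis=0)
    gps = np.mean([f[1] for f in feet], axis=0)
    return TrialAverage(grid=grid, gps=gps, subject_id=subject_id,
                        trial_id=trial_id, n_strides_left=len(left),
                        n_strides_right=len(right))


def process_trial(raw_left: RawTrial, raw_right: RawTrial,
                  height_m: float) -> TrialAverage:
    left = filter_strides(_process_strides(raw_left, height_m))
    right = filter_strides(_process_strides(raw_right, height_m))
    return average_trial(left, right, raw_left.subject_id, raw_left.trial_id)


def grid_columns() -> list[str]:
    """Flattened channel-major grid column names w_<ch>_<gc>."""
    return [f"w_{ch}_{g:03d}" for ch in CHANNELS for g in range(1, 101)]


def process_cohort(cohort: Cohort) -> tuple[pd.DataFrame, dict]:
    """All trials of a cohort -> one trial-average row per (subject, trial).

    Returns the frame (ids + subject attributes + 900 grid columns + 20 GP
    columns) and a provenance dict with per-trial stride accounting.
    """
    rows = []
    provenance = {"trials": [], "n_rows": 0}
    by_id = {s.subject_id: s for s in cohort.subjects}
    for sid in sorted(by_id):
        subj = by_id[sid]
        for trial in range(cohort.spec.n_trials):
            raws = {
                side: RawTrial(samples=cohort.signals[(sid, trial, side)],
                               side=side, subject_id=sid, trial_id=trial)
                for side in ("left", "right")
            }
            avg = process_trial(raws["left"], raws["right"],
                                subj.height_cm / 100.0)
            rec = {
                "subject_id": sid, "trial": trial, "sex": subj.sex,
                "age": subj.age, "height_cm": subj.height_cm,
                "weight_kg": subj.weight_kg, "bmi": subj.bmi,
                "hgs_kg": subj.hgs_kg, "gait_speed_mps": subj.gait_speed_mps,
            }
            rec.update(dict(zip(grid_columns(), avg.grid.ravel())))
            rec.update(dict(zip(GP_NAMES, avg.gps)))
            rows.append(rec)
            provenance["trials"].append({
                "subject_id": sid, "trial": trial,
                "strides_left": avg.n_strides_left,
                "strides_right": avg.n_strides_right,
            })
    df = pd.DataFrame(rows)
    provenance["n_rows"] = len(df)
    return df, provenance
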