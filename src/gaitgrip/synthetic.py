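"""Seeded synthetic gait cohorts with planted ground truth.

Generates per-subject, per-trial raw 9-channel foot-motion time series
(3 accelerations, 3 angular velocities, 3 sole-to-ground Euler angles at
100 Hz) built from smooth periodic per-channel templates.  A configurable
linear dependence of waveform amplitude on the subject's hand grip strength
(HGS) is planted inside chosen %GC windows, so the downstream SPM /
LOSO-LASSO stages can be validated against known truth.

Construction conventions (all deliberate, so truth is analytic):

* stance occupies exactly the first 60% of each stride, swing the last 40%;
* the forward foot-velocity profile is zero while the sole is flat
  (including the 21-25%GC neutral window) and integrates to one stride
  length per stride, so the planted gait speed is exactly recoverable;
* the superior acceleration channel carries a sharp heel-strike spike and
  the sagittal angular velocity crosses zero downward exactly at toe-off;
* noise is i.i.d. Gaussian smoothed with a fixed moving average so the
  statistic fields have non-degenerate smoothness (FWHM of a few %GC).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .spm import CHANNELS, QT_WINDOWS

__all__ = [
    "CohortSpec",
    "SubjectRecord",
    "Cohort",
    "GroundTruth",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "default_templates",
    "synthesize_trial",
    "CohortFormatError",
]

FS_HZ = 100
STANCE_FRACTION = 0.6
#: padding (in gait-cycle fraction) added around planted windows so linear
#: resampling cannot dilute the effect at the window edges
_PLANT_PAD = 0.015

_HGS_DEFAULTS = {"male": (34.7, 7.1), "female": (21.9, 4.8)}
_GS_DEFAULT = (1.29, 0.24)
_ANTHRO = {  # age (mean, sd, lo, hi), height cm, weight kg
    "male": ((70.3, 7.7, 60.0, 90.0), (166.7, 4.2), (66.8, 8.8)),
    "female": ((70.9, 5.9, 60.0, 90.0), (154.9, 6.6), (54.7, 9.4)),
}
_NOISE_DEFAULTS = {
    "Ax": 0.25, "Ay": 0.25, "Az": 0.25,
    "Gx": 4.0, "Gy": 4.0, "Gz": 4.0,
    "Ex": 0.5, "Ey": 0.5, "Ez": 0.5,
}


class CohortFormatError(ValueError):
    """Raised when an on-disk cohort does not conform to the CSV layout."""


def _bump(phi: np.ndarray, center: float, width: float) -> np.ndarray:
    """Raised-cosine bump of unit height, support |phi - center| < width."""
    d = phi - center
    out = np.zeros_like(phi)
    m = np.abs(d) < width
    out[m] = 0.5 * (1.0 + np.cos(np.pi * d[m] / width))
    return out


def _wrapped_bump(phi: np.ndarray, width: float) -> np.ndarray:
    """Unit bump at phi=0, periodic across the stride boundary."""
    d = np.minimum(phi, 1.0 - phi)
    out = np.zeros_like(phi)
    m = d < width
    out[m] = 0.5 * (1.0 + np.cos(np.pi * d[m] / width))
    return out


def _gx_template(phi: np.ndarray) -> np.ndarray:
    """Sagittal angular velocity: HS rotation, flat foot, push-off, swing.

    Exactly zero on the foot-flat plateau and crosses zero downward at
    phi = 0.6 (toe-off).
    """
    out = np.zeros_like(phi)
    m = phi < 0.12
    out[m] = 40.0 * np.sin(np.pi * phi[m] / 0.12)
    m = (phi >= 0.45) & (phi < 0.6)
    out[m] = 120.0 * np.sin(np.pi * (phi[m] - 0.45) / 0.15)
    m = phi >= 0.6
    out[m] = -180.0 * np.sin(np.pi * (phi[m] - 0.6) / 0.4)
    return out


def default_templates() -> dict:
    """Per-channel base waveform templates as callables of phi in [0, 1)."""
    return {
        "Ax": lambda p: (1.2 * np.sin(2 * np.pi * p + 2.0)
                         + 0.8 * np.sin(4 * np.pi * p + 0.7)
                         + 0.5 * np.sin(6 * np.pi * p)),
        "Az": lambda p: (8.0 * _wrapped_bump(p, 0.02)
                         + 3.0 * _bump(p, 0.75, 0.15)
                         + 0.8 * np.sin(2 * np.pi * p + 0.5)),
        "Gx": _gx_template,
        "Gy": lambda p: (25.0 * np.sin(2 * np.pi * p + 1.1)
                         + 15.0 * np.sin(4 * np.pi * p + 0.3)),
        "Gz": lambda p: (30.0 * np.sin(2 * np.pi * p + 2.4)
                         + 18.0 * np.sin(6 * np.pi * p + 1.0)),
        "Ex": lambda p: (14.0 * _bump(p, 0.52, 0.10)
                         - 31.6 * _bump(p, 0.75, 0.12)),
        "Ey": lambda p: (-5.2 * _bump(p, 0.05, 0.20)
                         + 3.6 * _bump(p, 0.62, 0.25)
                         + 2.0 * np.sin(2 * np.pi * p)),
        "Ez": lambda p: (8.0 * np.sin(2 * np.pi * p + 0.8)
                         + 4.0 * np.sin(4 * np.pi * p)),
    }


def forward_velocity_profile(phi: np.ndarray, gait_speed: float) -> np.ndarray:
    """Foot forward velocity over the stride: zero during foot flat.

    Support (0.45, 0.95); integrates to ``gait_speed`` per unit phi, so the
    mean foot velocity over a stride equals the walking speed and the peak
    equals 4x the walking speed.
    """
    v = np.zeros_like(phi)
    m = (phi > 0.45) & (phi < 0.95)
    v[m] = 4.0 * gait_speed * np.sin(np.pi * (phi[m] - 0.45) / 0.5) ** 2
    return v


def _ay_template(phi: np.ndarray, gait_speed: float, duration: float) -> np.ndarray:
    """Posterior acceleration = -d/dt of the forward velocity profile."""
    a = np.zeros_like(phi)
    m = (phi > 0.45) & (phi < 0.95)
    arg = np.pi * (phi[m] - 0.45) / 0.5
    dv_dphi = 4.0 * gait_speed * 2.0 * np.sin(arg) * np.cos(arg) * np.pi / 0.5
    a[m] = -dv_dphi / duration
    return a


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic single-sex cohort."""

    n_subjects: int
    sex: str = "male"
    n_trials: int = 4
    seed: int = 0
    planted_windows: tuple = ()          # ((channel, (t_s, t_e)), ...)
    effect_sizes: tuple = ()             # one coefficient per window
    noise_sd: dict | float | None = None  # per-channel SDs (or one scalar)
    hgs_dist: tuple[float, float] | None = None
    gs_dist: tuple[float, float] = _GS_DEFAULT
    strides_per_trial: int = 12
    stride_duration: float | None = None  # fixed value; None -> per-subject draw

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_trials < 1:
            raise ValueError("n_subjects and n_trials must be positive")
        if self.sex not in _HGS_DEFAULTS:
            raise ValueError(f"unknown sex: {self.sex!r}")
        if self.strides_per_trial < 10:
            raise ValueError("strides_per_trial must be >= 10")
        if len(self.planted_windows) != len(self.effect_sizes):
            raise ValueError("one effect size per planted window required")
        for ch, (ts, te) in self.planted_windows:
            if ch not in CHANNELS:
                raise ValueError(f"unknown channel {ch!r}")
            if not any(lo <= ts <= te <= hi for lo, hi in QT_WINDOWS):
                raise ValueError(
                    f"planted window {ch} [{ts}, {te}] not inside a Q_t window")
        for name, (mu, sd) in (("hgs_dist", self.hgs()), ("gs_dist", self.gs_dist)):
            if sd < 0:
                raise ValueError(f"{name} sd must be non-negative")
        for ch, sd in self.noise().items():
            if sd < 0:
                raise ValueError(f"noise_sd[{ch}] must be non-negative")

    def hgs(self) -> tuple[float, float]:
        return self.hgs_dist if self.hgs_dist is not None else _HGS_DEFAULTS[self.sex]

    def gs(self) -> tuple[float, float]:
        return self.gs_dist

    def noise(self) -> dict:
        if self.noise_sd is None:
            return dict(_NOISE_DEFAULTS)
        if isinstance(self.noise_sd, (int, float)):
            return {ch: float(self.noise_sd) for ch in CHANNELS}
        out = dict(_NOISE_DEFAULTS)
        out.update(self.noise_sd)
        return out


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    sex: str
    age: float
    height_cm: float
    weight_kg: float
    hgs_kg: float
    gait_speed_mps: float
    q1: bool
    q2: bool
    q3: bool
    q4: bool

    @property
    def bmi(self) -> float:
        return self.weight_kg / (self.height_cm / 100.0) ** 2


@dataclass
class Cohort:
    """Subjects plus raw trial signals, keyed (subject_id, trial, side)."""

    spec: CohortSpec
    subjects: list[SubjectRecord]
    signals: dict  # (subject_id, trial:int, side:str) -> (T, 9) float array

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        if self.subjects != other.subjects:
            return False
        if set(self.signals) != set(other.signals):
            return False
        return all(np.array_equal(self.signals[k], other.signals[k])
                   for k in self.signals)


@dataclass
class GroundTruth:
    """Exact event indices, planted support and subject-level truth."""

    hs_indices: dict      # (subject_id, trial, side) -> int array (S+1,)
    to_indices: dict      # (subject_id, trial, side) -> int array (S,)
    planted_windows: tuple
    effect_sizes: tuple
    hgs: dict             # subject_id -> kg
    gait_speed: dict      # subject_id -> m/s
    stride_duration: dict  # subject_id -> s


def _truncated_normal(rng, mean, sd, lo=0.0, size=None):
    """Rejection-sampled normal truncated below at ``lo``."""
    if sd == 0:
        return np.full(size, float(mean)) if size is not None else float(mean)
    out = rng.normal(mean, sd, size=size)
    bad = out <= lo
    while np.any(bad):
        out = np.where(bad, rng.normal(mean, sd, size=size), out)
        bad = out <= lo
    return out


def _smooth_noise(rng, n: int, sd: float, width: int = 7) -> np.ndarray:
    """Moving-average-smoothed Gaussian noise rescaled back to sd."""
    if sd == 0:
        return np.zeros(n)
    raw = rng.normal(0.0, sd, size=n + width - 1)
    kernel = np.ones(width) / width
    sm = np.convolve(raw, kernel, mode="valid")
    return sm * math.sqrt(width)  # undo the variance reduction of the mean


def synthesize_trial(
    rng: np.random.Generator,
    gait_speed: float,
    stride_duration: float,
    n_strides: int,
    hgs_offset: float = 0.0,
    planted_windows: tuple = (),
    effect_sizes: tuple = (),
    noise_sd: dict | None = None,
    templates: dict | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Build one raw trial; returns (samples (T, 9), hs indices, to indices).

    ``hgs_offset`` is the subject's HGS minus the population mean; each
    planted window adds ``effect * hgs_offset`` to its channel inside the
    window (with a small pad so resampling preserves the plateau).
    """
    templates = templates or default_templates()
    noise_sd = noise_sd or {ch: 0.0 for ch in CHANNELS}
    n = int(round(FS_HZ * stride_duration / 10.0)) * 10  # multiple of 10
    if n < 50:
        raise ValueError("stride duration too short")
    lead = int(round(0.3 * n))
    total = lead + n_strides * n + lead

    # phase of every sample in the trial (stride-periodic ramp)
    idx = np.arange(total)
    phi = ((idx - lead) % n) / n
    duration = n / FS_HZ

    samples = np.empty((total, len(CHANNELS)))
    for c, ch in enumerate(CHANNELS):
        if ch == "Ay":
            base = _ay_template(phi, gait_speed, duration)
        else:
            base = templates[ch](phi)
        for (wch, (ts, te)), eff in zip(planted_windows, effect_sizes):
            if wch != ch or eff == 0.0:
                continue
            lo = max((ts - 1) / 100.0 - _PLANT_PAD, 0.0)
            hi = min((te - 1) / 100.0 + _PLANT_PAD, 1.0)
            base = base + eff * hgs_offset * ((phi >= lo) & (phi <= hi))
        samples[:, c] = base + _smooth_noise(rng, total, noise_sd.get(ch, 0.0))

    hs = lead + n * np.arange(n_strides + 1)
    to = hs[:-1] + int(STANCE_FRACTION * n)
    return samples, hs, to


def sample_reference_values(spec: CohortSpec, n: int,
                            rng: np.random.Generator | None = None,
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Draw n (HGS, gait speed) pairs from the cohort distributions.

    Lightweight sampler (no waveforms) sharing the truncation rules of
    :func:`generate_cohort`; intended for distribution-level checks.
    """
    rng = rng or np.random.default_rng(spec.seed)
    hgs = _truncated_normal(rng, *spec.hgs(), lo=0.0, size=n)
    gs = _truncated_normal(rng, *spec.gs(), lo=0.2, size=n)
    return np.asarray(hgs, dtype=float), np.asarray(gs, dtype=float)


def generate_cohort(spec: CohortSpec) -> tuple[Cohort, GroundTruth]:
    """Generate a full seeded cohort plus its ground truth.

    Identical (spec, seed) pairs produce bit-identical cohorts.  Subject
    HGS is drawn from the cohort HGS distribution truncated at 0 kg; the
    waveform inside each planted window is shifted by
    ``effect_size x (HGS - distribution mean)``.
    """
    rng = np.random.default_rng(spec.seed)
    hgs_mean, hgs_sd = spec.hgs()
    gs_mean, gs_sd = spec.gs()
    (age_p, height_p, weight_p) = _ANTHRO[spec.sex]
    noise = spec.noise()

    subjects: list[SubjectRecord] = []
    signals: dict = {}
    gt = GroundTruth(hs_indices={}, to_indices={},
                     planted_windows=tuple(spec.planted_windows),
                     effect_sizes=tuple(spec.effect_sizes),
                     hgs={}, gait_speed={}, stride_duration={})

    for i in range(spec.n_subjects):
        sid = f"S{i:03d}"
        hgs = float(_truncated_normal(rng, hgs_mean, hgs_sd, lo=0.0))
        gs = float(_truncated_normal(rng, gs_mean, gs_sd, lo=0.2))
        age = float(np.clip(rng.normal(age_p[0], age_p[1]), age_p[2], age_p[3]))
        height = float(rng.normal(*height_p))
        weight = float(rng.normal(*weight_p))
        # stride duration: per-subject, rounded to 0.1 s so the stance/swing
        # sample counts divide evenly into the 60/40 %GC grid
        dur_draw = rng.normal(1.1, 0.05)
        dur = (spec.stride_duration if spec.stride_duration is not None
               else float(np.clip(round(dur_draw, 1), 0.8, 1.5)))
        subjects.append(SubjectRecord(
            subject_id=sid, sex=spec.sex, age=age, height_cm=height,
            weight_kg=weight, hgs_kg=hgs, gait_speed_mps=gs,
            q1=bool(rng.random() < 0.10), q2=bool(rng.random() < 0.15),
            q3=bool(rng.random() < 0.70), q4=bool(rng.random() < 0.50),
        ))
        gt.hgs[sid] = hgs
        gt.gait_speed[sid] = gs
        gt.stride_duration[sid] = dur
        for trial in range(spec.n_trials):
            for side in ("left", "right"):
                samples, hs, to = synthesize_trial(
                    rng, gs, dur, spec.strides_per_trial,
                    hgs_offset=hgs - hgs_mean,
                    planted_windows=spec.planted_windows,
                    effect_sizes=spec.effect_sizes,
                    noise_sd=noise,
                )
                key = (sid, trial, side)
                signals[key] = samples
                gt.hs_indices[key] = hs
                gt.to_indices[key] = to

    return Cohort(spec=spec, subjects=subjects, signals=signals), gt


# ---------------------------------------------------------------------------
# on-disk layout: one CSV per trial, a subjects.csv, and ground_truth.json
# ---------------------------------------------------------------------------

_TRIAL_COLUMNS = ["t"] + list(CHANNELS)


def write_cohort(cohort: Cohort, gt: GroundTruth, path: str | Path) -> None:
    """Write a cohort to ``path`` in the documented CSV layout."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in cohort.subjects:
        rows.append({
            "id": s.subject_id, "sex": s.sex, "age": s.age,
            "height_cm": s.height_cm, "weight_kg": s.weight_kg,
            "hgs_kg": s.hgs_kg, "gait_speed_mps": s.gait_speed_mps,
            "q1": int(s.q1), "q2": int(s.q2), "q3": int(s.q3), "q4": int(s.q4),
        })
    pd.DataFrame(rows).to_csv(path / "subjects.csv", index=False,
                              float_format="%.17g")
    for (sid, trial, side), samples in sorted(cohort.signals.items()):
        sub = path / sid
        sub.mkdir(exist_ok=True)
        t = np.arange(samples.shape[0]) / FS_HZ
        df = pd.DataFrame(np.column_stack([t, samples]), columns=_TRIAL_COLUMNS)
        df.to_csv(sub / f"trial_{trial}_{side}.csv", index=False,
                  float_format="%.17g")
    meta = {
        "fs_hz": FS_HZ,
        "planted_windows": [[ch, [int(ts), int(te)]]
                            for ch, (ts, te) in gt.planted_windows],
        "effect_sizes": list(gt.effect_sizes),
        "hs_indices": {f"{k[0]}/{k[1]}/{k[2]}": v.tolist()
                       for k, v in gt.hs_indices.items()},
        "to_indices": {f"{k[0]}/{k[1]}/{k[2]}": v.tolist()
                       for k, v in gt.to_indices.items()},
        "hgs": gt.hgs, "gait_speed": gt.gait_speed,
        "stride_duration": gt.stride_duration,
        "spec": {
            "n_subjects": cohort.spec.n_subjects, "sex": cohort.spec.sex,
            "n_trials": cohort.spec.n_trials, "seed": cohort.spec.seed,
            "strides_per_trial": cohort.spec.strides_per_trial,
        },
    }
    (path / "ground_truth.json").write_text(json.dumps(meta, indent=1))


def read_cohort(path: str | Path) -> tuple[Cohort, GroundTruth]:
    """Read a cohort written by :func:`write_cohort` (round-trip identity)."""
    path = Path(path)
    meta_path = path / "ground_truth.json"
    if not meta_path.exists():
        raise CohortFormatError(f"missing ground_truth.json under {path}")
    meta = json.loads(meta_path.read_text())
    if meta.get("fs_hz") != FS_HZ:
        raise CohortFormatError(
            f"unsupported sampling rate {meta.get('fs_hz')!r}; expected {FS_HZ} Hz")

    sdf = pd.read_csv(path / "subjects.csv", float_precision="round_trip")
    required = {"id", "sex", "age", "height_cm", "weight_kg", "hgs_kg",
                "gait_speed_mps", "q1", "q2", "q3", "q4"}
    missing = required - set(sdf.columns)
    if missing:
        raise CohortFormatError(f"subjects.csv missing columns: {sorted(missing)}")
    subjects = [SubjectRecord(
        subject_id=str(r["id"]), sex=str(r["sex"]), age=float(r["age"]),
        height_cm=float(r["height_cm"]), weight_kg=float(r["weight_kg"]),
        hgs_kg=float(r["hgs_kg"]), gait_speed_mps=float(r["gait_speed_mps"]),
        q1=bool(r["q1"]), q2=bool(r["q2"]), q3=bool(r["q3"]), q4=bool(r["q4"]),
    ) for _, r in sdf.iterrows()]

    spec_meta = meta["spec"]
    spec = CohortSpec(
        n_subjects=spec_meta["n_subjects"], sex=spec_meta["sex"],
        n_trials=spec_meta["n_trials"], seed=spec_meta["seed"],
        planted_windows=tuple((ch, (ts, te))
                              for ch, (ts, te) in meta["planted_windows"]),
        effect_sizes=tuple(meta["effect_sizes"]),
        strides_per_trial=spec_meta["strides_per_trial"],
    )
    signals: dict = {}
    gt = GroundTruth(
        hs_indices={}, to_indices={},
        planted_windows=spec.planted_windows, effect_sizes=spec.effect_sizes,
        hgs={k: float(v) for k, v in meta["hgs"].items()},
        gait_speed={k: float(v) for k, v in meta["gait_speed"].items()},
        stride_duration={k: float(v) for k, v in meta["stride_duration"].items()},
    )
    for s in subjects:
        for trial in range(spec.n_trials):
            for side in ("left", "right"):
                f = path / s.subject_id / f"trial_{trial}_{side}.csv"
                if not f.exists():
                    raise CohortFormatError(f"missing trial file {f}")
                df = pd.read_csv(f, float_precision="round_trip")
                if list(df.columns) != _TRIAL_COLUMNS:
                    raise CohortFormatError(
                        f"{f}: expected columns {_TRIAL_COLUMNS}, "
                        f"got {list(df.columns)}")
                if df.isna().any().any():
                    row = int(df.isna().any(axis=1).idxmax()) + 2  # 1-based + header
                    raise CohortFormatError(f"{f}: malformed value at line {row}")
                key = (s.subject_id, trial, side)
                signals[key] = df[list(CHANNELS)].to_numpy(dtype=float)
                gkey = f"{s.subject_id}/{trial}/{side}"
                gt.hs_indices[key] = np.asarray(meta["hs_indices"][gkey], dtype=int)
                gt.to_indices[key] = np.asarray(meta["to_indices"][gkey], dtype=int)
    return Cohort(spec=spec, subjects=subjects, signals=signals), gt
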