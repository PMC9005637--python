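"""Raw motion data -> analysis channels and gait events.

Converts 3D marker trajectories into sagittal-plane thigh and torso segment
angles (degrees) and angular velocities (deg/s), detects heel-strike/toe-off
events from vertical ground reaction force, and time-normalizes strides onto
a 0-100% phase grid.

Conventions (documented choices; the source data dictate none of them):

* right-handed lab frame, vertical = +Z, all angles in degrees;
* torso segment: centroid of the four iliac-spine markers -> T10 marker,
  angle measured from the upward vertical, positive = forward lean;
* thigh segment: greater trochanter -> lateral femoral epicondyle
  (proximal -> distal), angle measured from the downward vertical so a
  vertical thigh reads 0 deg and hip flexion is positive;
* "forward" is the principal horizontal direction of pelvis displacement;
* no smoothing by default — an optional zero-lag 4th-order Butterworth
  low-pass (6 Hz default) is available and should be recorded in the run
  config when used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import interp1d
from scipy.signal import butter, filtfilt

__all__ = [
    "MarkerSet",
    "TrialRecording",
    "GrfTrace",
    "CHANNELS",
    "torso_segment_vector",
    "thigh_segment_vector",
    "walking_direction",
    "segment_angle_sagittal",
    "angular_velocity",
    "interpolate_marker_gaps",
    "lowpass_filter",
    "detect_heel_strikes",
    "detect_events",
    "time_normalize_stride",
]

#: canonical channel order used throughout the package
CHANNELS = ("thigh_angle_deg", "thigh_vel_dps", "torso_angle_deg", "torso_vel_dps")

PELVIS_MARKERS = ("LASI", "RASI", "LPSI", "RPSI")
TORSO_MARKERS = PELVIS_MARKERS + ("T10",)
THIGH_MARKERS = ("GTR", "LFE")


class MissingMarkerError(KeyError):
    pass


class DegenerateGeometryError(ValueError):
    pass


@dataclass
class MarkerSet:
    """Named 3D marker trajectories in meters, lab frame, (n_samples, 3) each.

    Required names: LASI/RASI/LPSI/RPSI (anterior/posterior superior iliac
    spines), T10 (10th thoracic vertebra spinous process), GTR (greater
    trochanter), LFE (lateral femoral epicondyle).
    """

    trajectories: dict[str, np.ndarray]
    sampling_rate: float = 100.0

    def __post_init__(self) -> None:
        lengths = {v.shape[0] for v in self.trajectories.values()}
        if len(lengths) > 1:
            raise ValueError(f"marker trajectories differ in length: {lengths}")

    def __len__(self) -> int:
        return next(iter(self.trajectories.values())).shape[0]

    def get(self, name: str, i: int | slice | None = None) -> np.ndarray:
        if name not in self.trajectories:
            raise MissingMarkerError(f"marker {name!r} missing from MarkerSet")
        traj = self.trajectories[name]
        out = traj if i is None else traj[i]
        if not np.all(np.isfinite(out)):
            raise MissingMarkerError(f"marker {name!r} has non-finite samples")
        return out


@dataclass
class TrialRecording:
    """One walking trial: the four analysis channels plus gait events."""

    subject_id: str
    condition: str                     # speed-condition id, "C1".."C5"
    time_s: np.ndarray
    thigh_angle_deg: np.ndarray
    thigh_vel_dps: np.ndarray
    torso_angle_deg: np.ndarray
    torso_vel_dps: np.ndarray
    heel_strikes_s: np.ndarray
    toe_offs_s: np.ndarray
    sampling_rate: float = 100.0
    nominal_speed_m_s: float = float("nan")
    trial_id: str = "t0"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.time_s)
        for name in CHANNELS:
            if len(getattr(self, name)) != n:
                raise ValueError(f"channel {name} length != time axis length")
        hs = np.asarray(self.heel_strikes_s, dtype=float)
        if hs.size and (np.any(np.diff(hs) <= 0)
                        or hs[0] < self.time_s[0] - 1e-9
                        or hs[-1] > self.time_s[-1] + 1e-9):
            raise ValueError("heel-strike times must be increasing and inside the trial")

    def channel(self, name: str) -> np.ndarray:
        if name not in CHANNELS:
            raise KeyError(f"unknown channel {name!r}; expected one of {CHANNELS}")
        return getattr(self, name)

    def channel_matrix(self, names=CHANNELS) -> np.ndarray:
        return np.column_stack([self.channel(n) for n in names])


@dataclass
class GrfTrace:
    """Vertical ground-reaction-force trace in newtons."""

    force_n: np.ndarray
    sampling_rate: float = 1500.0

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(len(self.force_n)) / self.sampling_rate


def interpolate_marker_gaps(markers: MarkerSet,
                            max_gap_s: float = 0.1) -> MarkerSet:
    """Linearly fill short occlusion gaps (NaN runs) in marker trajectories.

    Gaps longer than ``max_gap_s``, or touching either end of the trial,
    are left as NaN — longer occlusions need proper gap-filling, which is
    out of scope here.
    """
    fs = markers.sampling_rate
    max_len = int(round(max_gap_s * fs))
    out: dict[str, np.ndarray] = {}
    for name, traj in markers.trajectories.items():
        filled = traj.copy()
        bad = ~np.all(np.isfinite(traj), axis=1)
        if bad.any() and not bad.all():
            idx = np.flatnonzero(bad)
            # split into consecutive runs
            for run in np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1):
                if (len(run) > max_len or run[0] == 0
                        or run[-1] == len(traj) - 1):
                    continue
                lo, hi = run[0] - 1, run[-1] + 1
                w = (run - lo) / (hi - lo)
                filled[run] = (1 - w[:, None]) * traj[lo] + w[:, None] * traj[hi]
        out[name] = filled
    return MarkerSet(out, fs)


def torso_segment_vector(markers: MarkerSet, i: int | slice | None = None) -> np.ndarray:
    """Pelvis-centroid -> T10 vector (the torso segment).

    The pelvis centroid is the mean of the four iliac-spine markers.
    """
    pelvis = np.mean([markers.get(m, i) for m in PELVIS_MARKERS], axis=0)
    return markers.get("T10", i) - pelvis


def thigh_segment_vector(markers: MarkerSet, i: int | slice | None = None) -> np.ndarray:
    """Greater trochanter -> lateral femoral epicondyle vector (proximal->distal)."""
    return markers.get("LFE", i) - markers.get("GTR", i)


def walking_direction(markers: MarkerSet) -> np.ndarray:
    """Unit horizontal direction of net pelvis-centroid displacement."""
    pelvis = np.mean([markers.get(m) for m in PELVIS_MARKERS], axis=0)
    disp = pelvis[-1] - pelvis[0]
    disp[2] = 0.0
    norm = np.linalg.norm(disp)
    if norm < 1e-9:
        raise DegenerateGeometryError("pelvis shows no net horizontal displacement")
    return disp / norm


def segment_angle_sagittal(segment_vector: np.ndarray,
                           forward: np.ndarray = (1.0, 0.0, 0.0),
                           reference: str = "up") -> np.ndarray:
    """Signed sagittal-plane angle of a segment vector, degrees.

    The sagittal plane is spanned by the walking direction ``forward`` and
    vertical +Z.  The angle is measured between the reference vertical
    ("up" for torso, "down" for thigh) and the vector's sagittal projection;
    positive tips toward ``forward``.  Range (-180, 180].

    Raises
    ------
    DegenerateGeometryError
        if the sagittal projection has (near-)zero norm.
    """
    v = np.asarray(segment_vector, dtype=float)
    fwd = np.asarray(forward, dtype=float).copy()
    fwd[2] = 0.0
    n = np.linalg.norm(fwd)
    if n < 1e-12:
        raise DegenerateGeometryError("forward direction must be horizontal and nonzero")
    fwd /= n

    x = v[..., 0] * fwd[0] + v[..., 1] * fwd[1]   # forward component
    z = v[..., 2]                                  # vertical component
    norm = np.hypot(x, z)
    if np.any(norm < 1e-12):
        raise DegenerateGeometryError("segment vector projects to zero in the sagittal plane")
    if reference == "up":
        ang = np.degrees(np.arctan2(x, z))
    elif reference == "down":
        ang = np.degrees(np.arctan2(x, -z))
    else:
        raise ValueError("reference must be 'up' or 'down'")
    if np.ndim(ang) == 0:
        return float(ang)
    return ang


def angular_velocity(angle_deg: np.ndarray, sampling_rate: float) -> np.ndarray:
    """Time derivative of an angle series, deg/s.

    Central differences on interior samples, one-sided at the two ends
    (``numpy.gradient``).  Requires at least 3 samples.
    """
    angle_deg = np.asarray(angle_deg, dtype=float)
    if angle_deg.size < 3:
        raise ValueError("angular_velocity needs at least 3 samples")
    return np.gradient(angle_deg) * float(sampling_rate)


def lowpass_filter(series: np.ndarray, sampling_rate: float,
                   cutoff_hz: float = 6.0, order: int = 4) -> np.ndarray:
    """Optional zero-lag Butterworth low-pass (forward-backward)."""
    b, a = butter(order, cutoff_hz, fs=sampling_rate)
    return filtfilt(b, a, np.asarray(series, dtype=float))


def detect_events(grf: GrfTrace, threshold_n: float = 20.0,
                  debounce_s: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Heel-strikes (upward crossings) and toe-offs (downward crossings).

    A crossing within ``debounce_s`` of the previous accepted crossing of the
    same kind is discarded.  Crossing times are linearly interpolated between
    the bracketing samples.  A trace that never crosses yields empty arrays.
    """
    if threshold_n <= 0:
        raise ValueError("threshold must be positive")
    f = np.asarray(grf.force_n, dtype=float)
    t = grf.time_s
    above = f >= threshold_n
    ups = np.flatnonzero(~above[:-1] & above[1:]) + 1
    downs = np.flatnonzero(above[:-1] & ~above[1:]) + 1

    def _times(idx: np.ndarray) -> np.ndarray:
        out = []
        for i in idx:
            f0, f1 = f[i - 1], f[i]
            frac = 0.0 if f1 == f0 else (threshold_n - f0) / (f1 - f0)
            out.append(t[i - 1] + frac * (t[i] - t[i - 1]))
        return np.asarray(out)

    def _debounce(times: np.ndarray) -> np.ndarray:
        kept: list[float] = []
        for x in times:
            if not kept or x - kept[-1] >= debounce_s:
                kept.append(x)
        return np.asarray(kept)

    return _debounce(_times(ups)), _debounce(_times(downs))


def detect_heel_strikes(grf: GrfTrace, threshold_n: float = 20.0,
                        debounce_s: float = 0.1) -> np.ndarray:
    """Heel-strike times from a vertical GRF trace (see ``detect_events``)."""
    return detect_events(grf, threshold_n, debounce_s)[0]


def time_normalize_stride(time_s: np.ndarray, series: np.ndarray,
                          hs_start_s: float, hs_end_s: float,
                          n_points: int = 101) -> np.ndarray:
    """Resample one stride onto ``n_points`` evenly spaced phase points.

    Linear interpolation over [hs_start_s, hs_end_s], endpoints inclusive, so
    the result covers 0-100% of the gait cycle.
    """
    time_s = np.asarray(time_s, dtype=float)
    if not (hs_start_s < hs_end_s):
        raise ValueError("stride start must precede stride end")
    if hs_start_s < time_s[0] - 1e-9 or hs_end_s > time_s[-1] + 1e-9:
        raise ValueError("stride events lie outside the recorded time span")
    if n_points < 2:
        raise ValueError("n_points must be at least 2")
    f = interp1d(time_s, np.asarray(series, dtype=float), assume_sorted=True,
                 bounds_error=False, fill_value=(series[0], series[-1]))
    grid = np.linspace(hs_start_s, hs_end_s, n_points)
    return f(grid)
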