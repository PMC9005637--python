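"""Synthetic multi-speed walking cohorts for the gait-phase pipeline.

Emulates the structure of walkway gait datasets: per-subject, per-trial
sagittal thigh and torso segment angles and angular velocities at 100 Hz,
heel-strike/toe-off event times, and a speed-condition label (C1-C5 bins
from 0.0-0.4 up to 1.4-1.8 m/s).

The kinematic model, per subject:

* the thigh swings once per gait cycle — a sum of up to three harmonics of
  the stride frequency, dominated by the first (default ~40 deg peak to
  peak);
* the torso keeps a mean forward lean and oscillates around it exactly
  twice per gait cycle in the sagittal plane;
* stride durations follow walking speed (longer strides when slower) with
  multiplicative log-normal jitter per stride;
* trial-to-trial variability is a smooth, band-limited perturbation whose
  amplitude is largest at the slowest speeds and larger for the torso than
  for the thigh.  The torso angle additionally receives a slow postural
  drift, which corrupts the angle channel far more than its derivative —
  this is what makes torso angular velocity better phase-locked to the gait
  cycle than torso angular position, mirroring what inter-subject
  correlation analyses report on real walkway data.

Velocity channels are central-difference derivatives of the underlying
(smoothly perturbed) angles, so on noise-free trials velocity is consistent
with the angle channel by construction.  The torso's angle channel carries
additional estimation noise that its velocity channel does not share, and
the velocity channel carries its own small sensor noise — angle estimates
drift and wander while angular velocity is measured directly.

Everything is a pure function of its arguments and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, filtfilt

from .kinematics import GrfTrace, TrialRecording, angular_velocity

__all__ = [
    "SPEED_CONDITIONS",
    "SpeedCondition",
    "SubjectProfile",
    "VariabilityModel",
    "stride_duration_for_speed",
    "thigh_profile",
    "torso_profile",
    "sample_subject_profile",
    "generate_trial",
    "apply_variability",
    "generate_cohort",
    "synthetic_grf",
]


@dataclass(frozen=True)
class SpeedCondition:
    """One walking-speed bin, e.g. C2 = 0.4-0.8 m/s."""

    id: str
    speed_range_m_s: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.speed_range_m_s
        if not lo < hi:
            raise ValueError(f"empty speed range for {self.id}")

    def contains(self, speed: float) -> bool:
        lo, hi = self.speed_range_m_s
        return lo <= speed <= hi


#: the five walkway speed conditions
SPEED_CONDITIONS: dict[str, SpeedCondition] = {
    "C1": SpeedCondition("C1", (0.0, 0.4)),
    "C2": SpeedCondition("C2", (0.4, 0.8)),
    "C3": SpeedCondition("C3", (0.8, 1.2)),
    "C4": SpeedCondition("C4", (1.0, 1.4)),
    "C5": SpeedCondition("C5", (1.4, 1.8)),
}


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject gait pattern parameters.

    ``thigh_harmonics`` holds (amplitude_deg, phase_rad) pairs for harmonics
    1..k of the stride frequency; the torso oscillates at exactly twice the
    stride frequency around ``torso_lean_deg``.
    """

    subject_id: str
    stride_duration_scale: float = 1.0          # multiplies the speed->duration map
    thigh_harmonics: tuple[tuple[float, float], ...] = ((20.0, 0.0), (4.0, 1.0), (1.5, 2.0))
    thigh_offset_deg: float = 0.0
    torso_lean_deg: float = 5.0
    torso_osc_amp_deg: float = 1.5
    torso_osc_phase_rad: float = 0.0
    subject_noise: dict = field(default_factory=dict)  # per-signal extra scale
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.stride_duration_scale <= 0:
            raise ValueError("stride_duration_scale must be positive")
        if self.torso_osc_amp_deg < 0:
            raise ValueError("torso_osc_amp_deg must be non-negative")


@dataclass(frozen=True)
class VariabilityModel:
    """Speed-dependent perturbation amplitudes.

    Per-speed multipliers scale base standard deviations.  Torso-angle
    multipliers strictly decrease from C1 to C3 (variability is highest in
    slow walking) and thigh multipliers never exceed torso-angle multipliers
    — the thigh is the more stereotyped segment at every speed.
    """

    torso_angle_mult: dict[str, float] = field(default_factory=lambda: {
        "C1": 5.0, "C2": 2.5, "C3": 1.0, "C4": 1.15, "C5": 1.3})
    torso_vel_mult: dict[str, float] = field(default_factory=lambda: {
        "C1": 4.0, "C2": 2.0, "C3": 1.0, "C4": 1.1, "C5": 1.2})
    # thigh variability falls monotonically as walking speeds up (roughly
    # proportional to stride duration), unlike the torso whose correlation
    # peaks at comfortable speed
    thigh_mult: dict[str, float] = field(default_factory=lambda: {
        "C1": 1.6, "C2": 1.3, "C3": 1.0, "C4": 0.9, "C5": 0.8})
    phase_jitter_scale: float = 1.0
    # within-stride progression irregularity (fraction of a cycle, C3 level):
    # slow walking advances unevenly through the cycle, fast walking is
    # carried by momentum — multipliers fall steeply with speed
    phase_warp_sd_cycles: float = 0.008
    phase_warp_mult: dict[str, float] = field(default_factory=lambda: {
        "C1": 4.0, "C2": 1.5, "C3": 1.0, "C4": 0.6, "C5": 0.4})
    # base (C3-level) perturbation SDs
    thigh_noise_sd_deg: float = 0.3
    torso_drift_sd_deg: float = 2.0
    torso_noise_sd_deg: float = 0.4
    torso_vel_noise_sd_dps: float = 1.5

    def __post_init__(self) -> None:
        ta = self.torso_angle_mult
        if not (ta["C1"] > ta["C2"] > ta["C3"]):
            raise ValueError("torso-angle multipliers must strictly decrease C1 > C2 > C3")
        for c, m in self.thigh_mult.items():
            if m > ta[c] + 1e-12:
                raise ValueError(f"thigh multiplier exceeds torso multiplier at {c}")

    @classmethod
    def zero(cls) -> "VariabilityModel":
        """Noise-free cohort (multiplier ordering kept, amplitudes zero)."""
        return cls(phase_jitter_scale=0.0, phase_warp_sd_cycles=0.0,
                   thigh_noise_sd_deg=0.0, torso_drift_sd_deg=0.0,
                   torso_noise_sd_deg=0.0, torso_vel_noise_sd_dps=0.0)

    @classmethod
    def informative_torso(cls) -> "VariabilityModel":
        """Torso angle dominated by postural drift, torso velocity clean.

        Used for ablation experiments isolating the torso-velocity channel:
        the angle channel carries mostly low-frequency drift (uninformative
        about gait phase) while its derivative stays phase-locked, and the
        thigh is noisier than in the default cohort so a second informative
        channel measurably helps.
        """
        return cls(
            torso_angle_mult={"C1": 5.0, "C2": 3.0, "C3": 2.0, "C4": 2.2, "C5": 2.5},
            thigh_mult={"C1": 1.5, "C2": 1.3, "C3": 1.0, "C4": 0.85, "C5": 0.75},
            thigh_noise_sd_deg=2.2,
            torso_drift_sd_deg=8.0,
            torso_noise_sd_deg=3.0,
            torso_vel_noise_sd_dps=0.5,
        )


def stride_duration_for_speed(speed_m_s: float,
                              slow=(0.3, 1.6), fast=(1.6, 0.9)) -> float:
    """Nominal stride duration in seconds for a walking speed.

    Linear interpolation between (0.3 m/s, 1.6 s) and (1.6 m/s, 0.9 s),
    extrapolated and clipped to stay positive.
    """
    v0, d0 = slow
    v1, d1 = fast
    d = d0 + (speed_m_s - v0) * (d1 - d0) / (v1 - v0)
    return float(max(d, 0.4))


def _check_phi(phi) -> np.ndarray:
    phi = np.asarray(phi, dtype=float)
    if np.any(phi < 0) or np.any(phi > 100):
        raise ValueError("phi must lie in [0, 100]")
    return phi


def thigh_profile(phi, profile: SubjectProfile):
    """Noise-free thigh angle (deg) at percent-cycle phi in [0, 100].

    Periodic with period 100; one dominant oscillation per gait cycle.
    """
    phi = _check_phi(phi)
    theta = 2.0 * np.pi * phi / 100.0
    out = np.full(np.shape(phi), profile.thigh_offset_deg, dtype=float)
    for k, (amp, ph) in enumerate(profile.thigh_harmonics, start=1):
        out = out + amp * np.cos(k * theta - ph)
    return out if out.shape else float(out)


def torso_profile(phi, profile: SubjectProfile):
    """Noise-free torso angle (deg): mean forward lean plus a 2-per-cycle
    oscillation, so its cycle mean equals ``torso_lean_deg`` exactly."""
    phi = _check_phi(phi)
    theta = 2.0 * np.pi * phi / 100.0
    out = profile.torso_lean_deg + profile.torso_osc_amp_deg * np.cos(
        2.0 * theta - profile.torso_osc_phase_rad)
    return out if np.shape(out) else float(out)


def sample_subject_profile(subject_id: str, rng: np.random.Generator) -> SubjectProfile:
    """Draw an individual's gait pattern around the population defaults."""
    a1 = 20.0 * (1.0 + 0.10 * rng.standard_normal())
    a2 = 4.0 * (1.0 + 0.20 * rng.standard_normal())
    a3 = 1.5 * (1.0 + 0.30 * rng.standard_normal())
    harmonics = (
        (abs(a1), 0.1 * rng.standard_normal()),
        (abs(a2), 1.0 + 0.2 * rng.standard_normal()),
        (abs(a3), 2.0 + 0.3 * rng.standard_normal()),
    )
    return SubjectProfile(
        subject_id=subject_id,
        stride_duration_scale=float(np.exp(0.06 * rng.standard_normal())),
        thigh_harmonics=harmonics,
        thigh_offset_deg=float(2.0 * rng.standard_normal()),
        torso_lean_deg=float(5.0 + 1.5 * rng.standard_normal()),
        torso_osc_amp_deg=float(abs(1.5 * (1.0 + 0.15 * rng.standard_normal()))),
        torso_osc_phase_rad=float(0.25 * rng.standard_normal()),
        rng_seed=int(rng.integers(0, 2**31 - 1)),
    )


def _bandlimited_noise(n: int, fs: float, cutoff_hz: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Unit-SD smooth noise: low-pass-filtered white noise, renormalized."""
    white = rng.standard_normal(n + 200)            # pad against filter edges
    b, a = butter(4, cutoff_hz, fs=fs)
    smooth = filtfilt(b, a, white)[100:-100]
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def generate_trial(profile: SubjectProfile, condition: SpeedCondition,
                   variability: VariabilityModel, seed: int,
                   n_strides: int = 3, margin_s: float = 0.3,
                   sampling_rate: float = 100.0,
                   trial_id: str = "t0") -> TrialRecording:
    """Synthesize one clean walking trial, then perturb it.

    ``n_strides`` full gait cycles are bracketed by ``margin_s`` of walking
    on each side (outside the labeled region).  Heel-strikes and toe-offs
    (at 60% of each cycle) come from the jittered stride-duration sequence.
    """
    if n_strides < 1:
        raise ValueError("n_strides must be >= 1")
    rng = np.random.default_rng([seed & 0x7FFFFFFF, profile.rng_seed])
    speed = float(rng.uniform(*condition.speed_range_m_s))
    base_dur = stride_duration_for_speed(speed) * profile.stride_duration_scale
    jitter_sd = 0.03 * variability.phase_jitter_scale
    durs = base_dur * np.exp(jitter_sd * rng.standard_normal(n_strides))

    # n_strides labeled cycles delimited by n_strides+1 heel-strikes; the
    # walking continues through the margins (phase extrapolated linearly)
    hs = margin_s + np.concatenate([[0.0], np.cumsum(durs)])
    total = hs[-1] + margin_s
    n = int(np.floor(total * sampling_rate)) + 1
    t = np.arange(n) / sampling_rate
    cycles = np.interp(t, hs, np.arange(len(hs)))
    pre = t < hs[0]
    post = t > hs[-1]
    cycles[pre] = (t[pre] - hs[0]) / durs[0]
    cycles[post] = (len(hs) - 1) + (t[post] - hs[-1]) / durs[-1]
    # within-stride progression irregularity: slow walking lacks the
    # momentum that carries fast walking evenly through the cycle, so the
    # kinematic progression wanders around the event-anchored linear phase
    warp_sd = (variability.phase_warp_sd_cycles
               * variability.phase_warp_mult.get(condition.id, 1.0))
    if warp_sd > 0:
        cycles = cycles + warp_sd * _bandlimited_noise(n, sampling_rate, 0.8, rng)
    theta = 2.0 * np.pi * cycles

    # segment excursions grow with walking speed: stride length roughly
    # follows speed x stride duration (~65% longer from 0.6 to 1.6 m/s),
    # and thigh excursion tracks stride length
    amp_factor = float(np.clip(0.55 + 0.45 * speed, 0.5, 1.4))
    # waveform shape also changes with speed: the stance fraction shrinks
    # and peak timings shift by a few percent of the cycle as walking
    # speeds up, skewing the within-cycle waveform
    skew = 0.5 * (1.0 - speed)
    theta_w = theta + skew * np.sin(theta)
    thigh = np.full(n, profile.thigh_offset_deg)
    for k, (amp, ph) in enumerate(profile.thigh_harmonics, start=1):
        thigh = thigh + amp_factor * amp * np.cos(k * theta_w - ph)
    torso = profile.torso_lean_deg + amp_factor * profile.torso_osc_amp_deg * np.cos(
        2.0 * theta_w - profile.torso_osc_phase_rad)

    heel_strikes = hs
    stance_frac = 0.6
    toe_offs = heel_strikes[:-1] + stance_frac * np.diff(heel_strikes)

    clean = TrialRecording(
        subject_id=profile.subject_id,
        condition=condition.id,
        time_s=t,
        thigh_angle_deg=thigh,
        thigh_vel_dps=angular_velocity(thigh, sampling_rate),
        torso_angle_deg=torso,
        torso_vel_dps=angular_velocity(torso, sampling_rate),
        heel_strikes_s=heel_strikes,
        toe_offs_s=toe_offs,
        sampling_rate=sampling_rate,
        nominal_speed_m_s=speed,
        trial_id=trial_id,
        meta={"n_strides": n_strides, "clean": True},
    )
    return apply_variability(clean, variability,
                             seed=int(rng.integers(0, 2**31 - 1)))


def apply_variability(recording: TrialRecording, variability: VariabilityModel,
                      seed: int) -> TrialRecording:
    """Add smooth, speed-scaled perturbations to a trial's channels.

    The thigh angle receives band-limited (≈0-6 Hz) noise and its velocity
    is recomputed as the derivative of the perturbed angle.  The torso
    models a wearable-style sensor pair: actual torso motion acquires a
    slow (≈0-0.15 Hz) postural drift; the angle *channel* adds band-limited
    estimation noise on top, while the velocity *channel* is the derivative
    of the drifting motion (not of the angle channel's estimation noise)
    plus its own small band-limited sensor noise — angular velocity is
    measured directly in practice, whereas angle estimates drift and wander.
    Events and the time axis are unchanged; with zero amplitudes the
    recording is returned unchanged (velocities consistent with angles).
    """
    cond = recording.condition
    if cond not in variability.torso_angle_mult:
        raise ValueError(f"speed condition {cond!r} unknown to the variability model")
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    n = len(recording.time_s)
    fs = recording.sampling_rate

    def noise(sd: float, cutoff: float) -> np.ndarray:
        # always consume the stream so zero-amplitude stays seed-compatible
        raw = _bandlimited_noise(n, fs, cutoff, rng)
        return sd * raw

    thigh = recording.thigh_angle_deg + noise(
        variability.thigh_noise_sd_deg * variability.thigh_mult[cond], 6.0)
    torso_motion = recording.torso_angle_deg + noise(
        variability.torso_drift_sd_deg * variability.torso_angle_mult[cond], 0.15)
    torso = torso_motion + noise(
        variability.torso_noise_sd_deg * variability.torso_angle_mult[cond], 6.0)
    torso_vel = angular_velocity(torso_motion, fs) + noise(
        variability.torso_vel_noise_sd_dps * variability.torso_vel_mult[cond], 6.0)

    return replace(
        recording,
        thigh_angle_deg=thigh,
        thigh_vel_dps=angular_velocity(thigh, fs),
        torso_angle_deg=torso,
        torso_vel_dps=torso_vel,
        meta={**recording.meta, "clean": False,
              "variability_seed": int(seed & 0x7FFFFFFF)},
    )


def generate_cohort(n_subjects: int,
                    conditions=("C1", "C2", "C3", "C4", "C5"),
                    trials_per_condition: int = 1,
                    variability: VariabilityModel | None = None,
                    seed: int = 0,
                    n_strides: int = 3) -> list[TrialRecording]:
    """Generate a labeled cohort: subjects x conditions x trials.

    Returns ``n_subjects * len(conditions) * trials_per_condition`` trial
    recordings at 100 Hz, deterministically from ``seed``.
    """
    if n_subjects < 1 or trials_per_condition < 1:
        raise ValueError("n_subjects and trials_per_condition must be >= 1")
    variability = variability if variability is not None else VariabilityModel()
    conds = [SPEED_CONDITIONS[c] if isinstance(c, str) else c for c in conditions]
    master = np.random.default_rng(seed & 0x7FFFFFFF)
    recordings: list[TrialRecording] = []
    for i in range(n_subjects):
        profile = sample_subject_profile(f"S{i + 1:03d}", master)
        for cond in conds:
            for j in range(trials_per_condition):
                trial_seed = int(master.integers(0, 2**31 - 1))
                recordings.append(generate_trial(
                    profile, cond, variability, trial_seed,
                    n_strides=n_strides, trial_id=f"{cond.id}_t{j:02d}"))
    return recordings


def synthetic_grf(heel_strikes_s: np.ndarray, toe_offs_s: np.ndarray,
                  duration_s: float, body_weight_n: float = 700.0,
                  sampling_rate: float = 1500.0) -> GrfTrace:
    """Simple vertical-GRF template for testing event detection.

    Each stance phase (heel-strike to the paired toe-off) carries a
    double-hump vertical force profile with a very steep onset/offset so the
    threshold crossing stays within one sample of the nominal event time.
    """
    n = int(round(duration_s * sampling_rate)) + 1
    t = np.arange(n) / sampling_rate
    f = np.zeros(n)
    for k, hs in enumerate(heel_strikes_s):
        if k >= len(toe_offs_s):
            break
        to = toe_offs_s[k]
        in_stance = (t >= hs) & (t <= to)
        s = (t[in_stance] - hs) / (to - hs)
        hump = np.sqrt(np.clip(np.sin(np.pi * s), 0.0, None))
        f[in_stance] = body_weight_n * hump * (1.0 + 0.15 * np.sin(2 * np.pi * s))
    return GrfTrace(force_n=f, sampling_rate=sampling_rate)
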