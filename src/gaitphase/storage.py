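"""Container formats: HDF5 cohorts (canonical) and CSV trials (interchange).

HDF5 layout: one group per subject, one subgroup per trial, one dataset per
channel, with speed condition, nominal speed, sampling rate and event times
stored as attributes.  CSV trials carry the five channel columns
(time_s, thigh_angle_deg, thigh_vel_dps, torso_angle_deg, torso_vel_dps)
with events in a ``*_events.csv`` sidecar — simulated and real data are
interchangeable downstream because both flow through these readers.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .kinematics import CHANNELS, TrialRecording

__all__ = ["save_cohort", "load_cohort", "save_trial_csv", "load_trial_csv"]


def save_cohort(cohort: list[TrialRecording], path: str | Path) -> None:
    """Write a cohort to one HDF5 file (see module docstring for layout)."""
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "gaitphase-cohort"
        f.attrs["version"] = 1
        for rec in cohort:
            g = f.require_group(f"subjects/{rec.subject_id}/trials/{rec.trial_id}")
            g.create_dataset("time_s", data=rec.time_s)
            for ch in CHANNELS:
                g.create_dataset(ch, data=rec.channel(ch))
            g.attrs["condition"] = rec.condition
            g.attrs["sampling_rate"] = rec.sampling_rate
            g.attrs["nominal_speed_m_s"] = rec.nominal_speed_m_s
            g.attrs["heel_strikes_s"] = rec.heel_strikes_s
            g.attrs["toe_offs_s"] = rec.toe_offs_s


def load_cohort(path: str | Path) -> list[TrialRecording]:
    """Read a cohort HDF5 file back into trial recordings."""
    out: list[TrialRecording] = []
    with h5py.File(path, "r") as f:
        for sid in sorted(f["subjects"]):
            trials = f[f"subjects/{sid}/trials"]
            for tid in sorted(trials):
                g = trials[tid]
                out.append(TrialRecording(
                    subject_id=sid,
                    trial_id=tid,
                    condition=str(g.attrs["condition"]),
                    time_s=g["time_s"][:],
                    thigh_angle_deg=g["thigh_angle_deg"][:],
                    thigh_vel_dps=g["thigh_vel_dps"][:],
                    torso_angle_deg=g["torso_angle_deg"][:],
                    torso_vel_dps=g["torso_vel_dps"][:],
                    heel_strikes_s=np.asarray(g.attrs["heel_strikes_s"]),
                    toe_offs_s=np.asarray(g.attrs["toe_offs_s"]),
                    sampling_rate=float(g.attrs["sampling_rate"]),
                    nominal_speed_m_s=float(g.attrs["nominal_speed_m_s"]),
                ))
    return out


def save_trial_csv(rec: TrialRecording, path: str | Path) -> None:
    """Write one trial as CSV plus an events sidecar."""
    path = Path(path)
    df = pd.DataFrame({"time_s": rec.time_s,
                       **{ch: rec.channel(ch) for ch in CHANNELS}})
    df.to_csv(path, index=False)
    events = pd.DataFrame(
        [("heel_strike", t) for t in rec.heel_strikes_s]
        + [("toe_off", t) for t in rec.toe_offs_s],
        columns=["event", "time_s"]).sort_values("time_s")
    events.to_csv(path.with_name(path.stem + "_events.csv"), index=False)


def load_trial_csv(path: str | Path, subject_id: str = "S001",
                   condition: str = "C3", trial_id: str = "t0") -> TrialRecording:
    """Read one trial from the CSV dialect (with its events sidecar)."""
    path = Path(path)
    if path.suffix.lower() == ".c3d":
        raise NotImplementedError(
            "C3D ingestion is not supported in this build; export markers "
            "and events to the CSV dialect instead")
    df = pd.read_csv(path)
    missing = {"time_s", *CHANNELS} - set(df.columns)
    if missing:
        raise ValueError(f"trial CSV missing columns: {sorted(missing)}")
    events = pd.read_csv(path.with_name(path.stem + "_events.csv"))
    hs = events.loc[events["event"] == "heel_strike", "time_s"].to_numpy()
    to = events.loc[events["event"] == "toe_off", "time_s"].to_numpy()
    t = df["time_s"].to_numpy()
    fs = 1.0 / float(np.median(np.diff(t)))
    return TrialRecording(
        subject_id=subject_id, condition=condition, trial_id=trial_id,
        time_s=t,
        thigh_angle_deg=df["thigh_angle_deg"].to_numpy(),
        thigh_vel_dps=df["thigh_vel_dps"].to_numpy(),
        torso_angle_deg=df["torso_angle_deg"].to_numpy(),
        torso_vel_dps=df["torso_vel_dps"].to_numpy(),
        heel_strikes_s=np.sort(hs), toe_offs_s=np.sort(to),
        sampling_rate=fs)
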