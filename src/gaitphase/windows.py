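"""Sliding-window dataset construction for sequence-to-one phase regression.

A window is ``window_len`` consecutive samples of the chosen feature
channels; its target is the polar-encoded phase (px, py) at the window's
final sample, i.e. the phase "now" given the last second of motion.
Windows are only built where every sample is labeled (between the first and
last heel-strike), so no window spans an unlabeled gap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinematics import TrialRecording
from .phase import GaitPhaseSeries, label_recording

__all__ = ["WindowBatch", "make_windows", "build_dataset"]

DEFAULT_WINDOW_LEN = 100


@dataclass
class WindowBatch:
    """Sliding windows plus their (px, py) targets and provenance.

    windows : (n_windows, window_len, n_channels)
    targets : (n_windows, 2), each row on the unit circle
    provenance : DataFrame with subject, trial, condition, end_index,
        end_time_s, phi — one row per window, aligned to sample times.
    """

    windows: np.ndarray
    targets: np.ndarray
    provenance: pd.DataFrame
    channels: tuple[str, ...]
    window_len: int

    def __len__(self) -> int:
        return self.windows.shape[0]

    @staticmethod
    def concatenate(batches: list["WindowBatch"]) -> "WindowBatch":
        batches = [b for b in batches if len(b)]
        if not batches:
            raise ValueError("no non-empty batches to concatenate")
        ref = batches[0]
        for b in batches[1:]:
            if b.channels != ref.channels or b.window_len != ref.window_len:
                raise ValueError("batches disagree on channels or window length")
        return WindowBatch(
            windows=np.concatenate([b.windows for b in batches]),
            targets=np.concatenate([b.targets for b in batches]),
            provenance=pd.concat([b.provenance for b in batches], ignore_index=True),
            channels=ref.channels,
            window_len=ref.window_len,
        )

    def subset(self, mask: np.ndarray) -> "WindowBatch":
        return WindowBatch(self.windows[mask], self.targets[mask],
                           self.provenance[mask].reset_index(drop=True),
                           self.channels, self.window_len)


def make_windows(recording: TrialRecording, channels,
                 window_len: int = DEFAULT_WINDOW_LEN, stride: int = 1,
                 phase: GaitPhaseSeries | None = None) -> WindowBatch:
    """Build sliding windows (stride-1 by default) over one labeled trial.

    ``stride`` > 1 subsamples window end positions (used to thin training
    sets); targets always belong to each window's final sample.  A trial
    with fewer labeled samples than ``window_len`` yields an empty batch
    with a warning, not an error.
    """
    if window_len < 1 or stride < 1:
        raise ValueError("window_len and stride must be positive")
    channels = tuple(channels)
    phase = phase if phase is not None else label_recording(
        recording.time_s, recording.heel_strikes_s)
    feats = recording.channel_matrix(channels)
    labeled = phase.labeled

    # an end index e is valid when samples [e-window_len+1, e] are all labeled
    ok = np.convolve(labeled.astype(int), np.ones(window_len, int),
                     mode="valid") == window_len
    ends = np.flatnonzero(ok) + window_len - 1
    ends = ends[::stride]
    if ends.size == 0:
        warnings.warn(
            f"trial {recording.subject_id}/{recording.trial_id}: fewer than "
            f"{window_len} contiguous labeled samples; empty window batch",
            stacklevel=2)
        prov = pd.DataFrame(columns=["subject", "trial", "condition",
                                     "end_index", "end_time_s", "phi"])
        return WindowBatch(np.empty((0, window_len, len(channels))),
                           np.empty((0, 2)), prov, channels, window_len)

    starts = ends - window_len + 1
    idx = starts[:, None] + np.arange(window_len)[None, :]
    windows = feats[idx]
    targets = np.column_stack([phase.px[ends], phase.py[ends]])
    prov = pd.DataFrame({
        "subject": recording.subject_id,
        "trial": recording.trial_id,
        "condition": recording.condition,
        "end_index": ends,
        "end_time_s": recording.time_s[ends],
        "phi": phase.phi[ends],
    })
    return WindowBatch(windows, targets, prov, channels, window_len)


def build_dataset(recordings, channels, window_len: int = DEFAULT_WINDOW_LEN,
                  stride: int = 1) -> WindowBatch:
    """Window every recording and concatenate into one batch."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        batches = [make_windows(r, channels, window_len, stride) for r in recordings]
    return WindowBatch.concatenate(batches)
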