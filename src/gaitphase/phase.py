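"""Gait-phase ground truth: percent-cycle, polar encoding, and linear decoding.

The gait cycle runs from one heel-strike to the next heel-strike of the same
leg.  Percent-cycle ``phi`` in [0, 100] is anchored at heel-strike (phi = 0)
and grows linearly in time between consecutive strikes.  Because the linear
label jumps from 100 to 0 at every heel-strike, training targets use the
polar encoding

    theta = 2*pi/100 * phi,      (px, py) = (cos theta, sin theta)

which is continuous across the cycle boundary.  Predictions are mapped back
to a bounded linear phase

    tau = atan2(py, px) / (2*pi),    tau_hat = tau + 1 if py < 0 else tau

so that ``tau_hat`` lives in [0, 1) with exact 0 at heel-strike.  Decoding
uses only the angle of (px, py), so it is invariant to positive rescaling of
the outputs — network outputs need not lie exactly on the unit circle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GaitPhaseSeries",
    "phase_from_events",
    "encode",
    "decode",
    "label_recording",
]


@dataclass(frozen=True)
class GaitPhaseSeries:
    """Per-sample gait-phase ground truth for one trial.

    Samples outside the first..last heel-strike span are unlabeled and carry
    NaN in every field; downstream windowing and evaluation exclude them.
    """

    phi: np.ndarray        # percent of cycle, [0, 100)
    theta: np.ndarray      # radians, [0, 2*pi)
    px: np.ndarray         # cos(theta)
    py: np.ndarray         # sin(theta)
    tau_hat: np.ndarray    # linear phase, [0, 1)

    @property
    def labeled(self) -> np.ndarray:
        """Boolean mask of labeled samples."""
        return ~np.isnan(self.phi)

    def __len__(self) -> int:
        return len(self.phi)


def phase_from_events(time_s: np.ndarray, heel_strikes_s: np.ndarray) -> np.ndarray:
    """Percent-of-cycle phi for each sample time, anchored at heel-strikes.

    Between consecutive heel-strikes phi rises linearly from 0 to 100; a
    sample exactly at a heel-strike starts the new cycle (phi = 0).  Samples
    before the first or after the last heel-strike get NaN (unlabeled).

    Parameters
    ----------
    time_s : array of sample times, seconds
    heel_strikes_s : strictly increasing event times, at least two

    Returns
    -------
    phi : array like ``time_s``, values in [0, 100) or NaN
    """
    time_s = np.asarray(time_s, dtype=float)
    hs = np.asarray(heel_strikes_s, dtype=float)
    if hs.ndim != 1 or hs.size < 2:
        raise ValueError(
            f"phase labeling needs at least 2 heel-strikes, got {hs.size}"
        )
    if np.any(np.diff(hs) <= 0):
        raise ValueError("heel-strike times must be strictly increasing")

    phi = np.full(time_s.shape, np.nan)
    # cycle index of each sample: hs[k] <= t < hs[k+1]
    idx = np.searchsorted(hs, time_s, side="right") - 1
    inside = (idx >= 0) & (idx < hs.size - 1)
    k = idx[inside]
    t0 = hs[k]
    t1 = hs[k + 1]
    phi[inside] = 100.0 * (time_s[inside] - t0) / (t1 - t0)
    # the final heel-strike itself begins a cycle with no successor: unlabeled
    return phi


def encode(phi):
    """Map percent-cycle phi in [0, 100] to (theta, px, py).

    NaN phi (unlabeled samples) propagates to NaN outputs.
    """
    phi = np.asarray(phi, dtype=float)
    finite = phi[~np.isnan(phi)]
    if finite.size and (finite.min() < 0 or finite.max() > 100):
        raise ValueError("phi must lie in [0, 100]")
    theta = 2.0 * np.pi * phi / 100.0
    return theta, np.cos(theta), np.sin(theta)


def decode(px, py):
    """Map (px, py) back to the bounded linear phase tau_hat in [0, 1).

    ``tau = atan2(py, px) / (2*pi)`` with 1 added on the lower half-plane
    (py < 0).  Inputs need not be unit-norm; (0, 0) has no phase and raises.
    """
    px = np.asarray(px, dtype=float)
    py = np.asarray(py, dtype=float)
    if np.any((px == 0) & (py == 0)):
        raise ValueError("phase undefined at (px, py) = (0, 0)")
    tau = np.arctan2(py, px) / (2.0 * np.pi)
    tau_hat = np.where(py < 0, tau + 1.0, tau)
    # atan2(-0.0, x>0) style edge: fold an exact 1.0 back to 0.0
    tau_hat = np.where(tau_hat >= 1.0, tau_hat - 1.0, tau_hat)
    if px.ndim == 0 and py.ndim == 0:
        return float(tau_hat)
    return tau_hat


def label_recording(time_s, heel_strikes_s) -> GaitPhaseSeries:
    """Build the full ground-truth series for one trial."""
    phi = phase_from_events(time_s, heel_strikes_s)
    theta, px, py = encode(phi)
    tau_hat = np.full_like(phi, np.nan)
    ok = ~np.isnan(phi)
    tau_hat[ok] = decode(px[ok], py[ok])
    return GaitPhaseSeries(phi=phi, theta=theta, px=px, py=py, tau_hat=tau_hat)
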