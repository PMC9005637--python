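"""Inter-subject kinematic variability via trajectory correlation matrices.

For one signal at one speed condition, every subject's strides are
time-normalized to 101 phase points (0-100% inclusive) and averaged into a
per-subject mean trajectory S_i; the grand mean A averages the S_i.  The
(n+1) x (n+1) Pearson correlation matrix over [A, S_1 .. S_n] — 51 x 51 for
a 50-subject cohort — is summarized by its first row: the mean and sample
SD of corr(A, S_i) over subjects.  High values mean a stereotyped,
population-consistent trajectory; the thigh scores near 1 at every speed
while torso correlations fall off sharply as walking slows.

A is computed over all subjects (each S_i is correlated against a grand
mean that includes itself, biasing coefficients up by O(1/n)); a
leave-one-out variant is available and the bias is asserted negligible at
cohort scale in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinematics import TrialRecording, time_normalize_stride

__all__ = [
    "TrajectoryBundle",
    "CorrelationSummary",
    "subject_mean_trajectory",
    "trajectory_bundle",
    "correlation_matrix",
    "summarize",
    "cohort_correlation_summary",
    "plot_correlation_heatmap",
]

N_POINTS = 101


@dataclass
class TrajectoryBundle:
    """Grand-mean and per-subject mean trajectories for one signal/speed."""

    grand_mean: np.ndarray                 # (n_points,)
    subject_means: dict[str, np.ndarray]   # subject id -> (n_points,)
    signal: str
    condition: str

    @property
    def n_subjects(self) -> int:
        return len(self.subject_means)


@dataclass
class CorrelationSummary:
    """Mean +/- SD of corr(A, S_i) for one signal at one speed."""

    signal: str
    condition: str
    mean: float
    sd: float
    n_subjects: int


def _strides(recording: TrialRecording, signal: str,
             n_points: int) -> list[np.ndarray]:
    hs = recording.heel_strikes_s
    series = recording.channel(signal)
    return [time_normalize_stride(recording.time_s, series, hs[k], hs[k + 1],
                                  n_points)
            for k in range(len(hs) - 1)]


def subject_mean_trajectory(recordings: list[TrialRecording], signal: str,
                            n_points: int = N_POINTS) -> np.ndarray:
    """Pointwise mean of every time-normalized stride of one subject.

    ``recordings`` should be one subject's trials at one speed condition.
    """
    strides: list[np.ndarray] = []
    for rec in recordings:
        strides.extend(_strides(rec, signal, n_points))
    if not strides:
        raise ValueError("no complete stride available for subject mean")
    return np.mean(strides, axis=0)


def trajectory_bundle(cohort: list[TrialRecording], signal: str,
                      condition: str, n_points: int = N_POINTS,
                      leave_one_out: bool = False) -> TrajectoryBundle:
    """Collect per-subject mean trajectories at one speed condition."""
    by_subject: dict[str, list[TrialRecording]] = {}
    for rec in cohort:
        if rec.condition == condition:
            by_subject.setdefault(rec.subject_id, []).append(rec)
    if not by_subject:
        raise ValueError(f"no recordings at condition {condition!r}")
    means = {sid: subject_mean_trajectory(recs, signal, n_points)
             for sid, recs in sorted(by_subject.items())}
    grand = np.mean(list(means.values()), axis=0)
    return TrajectoryBundle(grand_mean=grand, subject_means=means,
                            signal=signal, condition=condition)


def correlation_matrix(bundle: TrajectoryBundle,
                       leave_one_out: bool = False) -> tuple[np.ndarray, list[str]]:
    """Pearson correlations among [A, S_1 .. S_n]; A first.

    With ``leave_one_out`` the first row/column holds corr(A_{-i}, S_i),
    where A_{-i} excludes subject i from the grand mean (off-first-row
    entries are unchanged).
    """
    if bundle.n_subjects < 2:
        raise ValueError("correlation matrix needs at least 2 subjects")
    labels = ["A"] + list(bundle.subject_means.keys())
    rows = [bundle.grand_mean] + list(bundle.subject_means.values())
    for lab, tr in zip(labels, rows):
        if np.std(tr) < 1e-12:
            raise ValueError(f"trajectory {lab!r} is constant; correlation undefined")
    mat = np.corrcoef(np.asarray(rows))
    if leave_one_out:
        n = bundle.n_subjects
        for i, (sid, s) in enumerate(bundle.subject_means.items(), start=1):
            a_loo = (bundle.grand_mean * n - s) / (n - 1)
            if np.std(a_loo) < 1e-12:
                raise ValueError(f"leave-one-out mean without {sid!r} is constant")
            mat[0, i] = mat[i, 0] = np.corrcoef(a_loo, s)[0, 1]
    return mat, labels


def summarize(matrix: np.ndarray, labels: list[str], signal: str = "",
              condition: str = "") -> CorrelationSummary:
    """Mean +/- sample SD over the first row's off-diagonal entries."""
    if labels[0] != "A":
        raise ValueError("matrix must be ordered with the grand mean 'A' first")
    coeffs = np.asarray(matrix)[0, 1:]
    if coeffs.size < 2:
        raise ValueError("need at least 2 subjects to summarize")
    return CorrelationSummary(signal=signal, condition=condition,
                              mean=float(np.mean(coeffs)),
                              sd=float(np.std(coeffs, ddof=1)),
                              n_subjects=int(coeffs.size))


def plot_correlation_heatmap(matrix: np.ndarray, labels: list[str],
                             path=None, title: str = ""):
    """Correlation-matrix heatmap: blue positive, red negative, white ~0.

    Requires matplotlib (the ``plot`` extra).  Returns the figure; saves to
    ``path`` when given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(matrix, cmap="RdBu", vmin=-1.0, vmax=1.0)
    step = max(1, len(labels) // 10)
    ticks = range(0, len(labels), step)
    ax.set_xticks(list(ticks), [labels[i] for i in ticks], rotation=90,
                  fontsize=7)
    ax.set_yticks(list(ticks), [labels[i] for i in ticks], fontsize=7)
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def cohort_correlation_summary(cohort: list[TrialRecording],
                               signals=("thigh_angle_deg", "thigh_vel_dps",
                                        "torso_angle_deg", "torso_vel_dps"),
                               conditions=("C1", "C2", "C3", "C4", "C5"),
                               n_points: int = N_POINTS,
                               leave_one_out: bool = False) -> pd.DataFrame:
    """Correlation-summary table: rows = speed conditions, columns = signals.

    Each cell holds the mean (``<signal>``) and sample SD (``<signal>_sd``)
    of the per-subject correlations against the grand-mean trajectory.
    """
    present = {r.condition for r in cohort}
    rows = []
    for cond in conditions:
        if cond not in present:
            continue
        row: dict = {"condition": cond}
        for sig in signals:
            bundle = trajectory_bundle(cohort, sig, cond, n_points)
            mat, labels = correlation_matrix(bundle, leave_one_out)
            s = summarize(mat, labels, sig, cond)
            row[sig] = s.mean
            row[f"{sig}_sd"] = s.sd
        rows.append(row)
    return pd.DataFrame(rows).set_index("condition")
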