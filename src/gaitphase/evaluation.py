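"""Error metrics and factorial statistics for phase-estimation experiments.

Metrics:

* MSE on the polar outputs (px, py) — the training-loss space;
* circular absolute error on the linear phase tau_hat, which respects the
  wrap-around at heel-strike (max possible error 0.5 cycle);
* mid-stance MSE restricted to ground-truth phi in [30, 50]% of the cycle,
  where slow-walking estimators degrade;
* heel-strike detection error: each downward wrap of the predicted phase
  marks a predicted heel-strike; predicted and actual events are matched
  greedily (nearest first) within a window and the signed/absolute temporal
  differences are summarized.

Statistics: two-way ANOVA with interaction (statsmodels OLS, type-II sums
of squares) plus Bonferroni-corrected pairwise Welch t-tests per factor,
with the usual significance stars at 0.05 / 0.01 / 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "PhaseErrorReport",
    "HeelStrikeErrorReport",
    "mse_polar",
    "circular_phase_error",
    "midstance_mse",
    "phase_error_report",
    "predicted_heel_strikes",
    "heel_strike_error",
    "factorial_anova",
    "significance_stars",
]


@dataclass
class PhaseErrorReport:
    """Per-trial phase-error summary."""

    mse_polar: float
    circ_err_mean: float
    circ_err_sd: float
    midstance_mse: float
    n_samples: int


@dataclass
class HeelStrikeErrorReport:
    """Matched heel-strike timing errors for one trial."""

    signed_errors_s: np.ndarray      # predicted - actual, matched pairs
    n_missed: int                    # actual events with no match
    n_false: int                     # predicted events with no match

    @property
    def abs_mean_s(self) -> float:
        return float(np.mean(np.abs(self.signed_errors_s))) if len(self.signed_errors_s) else np.nan

    @property
    def abs_sd_s(self) -> float:
        return float(np.std(np.abs(self.signed_errors_s), ddof=1)) if len(self.signed_errors_s) > 1 else 0.0


def mse_polar(targets: np.ndarray, predictions: np.ndarray) -> float:
    """Mean squared error over both polar outputs jointly."""
    targets = np.asarray(targets, dtype=float)
    predictions = np.asarray(predictions, dtype=float)
    if targets.shape != predictions.shape:
        raise ValueError("targets and predictions must share shape")
    return float(np.mean((targets - predictions) ** 2))


def circular_phase_error(tau_true, tau_pred):
    """Wrap-aware absolute phase error: min(|d|, 1 - |d|), in [0, 0.5]."""
    tau_true = np.asarray(tau_true, dtype=float)
    tau_pred = np.asarray(tau_pred, dtype=float)
    for name, x in (("tau_true", tau_true), ("tau_pred", tau_pred)):
        if np.any(x < 0) or np.any(x >= 1):
            raise ValueError(f"{name} must lie in [0, 1)")
    d = np.abs(tau_pred - tau_true)
    err = np.minimum(d, 1.0 - d)
    return float(err) if err.ndim == 0 else err


def midstance_mse(phi_true, targets, predictions,
                  lo: float = 30.0, hi: float = 50.0) -> float:
    """Polar MSE restricted to samples with ground-truth phi in [lo, hi]%."""
    phi_true = np.asarray(phi_true, dtype=float)
    mask = (phi_true >= lo) & (phi_true <= hi)
    if not np.any(mask):
        return float("nan")
    return mse_polar(np.asarray(targets)[mask], np.asarray(predictions)[mask])


def phase_error_report(phi_true, targets, predictions, tau_pred=None) -> PhaseErrorReport:
    """Bundle the per-trial phase metrics."""
    from .phase import decode

    targets = np.asarray(targets, dtype=float)
    predictions = np.asarray(predictions, dtype=float)
    if tau_pred is None:
        tau_pred = decode(predictions[:, 0], predictions[:, 1])
    tau_true = np.asarray(phi_true, dtype=float) / 100.0
    tau_true = np.where(tau_true >= 1.0, tau_true - 1.0, tau_true)
    ce = circular_phase_error(tau_true, tau_pred)
    return PhaseErrorReport(
        mse_polar=mse_polar(targets, predictions),
        circ_err_mean=float(np.mean(ce)),
        circ_err_sd=float(np.std(ce, ddof=1)) if len(ce) > 1 else 0.0,
        midstance_mse=midstance_mse(phi_true, targets, predictions),
        n_samples=len(ce),
    )


def predicted_heel_strikes(tau_pred: np.ndarray, time_s: np.ndarray) -> np.ndarray:
    """Heel-strike times implied by downward wraps of a predicted phase.

    A wrap is a drop of more than 0.5 between consecutive samples; the event
    time is linearly interpolated to where the (unwrapped) phase crosses the
    cycle boundary.  A monotone non-wrapping series yields no events.
    """
    tau_pred = np.asarray(tau_pred, dtype=float)
    time_s = np.asarray(time_s, dtype=float)
    if tau_pred.shape != time_s.shape:
        raise ValueError("tau_pred and time_s must align")
    if len(tau_pred) < 2:
        return np.empty(0)
    d = np.diff(tau_pred)
    wraps = np.flatnonzero(d < -0.5)
    events = []
    for k in wraps:
        rise = (tau_pred[k + 1] + 1.0) - tau_pred[k]   # unwrapped increment
        frac = (1.0 - tau_pred[k]) / rise if rise > 0 else 0.0
        events.append(time_s[k] + frac * (time_s[k + 1] - time_s[k]))
    return np.asarray(events)


def heel_strike_error(actual_s, predicted_s,
                      max_match_window_s: float) -> HeelStrikeErrorReport:
    """Greedy nearest-first matching of predicted to actual heel-strikes.

    Each event participates in at most one match; pairs farther apart than
    ``max_match_window_s`` remain unmatched and are counted as misses
    (actual) or false detections (predicted).
    """
    actual = np.asarray(actual_s, dtype=float)
    predicted = np.asarray(predicted_s, dtype=float)
    for name, x in (("actual", actual), ("predicted", predicted)):
        if x.size > 1 and np.any(np.diff(x) < 0):
            raise ValueError(f"{name} event times must be sorted")
    if actual.size == 0 or predicted.size == 0:
        return HeelStrikeErrorReport(np.empty(0), int(actual.size), int(predicted.size))
    diff = predicted[:, None] - actual[None, :]
    cand = [(abs(diff[i, j]), i, j)
            for i in range(predicted.size) for j in range(actual.size)
            if abs(diff[i, j]) <= max_match_window_s]
    cand.sort(key=lambda c: c[0])
    used_p: set[int] = set()
    used_a: set[int] = set()
    signed = []
    for _, i, j in cand:
        if i in used_p or j in used_a:
            continue
        used_p.add(i)
        used_a.add(j)
        signed.append(diff[i, j])
    return HeelStrikeErrorReport(
        signed_errors_s=np.asarray(signed),
        n_missed=int(actual.size - len(used_a)),
        n_false=int(predicted.size - len(used_p)),
    )


def significance_stars(p: float) -> str:
    """The *, **, *** convention at 0.05 / 0.01 / 0.001."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def factorial_anova(table: pd.DataFrame, value: str, factor_a: str,
                    factor_b: str, alpha: float = 0.05):
    """Two-way ANOVA with interaction plus Bonferroni pairwise comparisons.

    Observations are per-trial error values; each (factor_a, factor_b) cell
    needs at least one observation and each factor at least two levels.
    Returns ``(anova_table, pairwise)`` where ``anova_table`` is the type-II
    ANOVA with a ``stars`` column and ``pairwise`` holds per-factor level
    pairs with raw and Bonferroni-adjusted p-values (raw p times the number
    of comparisons in that family, capped at 1).
    """
    df = table[[value, factor_a, factor_b]].dropna().copy()
    for f in (factor_a, factor_b):
        if df[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs at least 2 levels")
    counts = df.groupby([factor_a, factor_b], observed=True).size()
    full = df[factor_a].nunique() * df[factor_b].nunique()
    if len(counts) < full:
        raise ValueError(
            "unbalanced design with empty cells; collect at least one "
            "observation per cell (type-II sums of squares cannot rescue "
            "missing cells)")
    model = smf.ols(f"Q('{value}') ~ C(Q('{factor_a}')) * C(Q('{factor_b}'))",
                    data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    anova["stars"] = [significance_stars(p) if np.isfinite(p) else ""
                      for p in anova["PR(>F)"]]

    rows = []
    for f in (factor_a, factor_b):
        levels = sorted(df[f].unique())
        pairs = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1:]]
        m = len(pairs)
        for a, b in pairs:
            xa = df.loc[df[f] == a, value]
            xb = df.loc[df[f] == b, value]
            t, p = stats.ttest_ind(xa, xb, equal_var=False)
            p_adj = min(1.0, p * m)
            rows.append({"factor": f, "level_a": a, "level_b": b,
                         "mean_a": xa.mean(), "mean_b": xb.mean(),
                         "t": t, "p_raw": p, "p_bonferroni": p_adj,
                         "significant": p_adj <= alpha,
                         "stars": significance_stars(p_adj)})
    return anova, pd.DataFrame(rows)
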