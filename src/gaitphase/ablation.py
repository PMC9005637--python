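"""Feature-ablation x speed-model experiment grid.

Feature sets (thigh channels always included):

* Set 1 — thigh angle, thigh velocity, torso angle, torso velocity
* Set 2 — thigh angle, thigh velocity, torso velocity
* Set 3 — thigh angle, thigh velocity, torso angle
* Set 4 — thigh angle, thigh velocity (baseline)

Speed-dependent models, by training conditions:

* general     — C2, C3, C4, C5
* slow        — C2 only
* normal_fast — C3, C4, C5

C1 (0.0-0.4 m/s) is never trained on: it denotes extremely slow walking.
The full grid is 4 sets x 3 models = 12 trained networks.  All cells share
one subject partition — training, validation and prediction subjects are
pairwise disjoint — and derive their seeds from one base seed plus a stable
per-cell hash, so any cell is reproducible in isolation.  Every cell is
evaluated per speed condition (C2-C5) on the held-out prediction subjects:
polar MSE, circular phase error, mid-stance MSE, and heel-strike detection
error from wraps of the predicted phase.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimator import PhaseLSTMRegressor
from .evaluation import heel_strike_error, phase_error_report, predicted_heel_strikes
from .kinematics import TrialRecording
from .phase import decode
from .windows import WindowBatch, build_dataset, make_windows

__all__ = [
    "FEATURE_SETS",
    "SPEED_MODELS",
    "SubjectPartition",
    "AblationResult",
    "select_features",
    "split_subjects",
    "run_grid",
]

FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "SET1": ("thigh_angle_deg", "thigh_vel_dps", "torso_angle_deg", "torso_vel_dps"),
    "SET2": ("thigh_angle_deg", "thigh_vel_dps", "torso_vel_dps"),
    "SET3": ("thigh_angle_deg", "thigh_vel_dps", "torso_angle_deg"),
    "SET4": ("thigh_angle_deg", "thigh_vel_dps"),
}

SPEED_MODELS: dict[str, tuple[str, ...]] = {
    "general": ("C2", "C3", "C4", "C5"),
    "slow": ("C2",),
    "normal_fast": ("C3", "C4", "C5"),
}

#: conditions every cell is evaluated on
PREDICTION_CONDITIONS = ("C2", "C3", "C4", "C5")


@dataclass(frozen=True)
class SubjectPartition:
    """Pairwise-disjoint subject groups shared by every grid cell."""

    train: tuple[str, ...]
    validation: tuple[str, ...]
    prediction: tuple[str, ...]

    def __post_init__(self) -> None:
        groups = [set(self.train), set(self.validation), set(self.prediction)]
        total = sum(len(g) for g in groups)
        if len(set().union(*groups)) != total:
            raise ValueError("train/validation/prediction subjects overlap")


@dataclass
class AblationResult:
    """Grid outputs: per-cell training summary and per-condition errors."""

    cells: pd.DataFrame        # set, model, seed, train/val MSE, best epoch
    predictions: pd.DataFrame  # one row per cell x condition x trial
    partition: SubjectPartition
    config: dict = field(default_factory=dict)
    models: dict = field(default_factory=dict)   # (set, model) -> estimator

    def condition_means(self, value: str = "mse_polar") -> pd.DataFrame:
        """Mean error per (set, model, condition)."""
        return (self.predictions
                .groupby(["feature_set", "speed_model", "condition"],
                         observed=True)[value]
                .mean().reset_index())


def select_features(recording: TrialRecording, feature_set: str) -> np.ndarray:
    """Channel matrix for one trial in the set's declared column order."""
    if feature_set not in FEATURE_SETS:
        raise KeyError(f"unknown feature set {feature_set!r}")
    return recording.channel_matrix(FEATURE_SETS[feature_set])


def cell_seed(base_seed: int, feature_set: str, speed_model: str) -> int:
    """Stable per-cell seed: base plus a CRC of the cell's identity."""
    tag = f"{feature_set}|{speed_model}".encode()
    return int((base_seed + zlib.crc32(tag)) % (2**31 - 1))


def split_subjects(subject_ids, n_prediction: int, val_fraction: float,
                   seed: int) -> SubjectPartition:
    """Seeded subject-level partition into train / validation / prediction."""
    ids = sorted(set(subject_ids))
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    perm = [ids[i] for i in rng.permutation(len(ids))]
    if n_prediction >= len(ids) - 1:
        raise ValueError(
            f"need at least {n_prediction + 2} subjects for {n_prediction} "
            "prediction subjects plus disjoint train/validation groups")
    pred = perm[:n_prediction]
    rest = perm[n_prediction:]
    n_val = max(1, int(round(val_fraction * len(rest))))
    if n_val >= len(rest):
        raise ValueError("validation fraction leaves no training subjects")
    return SubjectPartition(train=tuple(sorted(rest[n_val:])),
                            validation=tuple(sorted(rest[:n_val])),
                            prediction=tuple(sorted(pred)))


def _evaluate_cell(model: PhaseLSTMRegressor, trials: list[TrialRecording],
                   channels, window_len: int, feature_set: str,
                   speed_model: str) -> list[dict]:
    rows = []
    for rec in trials:
        batch = make_windows(rec, channels, window_len, stride=1)
        if len(batch) == 0:
            continue
        preds = model.predict(batch.windows)
        tau_pred = decode(preds[:, 0], preds[:, 1])
        report = phase_error_report(batch.provenance["phi"].to_numpy(),
                                    batch.targets, preds, tau_pred)
        # heel-strike detection over the window-covered span
        t = batch.provenance["end_time_s"].to_numpy()
        pred_hs = predicted_heel_strikes(tau_pred, t)
        hs = rec.heel_strikes_s
        covered = hs[(hs >= t[0]) & (hs <= t[-1])]
        durations = np.diff(rec.heel_strikes_s)
        window = 0.5 * float(np.median(durations)) if durations.size else 0.5
        hs_report = heel_strike_error(covered, pred_hs, window)
        rows.append({
            "feature_set": feature_set, "speed_model": speed_model,
            "subject": rec.subject_id, "trial": rec.trial_id,
            "condition": rec.condition,
            "mse_polar": report.mse_polar,
            "circ_err_mean": report.circ_err_mean,
            "midstance_mse": report.midstance_mse,
            "hs_abs_err_s": hs_report.abs_mean_s,
            "hs_n_matched": len(hs_report.signed_errors_s),
            "hs_n_missed": hs_report.n_missed,
            "hs_n_false": hs_report.n_false,
        })
    return rows


def run_grid(cohort: list[TrialRecording],
             sets=("SET1", "SET2", "SET3", "SET4"),
             models=("general", "slow", "normal_fast"),
             n_prediction_subjects: int = 8,
             val_fraction: float = 0.2,
             window_len: int = 100,
             train_stride: int = 1,
             hidden_units=(128, 64, 64, 32),
             bidirectional=(True, False, False, False),
             learning_rate: float = 1e-3,
             batch_size: int = 64,
             max_epochs: int = 100,
             patience: int = 10,
             base_seed: int = 0,
             replicates: int = 1,
             keep_models: bool = False,
             verbose: int = 0) -> AblationResult:
    """Train and evaluate every (feature set x speed model) cell.

    ``train_stride`` thins training/validation windows (prediction windows
    always use stride 1).  Cells are independent given the shared subject
    partition and the per-cell seeds, so their order does not matter.
    ``replicates`` > 1 retrains each cell with perturbed seeds (same data,
    same partition) to quantify run-to-run variance; replicate 0 is the
    canonical run.
    """
    subjects = {r.subject_id for r in cohort}
    partition = split_subjects(subjects, n_prediction_subjects, val_fraction,
                               seed=base_seed)
    pred_trials = [r for r in cohort if r.subject_id in partition.prediction
                   and r.condition in PREDICTION_CONDITIONS]

    cell_rows, pred_rows, kept = [], [], {}
    for fs in sets:
        channels = FEATURE_SETS[fs]
        for sm in SPEED_MODELS.keys():
            if sm not in models:
                continue
            conds = SPEED_MODELS[sm]
            train_recs = [r for r in cohort if r.subject_id in partition.train
                          and r.condition in conds]
            val_recs = [r for r in cohort if r.subject_id in partition.validation
                        and r.condition in conds]
            if not train_recs or not val_recs:
                raise ValueError(
                    f"cell ({fs}, {sm}): no trials for training or validation; "
                    f"cohort needs conditions {conds} for partitioned subjects")
            train = build_dataset(train_recs, channels, window_len, train_stride)
            val = build_dataset(val_recs, channels, window_len, train_stride)
            for rep in range(replicates):
                seed = (cell_seed(base_seed, fs, sm) + rep * 7919) % (2**31 - 1)
                model = PhaseLSTMRegressor(
                    hidden_units=hidden_units, bidirectional=bidirectional,
                    learning_rate=learning_rate, batch_size=batch_size,
                    max_epochs=max_epochs, patience=patience,
                    random_state=seed, verbose=max(0, verbose - 1))
                model.fit(train.windows, train.targets,
                          validation_data=(val.windows, val.targets))
                if verbose:
                    print(f"[{fs} x {sm} r{rep}] best val MSE "
                          f"{model.best_val_mse_:.5f} (epoch {model.best_epoch_})")
                cell_rows.append({
                    "feature_set": fs, "speed_model": sm, "seed": seed,
                    "replicate": rep,
                    "n_train_windows": len(train), "n_val_windows": len(val),
                    "final_train_mse": model.final_train_mse_,
                    "best_val_mse": model.best_val_mse_,
                    "best_epoch": model.best_epoch_,
                    "n_epochs": len(model.history_),
                })
                rows = _evaluate_cell(model, pred_trials, channels,
                                      window_len, fs, sm)
                for r in rows:
                    r["replicate"] = rep
                pred_rows.extend(rows)
                if keep_models and rep == 0:
                    kept[(fs, sm)] = model

    return AblationResult(
        cells=pd.DataFrame(cell_rows),
        predictions=pd.DataFrame(pred_rows),
        partition=partition,
        config={"sets": tuple(sets), "models": tuple(models),
                "window_len": window_len, "train_stride": train_stride,
                "hidden_units": tuple(hidden_units),
                "bidirectional": tuple(bidirectional),
                "learning_rate": learning_rate, "batch_size": batch_size,
                "max_epochs": max_epochs, "patience": patience,
                "base_seed": base_seed,
                "n_prediction_subjects": n_prediction_subjects,
                "val_fraction": val_fraction},
        models=kept,
    )
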