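"""Pre-registered desk-scale experiments exercising the full pipeline.

Full-scale training of the 12-cell grid on a 50-subject cohort with the
(128, 64, 64, 32) network is a cluster-sized job; the studies here are the
package's own scaled-down replications, designed once and kept fixed:

* ``correlation_study`` — 50 subjects x C1-C5 x 2 trials with the default
  variability model; the Table-1-style correlation summary whose qualitative
  ordering (thigh above torso at every speed, torso rising from C1 to C3)
  the generator is built to exhibit.

* ``scaled_ablation_study`` — 20 subjects x C2-C5 x 3 trials with the
  informative-torso variability preset (torso angular velocity phase-locked,
  torso angle drift-dominated), feature sets 2-4 crossed with all three
  speed-dependent models, a reduced 32/16-unit network (first layer
  bidirectional), window 100 with training windows thinned 8x, batch 64,
  Adam 1e-3, at most 10 epochs with patience 4, 4 held-out prediction
  subjects.  These sizes give each condition enough windows that per-cell
  prediction errors are dominated by the torso-information effect rather
  than data starvation, while a full grid run stays in the minutes range
  on one CPU core.
"""

from __future__ import annotations

import pandas as pd

from .ablation import AblationResult, run_grid
from .simulate import VariabilityModel, generate_cohort
from .variability import cohort_correlation_summary

__all__ = ["ablation_cohort", "ablation_summary", "correlation_study",
           "run_variance_probe", "scaled_ablation_study"]


def correlation_study(seed: int = 0, n_subjects: int = 50,
                      trials_per_condition: int = 2) -> pd.DataFrame:
    """Correlation-summary table on a default-variability cohort (C1-C5)."""
    cohort = generate_cohort(n_subjects, ["C1", "C2", "C3", "C4", "C5"],
                             trials_per_condition, seed=seed)
    return cohort_correlation_summary(cohort)


def ablation_cohort(seed: int = 0):
    """The frozen cohort of the scaled ablation study."""
    return generate_cohort(
        20, ["C2", "C3", "C4", "C5"], 3,
        variability=VariabilityModel.informative_torso(), seed=seed)


def scaled_ablation_study(seed: int = 0, verbose: int = 0) -> AblationResult:
    """Feature sets 2-4 x all speed models on an informative-torso cohort."""
    cohort = ablation_cohort(seed)
    return run_grid(
        cohort,
        sets=("SET2", "SET3", "SET4"),
        models=("general", "slow", "normal_fast"),
        n_prediction_subjects=4, val_fraction=0.2,
        window_len=100, train_stride=8,
        hidden_units=(32, 16), bidirectional=(True, False),
        learning_rate=1e-3, batch_size=64, max_epochs=10, patience=4,
        base_seed=seed, verbose=verbose)


def run_variance_probe(seed: int = 0, replicates: int = 3,
                       cohort=None) -> dict:
    """Run-to-run variance of one cell's mean prediction MSE.

    Retrains the thigh-only general-model cell ``replicates`` times on the
    same cohort, partition and data, varying only the training seed, and
    returns the replicate means and their sample SD — the yardstick for
    judging whether a between-cell difference exceeds training noise.
    """
    cohort = cohort if cohort is not None else ablation_cohort(seed)
    res = run_grid(
        cohort, sets=("SET4",), models=("general",),
        n_prediction_subjects=4, val_fraction=0.2,
        window_len=100, train_stride=8,
        hidden_units=(32, 16), bidirectional=(True, False),
        learning_rate=1e-3, batch_size=64, max_epochs=10, patience=4,
        base_seed=seed, replicates=replicates)
    means = (res.predictions.groupby("replicate")["mse_polar"].mean())
    return {"replicate_means": [float(m) for m in means],
            "sigma": float(means.std(ddof=1))}


def ablation_summary(result: AblationResult) -> dict:
    """Headline numbers of the scaled study.

    Feature-set means are taken on the general model (the model trained on
    all prediction conditions); per-condition means for the slow and
    normal-fast models are averaged over feature sets.
    """
    preds = result.predictions
    general = preds[preds.speed_model == "general"]
    set_means = general.groupby("feature_set")["mse_polar"].mean()
    cond = (preds.groupby(["speed_model", "condition"], observed=True)
            ["mse_polar"].mean())
    return {
        "set_mse": set_means.to_dict(),
        "slow_by_condition": cond.loc["slow"].to_dict(),
        "normal_fast_by_condition": cond.loc["normal_fast"].to_dict(),
        "general_by_condition": cond.loc["general"].to_dict(),
    }
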