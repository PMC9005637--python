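"""Ablation grid: feature selection, partitions, cell plumbing."""

import numpy as np
import pytest

from gaitphase.ablation import (FEATURE_SETS, SPEED_MODELS, SubjectPartition,
                                cell_seed, run_grid, select_features,
                                split_subjects)
from gaitphase.simulate import VariabilityModel, generate_cohort
from gaitphase.windows import build_dataset


class TestFeatureSets:
    def test_set_definitions(self):
        assert FEATURE_SETS["SET1"] == ("thigh_angle_deg", "thigh_vel_dps",
                                        "torso_angle_deg", "torso_vel_dps")
        assert FEATURE_SETS["SET2"] == ("thigh_angle_deg", "thigh_vel_dps",
                                        "torso_vel_dps")
        assert FEATURE_SETS["SET3"] == ("thigh_angle_deg", "thigh_vel_dps",
                                        "torso_angle_deg")
        assert FEATURE_SETS["SET4"] == ("thigh_angle_deg", "thigh_vel_dps")
        for channels in FEATURE_SETS.values():
            assert "thigh_angle_deg" in channels and "thigh_vel_dps" in channels

    @pytest.mark.parametrize("fs,ncols", [("SET1", 4), ("SET2", 3),
                                          ("SET3", 3), ("SET4", 2)])
    def test_column_counts(self, fs, ncols, small_cohort):
        assert select_features(small_cohort[0], fs).shape[1] == ncols

    def test_set2_excludes_torso_angle(self, small_cohort):
        rec = small_cohort[0]
        mat = select_features(rec, "SET2")
        assert not any(np.array_equal(mat[:, j], rec.torso_angle_deg)
                       for j in range(mat.shape[1]))
        assert np.array_equal(mat[:, 2], rec.torso_vel_dps)

    def test_unknown_set_rejected(self, small_cohort):
        with pytest.raises(KeyError, match="SET9"):
            select_features(small_cohort[0], "SET9")


class TestSpeedModels:
    def test_definitions_exclude_c1(self):
        assert SPEED_MODELS["general"] == ("C2", "C3", "C4", "C5")
        assert SPEED_MODELS["slow"] == ("C2",)
        assert SPEED_MODELS["normal_fast"] == ("C3", "C4", "C5")
        for conds in SPEED_MODELS.values():
            assert "C1" not in conds


class TestPartition:
    def test_disjoint_groups(self):
        p = split_subjects([f"S{i}" for i in range(20)], 4, 0.2, seed=0)
        assert not (set(p.train) & set(p.validation))
        assert not (set(p.train) & set(p.prediction))
        assert not (set(p.validation) & set(p.prediction))
        assert len(p.train) + len(p.validation) + len(p.prediction) == 20

    def test_seeded_determinism(self):
        ids = [f"S{i}" for i in range(12)]
        assert split_subjects(ids, 3, 0.2, 7) == split_subjects(ids, 3, 0.2, 7)

    def test_insufficient_subjects(self):
        with pytest.raises(ValueError, match="at least"):
            split_subjects(["a", "b", "c"], 3, 0.2, 0)

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            SubjectPartition(("a", "b"), ("b",), ("c",))


class TestCellSeeds:
    def test_stable_and_distinct(self):
        s1 = cell_seed(5, "SET2", "general")
        assert s1 == cell_seed(5, "SET2", "general")
        assert s1 != cell_seed(5, "SET4", "general")
        assert s1 != cell_seed(5, "SET2", "slow")
        assert 0 <= s1 < 2**31


@pytest.fixture(scope="module")
def tiny_grid():
    """12-cell grid at minimal scale (tiny net, short windows)."""
    cohort = generate_cohort(7, ["C2", "C3", "C4", "C5"], 1,
                             variability=VariabilityModel(), seed=3,
                             n_strides=2)
    result = run_grid(cohort, sets=("SET1", "SET2", "SET3", "SET4"),
                      models=("general", "slow", "normal_fast"),
                      n_prediction_subjects=2, val_fraction=0.25,
                      window_len=40, train_stride=25,
                      hidden_units=(4,), bidirectional=(False,),
                      max_epochs=2, patience=1, base_seed=9)
    return cohort, result


class TestRunGrid:
    def test_twelve_cells(self, tiny_grid):
        _, result = tiny_grid
        assert len(result.cells) == 12
        assert set(zip(result.cells.feature_set, result.cells.speed_model)) == {
            (s, m) for s in FEATURE_SETS for m in SPEED_MODELS}

    def test_slow_model_trains_only_on_c2(self, tiny_grid):
        cohort, result = tiny_grid
        p = result.partition
        expected = build_dataset(
            [r for r in cohort
             if r.subject_id in p.train and r.condition == "C2"],
            FEATURE_SETS["SET1"], 40, 25)
        row = result.cells[(result.cells.feature_set == "SET1")
                           & (result.cells.speed_model == "slow")].iloc[0]
        assert row.n_train_windows == len(expected)
        general = result.cells[(result.cells.feature_set == "SET1")
                               & (result.cells.speed_model == "general")].iloc[0]
        assert general.n_train_windows > row.n_train_windows

    def test_prediction_covers_only_c2_to_c5_heldout_subjects(self, tiny_grid):
        _, result = tiny_grid
        preds = result.predictions
        assert set(preds.condition) <= {"C2", "C3", "C4", "C5"}
        assert set(preds.subject) <= set(result.partition.prediction)

    def test_partition_shared_across_cells(self, tiny_grid):
        _, result = tiny_grid
        # every cell evaluated the same prediction trials
        counts = result.predictions.groupby(
            ["feature_set", "speed_model"], observed=True).size()
        assert counts.nunique() == 1

    def test_cell_order_irrelevant(self, tiny_grid):
        """Reordering grid cells changes nothing: cells are independent
        given the shared partition and per-cell seeds."""
        cohort, result = tiny_grid
        reordered = run_grid(cohort, sets=("SET4", "SET1"),
                             models=("slow", "general"),
                             n_prediction_subjects=2, val_fraction=0.25,
                             window_len=40, train_stride=25,
                             hidden_units=(4,), bidirectional=(False,),
                             max_epochs=2, patience=1, base_seed=9)
        for _, row in reordered.cells.iterrows():
            ref = result.cells[
                (result.cells.feature_set == row.feature_set)
                & (result.cells.speed_model == row.speed_model)].iloc[0]
            assert row.best_val_mse == ref.best_val_mse
            assert row.seed == ref.seed

    def test_insufficient_subjects_rejected(self):
        cohort = generate_cohort(3, ["C2", "C3", "C4", "C5"], 1, seed=0,
                                 n_strides=2)
        with pytest.raises(ValueError, match="at least"):
            run_grid(cohort, sets=("SET4",), models=("general",),
                     n_prediction_subjects=3, window_len=40,
                     hidden_units=(4,), bidirectional=(False,),
                     max_epochs=2, patience=1)
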