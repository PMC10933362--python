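"""Feature-matrix assembly, imputation and stratified partitioning."""

import numpy as np
import pandas as pd
import pytest

from onioncnd.feature_table import (
    CLIMATE_COLUMNS,
    FEATURE_GROUPS,
    FeatureMatrix,
    SOIL_COLUMNS,
    TISSUE_COLUMNS,
    TrialObservation,
    assemble,
    frame_to_observations,
    impute,
    observations_to_frame,
    stratified_split,
)


def toy_matrix(n=100, strata=("a",), seed=0, missing=0.0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        {
            "x1": rng.normal(size=n),
            "x2": rng.normal(size=n),
            "x3": rng.normal(size=n),
        }
    )
    if missing:
        mask = rng.random(X.shape) < missing
        X = X.mask(mask)
    labels = pd.Series([strata[i % len(strata)] for i in range(n)])
    return FeatureMatrix(
        X=X,
        target=pd.Series(rng.normal(size=n)),
        strata=labels,
        missing_mask=X.isna(),
        codebook={},
        groups=("soil",),
    )


class TestTrialObservation:
    def test_split_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="split fractions"):
            TrialObservation(
                trial_id="t", year=2015, municipality="Ituporanga", cultivar="Caete",
                establishment="transplant", tillage="no-till", previous_crop="maize",
                n_dose=100, p_dose=0, k_dose=0, split_schedule=(0.5, 0.4),
            )

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError, match="n_dose"):
            TrialObservation(
                trial_id="t", year=2015, municipality="x", cultivar="c",
                establishment="e", tillage="t", previous_crop="p",
                n_dose=-1, p_dose=0, k_dose=0, split_schedule=(),
            )

    def test_frame_round_trip(self, default_trials):
        frame = observations_to_frame(default_trials.observations[:25])
        back = frame_to_observations(frame)
        again = observations_to_frame(back)
        pd.testing.assert_frame_equal(frame, again)


class TestAssemble:
    def test_all_groups_width(self, default_trials):
        matrix = assemble(default_trials.observations)
        expected = sum(len(cols) for cols in FEATURE_GROUPS.values())
        assert len(matrix.columns) == expected

    def test_fertilization_only_projection(self, default_trials):
        matrix = assemble(default_trials.observations, groups=("fertilization",))
        assert matrix.columns == ["n_dose", "p_dose", "k_dose", "n_split_count"]

    def test_excluding_pk_doses(self, default_trials):
        matrix = assemble(default_trials.observations, exclude=("p_dose", "k_dose"))
        assert "p_dose" not in matrix.columns and "k_dose" not in matrix.columns
        assert "n_dose" in matrix.columns

    def test_unknown_group_rejected(self, default_trials):
        with pytest.raises(ValueError, match="unknown feature groups"):
            assemble(default_trials.observations, groups=("climate", "phenology"))

    def test_codebook_round_trips_categories(self, default_trials):
        matrix = assemble(default_trials.observations, groups=("management",))
        decoded = matrix.decode("cultivar")
        original = [obs.cultivar for obs in default_trials.observations]
        assert decoded.tolist() == original

    def test_all_missing_column_dropped_with_warning(self, default_trials):
        frame = observations_to_frame(default_trials.observations[:40])
        frame["soil_zn"] = np.nan
        with pytest.warns(UserWarning, match="soil_zn"):
            matrix = assemble(frame_to_observations(frame))
        assert "soil_zn" not in matrix.columns


class TestImpute:
    def test_complete_matrix_returned_unchanged(self):
        matrix = toy_matrix(50)
        out = impute(matrix, seed=1)
        pd.testing.assert_frame_equal(out.X, matrix.X)

    def test_observed_cells_untouched_and_deterministic(self):
        matrix = toy_matrix(120, missing=0.13, seed=3)
        out1 = impute(matrix, seed=9)
        out2 = impute(matrix, seed=9)
        pd.testing.assert_frame_equal(out1.X, out2.X)
        observed = ~matrix.X.isna().to_numpy()
        assert np.array_equal(out1.X.to_numpy()[observed], matrix.X.to_numpy()[observed])
        assert not out1.has_missing()

    def test_mcar_mask_recovery_on_linear_structure(self):
        # low-noise linear structure; 13% of cells masked completely at
        # random must be recovered with correlation > 0.8
        rng = np.random.default_rng(12)
        n = 300
        z = rng.normal(size=n)
        X = pd.DataFrame(
            {f"v{i}": coef * z + 0.15 * rng.normal(size=n)
             for i, coef in enumerate([1.0, -1.0, 0.8, 1.2, -0.6, 0.9])}
        )
        mask = rng.random(X.shape) < 0.13
        masked = X.mask(mask)
        matrix = FeatureMatrix(
            X=masked, target=pd.Series(z), strata=pd.Series(["a"] * n),
            missing_mask=masked.isna(), codebook={}, groups=("soil",),
        )
        filled = impute(matrix, seed=4)
        truth = X.to_numpy()[mask]
        recovered = filled.X.to_numpy()[mask]
        assert np.corrcoef(truth, recovered)[0, 1] > 0.8

    def test_entirely_missing_column_rejected(self):
        matrix = toy_matrix(30)
        matrix.X["x1"] = np.nan
        with pytest.raises(ValueError, match="x1"):
            impute(matrix, seed=0)

    def test_categorical_codes_restored_to_valid_range(self):
        rng = np.random.default_rng(5)
        n = 80
        X = pd.DataFrame({
            "cat": rng.integers(0, 3, n).astype(float),
            "num": rng.normal(size=n),
        })
        X.loc[rng.choice(n, 10, replace=False), "cat"] = np.nan
        matrix = FeatureMatrix(
            X=X, target=pd.Series(rng.normal(size=n)), strata=pd.Series(["a"] * n),
            missing_mask=X.isna(), codebook={"cat": ["u", "v", "w"]}, groups=("soil",),
        )
        out = impute(matrix, seed=6)
        assert set(out.X["cat"].unique()) <= {0.0, 1.0, 2.0}


class TestStratifiedSplit:
    def test_single_stratum_70_30(self):
        train, test = stratified_split(toy_matrix(100), 0.7, seed=1)
        assert len(train) == 70 and len(test) == 30
        assert len(np.intersect1d(train, test)) == 0
        assert len(np.union1d(train, test)) == 100

    def test_two_equal_strata_counts(self):
        matrix = toy_matrix(100, strata=("a", "b"))
        train, test = stratified_split(matrix, 0.7, seed=2)
        labels = matrix.strata.to_numpy()
        assert (labels[train] == "a").sum() == 35
        assert (labels[train] == "b").sum() == 35

    def test_singleton_stratum_goes_to_train_with_warning(self):
        matrix = toy_matrix(21, strata=tuple("ab" * 10 + "c"))
        with pytest.warns(UserWarning, match="singleton"):
            train, test = stratified_split(matrix, 0.7, seed=3)
        singleton_row = np.flatnonzero(matrix.strata.to_numpy() == "c")
        assert singleton_row[0] in train

    def test_train_frequency_close_to_fraction(self):
        matrix = toy_matrix(60, strata=("a", "b", "c"))
        hits = np.zeros(60)
        n_splits = 1000
        for seed in range(n_splits):
            train, _ = stratified_split(matrix, 0.7, seed=seed)
            hits[train] += 1
        freq = hits / n_splits
        assert np.all(np.abs(freq - 0.7) < 0.05)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            stratified_split(toy_matrix(10), 1.2, seed=0)


def test_select_restricts_columns_and_codebook(default_trials):
    matrix = assemble(default_trials.observations, groups=("management", "tissue"))
    sub = matrix.select(["cultivar", *TISSUE_COLUMNS])
    assert sub.columns == ["cultivar", *TISSUE_COLUMNS]
    assert set(sub.codebook) == {"cultivar"}
    with pytest.raises(KeyError):
        matrix.select(["nope"])
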