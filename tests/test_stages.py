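import dataclasses

import numpy as np
import pandas as pd
import pytest

from pmgrid import preprocess, spatial_features, stages, validation
from pmgrid.stages import (
    LearnerSpec,
    SP_COLUMNS,
    SPT_COLUMNS,
    STAGE2_PREDICTORS,
    STAGE3_COLUMNS,
    augment_pm25,
    build_stage3_table,
    fit_stage1,
    fit_stage2,
    fit_stage3,
    impute_aod,
    predict_stage3,
)
from pmgrid.synthetic import WorldConfig, generate_world, true_aod_fields

from conftest import SMALL_CONFIG


@pytest.fixture(scope="module")
def clean_world():
    """Small world with an exact PM2.5 = 0.6 * PM10 relationship."""
    return generate_world(
        dataclasses.replace(SMALL_CONFIG, sigma_pm10_ratio=0.0, sigma_obs=0.0)
    )


@pytest.fixture(scope="module")
def filtered(small_world):
    sites, records = preprocess.dedupe_colocated(
        small_world.sites, small_world.records
    )
    return sites, preprocess.apply_completeness_filters(records)


@pytest.fixture(scope="module")
def stage3_inputs(small_world, filtered):
    sites, records = filtered
    model = fit_stage1(records, sites, 2016, LearnerSpec(30, 4, seed=0))
    augmented = augment_pm25(records, sites, 2016, model)
    lagged = {2016: spatial_features.monitor_feature_table(records, sites, 2016)}
    aod = true_aod_fields(small_world)
    table = build_stage3_table(small_world, augmented, sites, aod, lagged)
    return table, augmented


class TestStage1:
    def test_recovers_exact_linear_ratio(self, clean_world):
        sites, records = preprocess.dedupe_colocated(
            clean_world.sites, clean_world.records
        )
        records = preprocess.apply_completeness_filters(records)
        model = fit_stage1(records, sites, 2016, LearnerSpec(100, 4, seed=1))
        df = stages._stage1_frame(records, sites)
        df = df[df["pm25"].notna() & df["pm10"].notna()]
        stats = validation.performance_stats(model.oob_pred, df["pm25"], method="OOB")
        assert stats.r2 > 0.99

    def test_records_hyperparameters_and_schema(self, filtered):
        sites, records = filtered
        model = fit_stage1(records, sites, 2016, LearnerSpec(500, 4, seed=0))
        assert model.spec.ntree == 500
        assert model.spec.mtry == 4
        assert model.learner.n_estimators == 500
        assert model.learner.max_features == 4
        assert model.schema == stages.STAGE1_PREDICTORS
        assert model.target_transform == "identity"

    def test_year_without_colocated_data_rejected(self, filtered):
        sites, records = filtered
        with pytest.raises(ValueError, match="1999"):
            fit_stage1(records, sites, 1999)


class TestAugment:
    def test_observed_rows_pass_through_and_counts_add_up(self, filtered):
        sites, records = filtered
        model = fit_stage1(records, sites, 2016, LearnerSpec(20, 4, seed=0))
        aug = augment_pm25(records, sites, 2016, model)

        n_obs = records["pm25"].notna().sum()
        n_pm10_only = (records["pm25"].isna() & records["pm10"].notna()).sum()
        assert len(aug) == n_obs + n_pm10_only
        assert (aug["provenance"] == "observed").sum() == n_obs

        obs = aug[aug["provenance"] == "observed"].set_index(["monitor_id", "date"])
        orig = records[records["pm25"].notna()].copy()
        orig["date"] = pd.to_datetime(orig["date"])
        orig = orig.set_index(["monitor_id", "date"])
        joined = obs.join(orig[["pm25"]], rsuffix="_orig")
        assert np.allclose(joined["pm25"], joined["pm25_orig"])

    def test_wrong_year_model_rejected(self, filtered):
        sites, records = filtered
        model = fit_stage1(records, sites, 2016, LearnerSpec(20, 4, seed=0))
        with pytest.raises(ValueError, match="year"):
            augment_pm25(records, sites, 2015, model)


class TestStage2:
    def test_schema_is_35_cams_plus_three(self):
        assert len(STAGE2_PREDICTORS) == 38
        assert sum(c.startswith("cams_") for c in STAGE2_PREDICTORS) == 35
        assert STAGE2_PREDICTORS[-3:] == ("yday", "northing", "easting")

    def test_identity_world_oob_near_perfect(self):
        world = generate_world(
            dataclasses.replace(SMALL_CONFIG, identity_aod=True)
        )
        fields = preprocess.composite_all_days(world)
        model = fit_stage2(fields[0.47], world, 2016, LearnerSpec(50, 20, seed=2))
        obs = fields[0.47].values[np.isfinite(fields[0.47].values)]
        stats = validation.performance_stats(model.oob_pred, obs, method="OOB")
        assert stats.r2 > 0.99
        assert model.spec.ntree == 50
        assert model.spec.mtry == 20

    def test_imputation_contract(self, small_world):
        fields = preprocess.composite_all_days(small_world)
        field = fields[0.55]
        model = fit_stage2(field, small_world, 2016, LearnerSpec(20, 20, seed=3))
        filled = impute_aod(model, field, small_world)

        assert filled.missing_fraction == 0.0
        observed = np.isfinite(field.values)
        # Observed composites survive bitwise; gaps become provenance=imputed.
        assert np.array_equal(filled.values[observed], field.values[observed])
        assert (filled.provenance[observed] == preprocess.PROVENANCE_OBSERVED).all()
        assert (filled.provenance[~observed] == preprocess.PROVENANCE_IMPUTED).all()

        # A gap-free field passes through untouched.
        again = impute_aod(model, filled, small_world)
        assert np.array_equal(again.values, filled.values)

    def test_wavelength_mismatch_rejected(self, small_world):
        fields = preprocess.composite_all_days(small_world)
        model = fit_stage2(fields[0.55], small_world, 2016, LearnerSpec(5, 20, seed=3))
        with pytest.raises(ValueError, match="wavelength"):
            impute_aod(model, fields[0.47], small_world)


class TestStage3Table:
    def test_schema_counts(self, stage3_inputs):
        table, _ = stage3_inputs
        predictors = [c for c in table.columns
                      if c not in ("monitor_id", "date", "pm25", "provenance")]
        assert len(SPT_COLUMNS) == 15
        assert len(SP_COLUMNS) == 27
        assert set(predictors) == set(STAGE3_COLUMNS)
        assert len(predictors) == 42

    def test_row_count_matches_augmented_series(self, stage3_inputs):
        table, augmented = stage3_inputs
        assert len(table) == len(augmented)

    def test_no_missing_values(self, stage3_inputs):
        table, _ = stage3_inputs
        assert table[list(STAGE3_COLUMNS)].notna().all().all()

    def test_ndvi_constant_within_calendar_month_per_cell(self, stage3_inputs, filtered):
        table, _ = stage3_inputs
        sites, _ = filtered
        t = table.merge(sites[["monitor_id", "cell_id"]], on="monitor_id")
        t["month_key"] = pd.to_datetime(t["date"]).dt.to_period("M")
        nunique = t.groupby(["cell_id", "month_key"])["ndvi"].nunique()
        assert (nunique == 1).all()

    def test_model_surface_entered_as_log(self, stage3_inputs, small_world, filtered):
        table, _ = stage3_inputs
        sites, _ = filtered
        row = table.iloc[0]
        t = small_world.day_index(row["date"])
        r, c = small_world.grid.cell_to_rowcol(
            sites.set_index("monitor_id").loc[row["monitor_id"], "cell_id"]
        )
        assert row["log_ctm_pm25"] == pytest.approx(
            np.log(small_world.ctm_pm25[t, r, c])
        )


class TestStage3Model:
    def test_metadata_and_log_transform(self, stage3_inputs):
        table, _ = stage3_inputs
        model = fit_stage3(table, 2016, LearnerSpec(10, 20, seed=4))
        assert model.target_transform == "log"
        assert model.schema == STAGE3_COLUMNS
        assert model.spec.mtry == 20

    def test_nonpositive_target_rejected(self, stage3_inputs):
        table, _ = stage3_inputs
        bad = table.copy()
        bad.loc[bad.index[0], "pm25"] = 0.0
        with pytest.raises(ValueError, match="positive"):
            fit_stage3(bad, 2016, LearnerSpec(5, 20, seed=4))

    def test_predictions_positive_and_permutation_equivariant(self, stage3_inputs):
        table, _ = stage3_inputs
        model = fit_stage3(table, 2016, LearnerSpec(10, 20, seed=4))
        sub = table.head(200)
        pred = predict_stage3(model, sub)
        assert (pred > 0).all()
        perm = np.random.default_rng(0).permutation(len(sub))
        assert np.allclose(predict_stage3(model, sub.iloc[perm]), pred[perm])

    def test_prediction_invariant_to_column_order(self, stage3_inputs):
        table, _ = stage3_inputs
        model = fit_stage3(table, 2016, LearnerSpec(10, 20, seed=4))
        sub = table.head(50)
        shuffled = sub[list(reversed(sub.columns))]
        assert np.allclose(
            predict_stage3(model, shuffled), predict_stage3(model, sub)
        )

    def test_constant_target_predicts_its_value(self, stage3_inputs):
        table, _ = stage3_inputs
        const = table.copy()
        const["pm25"] = 7.0
        model = fit_stage3(const, 2016, LearnerSpec(10, 20, seed=4))
        pred = predict_stage3(model, const.head(20))
        assert np.allclose(pred, 7.0)

    def test_per_year_isolation(self, stage3_inputs):
        # Fitting a given year ignores rows of any other year entirely.
        table, _ = stage3_inputs
        polluted = table.copy()
        alien = table.head(300).copy()
        alien["date"] = pd.to_datetime(alien["date"]) - pd.DateOffset(years=3)
        alien["pm25"] = 999.0
        polluted = pd.concat([alien, polluted], ignore_index=True)

        m_clean = fit_stage3(table, 2016, LearnerSpec(10, 20, seed=4))
        m_poll = fit_stage3(polluted, 2016, LearnerSpec(10, 20, seed=4))
        sub = table.head(100)
        assert np.allclose(
            predict_stage3(m_clean, sub), predict_stage3(m_poll, sub)
        )

    def test_schema_mismatch_rejected(self, stage3_inputs):
        table, _ = stage3_inputs
        model = fit_stage3(table, 2016, LearnerSpec(5, 20, seed=4))
        with pytest.raises(ValueError, match="schema"):
            predict_stage3(model, table.drop(columns=["ndvi"]))


def test_model_bundle_roundtrip(stage3_inputs, tmp_path):
    table, _ = stage3_inputs
    model = fit_stage3(table, 2016, LearnerSpec(10, 20, seed=4))
    model.save(tmp_path / "bundle")
    back = stages.FittedStageModel.load(tmp_path / "bundle")
    assert back.schema == model.schema
    assert back.target_transform == "log"
    sub = table.head(40)
    np.testing.assert_allclose(
        predict_stage3(back, sub), predict_stage3(model, sub)
    )
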