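"""Stage-1/2/3 random-forest models of the multi-stage PM2.5 framework.

* **Stage-1** extends the PM2.5 monitor series: a per-year forest learns
  PM2.5 from co-located PM10 plus monitor type, month, day-of-week and
  coordinates, then predicts PM2.5 on monitor-days where only PM10 was
  measured.
* **Stage-2** fills the cloud gaps of the daily satellite-AOD composite:
  a per-year, per-wavelength forest learns observed AOD from the 35
  modelled-AOD reanalysis columns (5 wavelengths x 7 sub-day hours)
  plus day-of-year and coordinates, then imputes every missing cell.
* **Stage-3** is the main model: a per-year forest for log PM2.5 from
  15 spatio-temporal and 27 spatial predictors at the monitor-days of
  the (Stage-1-augmented) PM2.5 series.

All stages use bootstrap-bagged randomized trees with out-of-bag (OOB)
predictions; tree counts and the per-split predictor draw (mtry) follow
the reference configuration for each stage (500/4, 50/20, 500/20).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .spatial_features import LAGGED_FEATURES
from .synthetic import (
    AOD_WAVELENGTHS,
    CAMS_HOURS,
    MONITOR_TYPES,
    STATIC_COLUMNS,
    SyntheticWorld,
)
from .preprocess import (
    DailyAODField,
    PROVENANCE_IMPUTED,
)

__all__ = [
    "LearnerSpec",
    "FittedStageModel",
    "STAGE1_PREDICTORS",
    "STAGE2_PREDICTORS",
    "SPT_COLUMNS",
    "SP_COLUMNS",
    "STAGE3_COLUMNS",
    "CAMSLinker",
    "fit_stage1",
    "augment_pm25",
    "fit_stage2",
    "impute_aod",
    "build_stage3_table",
    "build_grid_stage3_table",
    "fit_stage3",
    "predict_stage3",
]

STAGE1_PREDICTORS = ("pm10", "monitor_type_code", "month", "dow", "northing", "easting")

CAMS_COLUMNS = tuple(
    f"cams_w{int(round(wl * 1000)):04d}_h{h:02d}" for wl in AOD_WAVELENGTHS for h in CAMS_HOURS
)
STAGE2_PREDICTORS = CAMS_COLUMNS + ("yday", "northing", "easting")

#: The 15 spatio-temporal Stage-3 predictors.
SPT_COLUMNS = (
    "log_ctm_pm25",
    "aod_047",
    "aod_055",
    "air_temp",
    "slp",
    "rh",
    "precip",
    "wind_speed",
    "wind_dir",
    "blh_00",
    "blh_12",
    "ndvi",
    "yday",
    "month",
    "dow",
)
#: The 27 spatial Stage-3 predictors (lagged PM2.5 entered as log).
SP_COLUMNS = LAGGED_FEATURES + STATIC_COLUMNS
STAGE3_COLUMNS = SPT_COLUMNS + SP_COLUMNS


@dataclass(frozen=True)
class LearnerSpec:
    """Forest hyperparameters: tree count, per-split predictor draw, seed."""

    ntree: int
    mtry: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ntree < 1:
            raise ValueError(f"ntree must be >= 1, got {self.ntree}")
        if self.mtry < 1:
            raise ValueError(f"mtry must be >= 1, got {self.mtry}")


@dataclass
class FittedStageModel:
    """A fitted per-year forest with its frozen predictor schema.

    ``oob_pred`` is aligned to the training rows (``train_index``) and
    is on the transformed target scale (log for Stage-3).
    """

    stage: int
    year: int
    spec: LearnerSpec
    learner: RandomForestRegressor
    schema: tuple
    target_transform: str  # "identity" | "log"
    oob_pred: np.ndarray
    train_index: pd.Index
    wavelength: float | None = None

    def _matrix(self, table: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.schema if c not in table.columns]
        if missing:
            raise ValueError(f"table lacks schema columns {missing}")
        return table.loc[:, list(self.schema)].to_numpy(float)

    def predict_raw(self, table: pd.DataFrame) -> np.ndarray:
        """Forest output on the transformed target scale."""
        return self.learner.predict(self._matrix(table))

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        """Prediction on the native concentration scale."""
        raw = self.predict_raw(table)
        return np.exp(raw) if self.target_transform == "log" else raw

    @property
    def oob_pred_native(self) -> np.ndarray:
        return np.exp(self.oob_pred) if self.target_transform == "log" else self.oob_pred

    def save(self, directory) -> None:
        """Serialize as a directory bundle: JSON manifest + pickled learner."""
        import json
        import pickle
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "stage": self.stage,
            "year": self.year,
            "wavelength": self.wavelength,
            "schema": list(self.schema),
            "target_transform": self.target_transform,
            "spec": {"ntree": self.spec.ntree, "mtry": self.spec.mtry,
                     "seed": self.spec.seed},
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
        with open(directory / "learner.pkl", "wb") as fh:
            pickle.dump(
                {"learner": self.learner, "oob_pred": self.oob_pred,
                 "train_index": self.train_index},
                fh,
            )

    @classmethod
    def load(cls, directory) -> "FittedStageModel":
        import json
        import pickle
        from pathlib import Path

        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        with open(directory / "learner.pkl", "rb") as fh:
            blob = pickle.load(fh)
        return cls(
            stage=manifest["stage"],
            year=manifest["year"],
            spec=LearnerSpec(**manifest["spec"]),
            learner=blob["learner"],
            schema=tuple(manifest["schema"]),
            target_transform=manifest["target_transform"],
            oob_pred=blob["oob_pred"],
            train_index=blob["train_index"],
            wavelength=manifest["wavelength"],
        )


def _fit_forest(X: np.ndarray, y: np.ndarray, spec: LearnerSpec) -> RandomForestRegressor:
    rf = RandomForestRegressor(
        n_estimators=spec.ntree,
        max_features=min(spec.mtry, X.shape[1]),
        bootstrap=True,
        oob_score=True,
        random_state=spec.seed,
        n_jobs=1,
    )
    import warnings

    with warnings.catch_warnings():
        # Rows never left out of bag (possible at very small ntree) are benign.
        warnings.filterwarnings("ignore", message="Some inputs do not have OOB scores")
        warnings.filterwarnings("ignore", category=RuntimeWarning)
        rf.fit(X, y)
    return rf


# ---------------------------------------------------------------------------
# Stage-1
# ---------------------------------------------------------------------------

def _stage1_frame(records: pd.DataFrame, sites: pd.DataFrame) -> pd.DataFrame:
    # Records may already carry site columns (e.g. a previously assembled
    # frame fed back through cross-validation); refresh them from sites.
    base = records.drop(
        columns=[c for c in ("easting", "northing", "monitor_type",
                             "monitor_type_code", "month", "dow") if c in records],
    )
    df = base.merge(
        sites[["monitor_id", "easting", "northing", "monitor_type"]],
        on="monitor_id",
        how="left",
    )
    df["date"] = pd.to_datetime(df["date"])
    df["monitor_type_code"] = (
        df["monitor_type"].map({t: i for i, t in enumerate(MONITOR_TYPES)}).astype(float)
    )
    df["month"] = df["date"].dt.month.astype(float)
    df["dow"] = df["date"].dt.dayofweek.astype(float)
    return df


def fit_stage1(
    records: pd.DataFrame,
    sites: pd.DataFrame,
    year: int,
    spec: LearnerSpec = LearnerSpec(500, 4),
) -> FittedStageModel:
    """Fit the per-year PM10 -> PM2.5 augmentation forest.

    Trains on monitor-days of ``year`` where both pollutants are
    present. Raises if there are none.
    """
    df = _stage1_frame(records, sites)
    df = df[(df["date"].dt.year == year) & df["pm25"].notna() & df["pm10"].notna()]
    if df.empty:
        raise ValueError(f"no co-located PM2.5/PM10 data in {year}")
    X = df.loc[:, list(STAGE1_PREDICTORS)].to_numpy(float)
    y = df["pm25"].to_numpy(float)
    rf = _fit_forest(X, y, spec)
    return FittedStageModel(
        stage=1,
        year=year,
        spec=spec,
        learner=rf,
        schema=STAGE1_PREDICTORS,
        target_transform="identity",
        oob_pred=rf.oob_prediction_,
        train_index=df.index,
    )


def augment_pm25(
    records: pd.DataFrame,
    sites: pd.DataFrame,
    year: int,
    model: FittedStageModel,
) -> pd.DataFrame:
    """Combine observed PM2.5 with Stage-1 predictions on PM10-only days.

    Returns one row per monitor-day of ``year`` that has at least one
    pollutant: columns monitor_id, date, pm25, provenance
    ("observed" or "stage1").
    """
    if model.year != year:
        raise ValueError(f"model year {model.year} does not match {year}")
    df = _stage1_frame(records, sites)
    df = df[df["date"].dt.year == year]
    observed = df[df["pm25"].notna()]
    pm10_only = df[df["pm25"].isna() & df["pm10"].notna()]
    out = [
        pd.DataFrame({
            "monitor_id": observed["monitor_id"],
            "date": observed["date"],
            "pm25": observed["pm25"],
            "provenance": "observed",
        })
    ]
    if not pm10_only.empty:
        pred = model.predict(pm10_only)
        out.append(pd.DataFrame({
            "monitor_id": pm10_only["monitor_id"],
            "date": pm10_only["date"],
            "pm25": pred,
            "provenance": "stage1",
        }))
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# Stage-2
# ---------------------------------------------------------------------------

class CAMSLinker:
    """Nearest-centroid linkage of the coarse modelled-AOD to the 1 km grid.

    Precomputes, per 1 km cell, the coarse pixel whose centroid is
    nearest (ties to the lowest pixel index) and serves the 35
    wavelength-hour reanalysis columns for arbitrary (day, cell) pairs.
    """

    def __init__(self, world: SyntheticWorld):
        self.world = world
        ccx, ccy = world.coarse_grid.centroids()
        cx, cy = world.grid.centroids()
        d2 = (cx[:, None] - ccx[None]) ** 2 + (cy[:, None] - ccy[None]) ** 2
        self.coarse_of_cell = np.argmin(d2, axis=1)
        T = world.n_days
        self._flat = world.cams.reshape(T, len(CAMS_COLUMNS), -1)

    def features(self, t_idx: np.ndarray, cell_ids: np.ndarray) -> pd.DataFrame:
        t_idx = np.asarray(t_idx)
        cell_ids = np.asarray(cell_ids)
        ci = self.coarse_of_cell[cell_ids]
        X = self._flat[t_idx[:, None], np.arange(len(CAMS_COLUMNS))[None, :], ci[:, None]]
        df = pd.DataFrame(X, columns=list(CAMS_COLUMNS))
        ex, no = self.world.grid.centroid(cell_ids)
        df["yday"] = self.world.dates.dayofyear.to_numpy()[t_idx].astype(float)
        df["northing"] = no
        df["easting"] = ex
        return df


def fit_stage2(
    aod_field: DailyAODField,
    world: SyntheticWorld,
    year: int,
    spec: LearnerSpec = LearnerSpec(50, 20),
    linker: CAMSLinker | None = None,
) -> FittedStageModel:
    """Fit the per-year, per-wavelength AOD gap-filling forest.

    Trains on every (cell, day) of ``year`` with an observed daily
    composite; raises when the year has no observed AOD at all.
    """
    linker = linker or CAMSLinker(world)
    in_year = world.dates.year.to_numpy() == year
    obs = np.isfinite(aod_field.values) & in_year[:, None, None]
    if not obs.any():
        raise ValueError(f"no observed AOD in {year} at {aod_field.wavelength} um")
    t_idx, rows, cols = np.nonzero(obs)
    cell_ids = world.grid.rowcol_to_cell(rows, cols)
    X_df = linker.features(t_idx, cell_ids)
    y = aod_field.values[t_idx, rows, cols]
    rf = _fit_forest(X_df.to_numpy(float), y, spec)
    return FittedStageModel(
        stage=2,
        year=year,
        spec=spec,
        learner=rf,
        schema=STAGE2_PREDICTORS,
        target_transform="identity",
        oob_pred=rf.oob_prediction_,
        train_index=X_df.index,
        wavelength=aod_field.wavelength,
    )


def impute_aod(
    models: "FittedStageModel | dict",
    aod_field: DailyAODField,
    world: SyntheticWorld,
    linker: CAMSLinker | None = None,
) -> DailyAODField:
    """Fill every missing cell of the daily composite with forest predictions.

    Observed values are carried over bitwise; imputed cells get
    provenance ``imputed``. ``models`` is one fitted Stage-2 model or a
    ``{year: model}`` mapping covering all years in the field.
    """
    by_year = models if isinstance(models, dict) else {models.year: models}
    for m in by_year.values():
        if m.wavelength != aod_field.wavelength:
            raise ValueError(
                f"model wavelength {m.wavelength} != field {aod_field.wavelength}"
            )
    linker = linker or CAMSLinker(world)
    values = aod_field.values.copy()
    provenance = aod_field.provenance.copy()
    years = world.dates.year.to_numpy()
    missing = ~np.isfinite(values)
    for year in np.unique(years[missing.any(axis=(1, 2))]):
        if int(year) not in by_year:
            raise ValueError(f"no Stage-2 model for year {year}")
        sel = missing & (years == year)[:, None, None]
        t_idx, rows, cols = np.nonzero(sel)
        if t_idx.size == 0:
            continue
        cell_ids = world.grid.rowcol_to_cell(rows, cols)
        X_df = linker.features(t_idx, cell_ids)
        values[t_idx, rows, cols] = by_year[int(year)].predict(X_df)
        provenance[t_idx, rows, cols] = PROVENANCE_IMPUTED
    return DailyAODField(
        wavelength=aod_field.wavelength,
        dates=aod_field.dates,
        values=values,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# Stage-3
# ---------------------------------------------------------------------------

def _extract_field(arr: np.ndarray, t_idx, rows, cols) -> np.ndarray:
    return arr[t_idx, rows, cols]


def _assemble_stage3(
    world: SyntheticWorld,
    t_idx: np.ndarray,
    cell_ids: np.ndarray,
    aod_fields: dict,
    lagged: pd.DataFrame,
    lagged_key: str,
    lagged_key_values: np.ndarray,
) -> pd.DataFrame:
    """Shared Stage-3 predictor assembly for monitor- and cell-keyed rows."""
    rows, cols = world.grid.cell_to_rowcol(cell_ids)
    dates = world.dates[t_idx]

    data = {}
    data["log_ctm_pm25"] = np.log(_extract_field(world.ctm_pm25, t_idx, rows, cols))
    for wl, name in ((0.47, "aod_047"), (0.55, "aod_055")):
        f = aod_fields[wl]
        vals = _extract_field(f.values, t_idx, rows, cols)
        data[name] = vals
    for met_name in ("air_temp", "slp", "rh", "precip", "wind_speed", "wind_dir",
                     "blh_00", "blh_12"):
        data[met_name] = _extract_field(world.met[met_name], t_idx, rows, cols)
    m_idx = world.months.get_indexer(dates.to_period("M"))
    data["ndvi"] = world.ndvi[m_idx, rows, cols]
    data["yday"] = dates.dayofyear.to_numpy().astype(float)
    data["month"] = dates.month.to_numpy().astype(float)
    data["dow"] = dates.dayofweek.to_numpy().astype(float)

    lag = lagged.set_index(lagged_key)
    lag_rows = lag.loc[lagged_key_values]
    for name in LAGGED_FEATURES:
        v = lag_rows[name].to_numpy(float)
        # Annual-average concentrations enter the model on the log scale;
        # the two nearest-distance features stay in km.
        data[name] = np.log(v) if name.startswith("lag_") else v

    statics = world.statics.set_index("cell_id")
    st_rows = statics.loc[cell_ids]
    for name in STATIC_COLUMNS:
        data[name] = st_rows[name].to_numpy(float)

    table = pd.DataFrame(data)
    bad = table.columns[table.isna().any()].tolist()
    if bad:
        first = table.index[table[bad[0]].isna()][0]
        raise ValueError(
            f"missing values in Stage-3 predictors {bad} (first at row {first})"
        )
    return table


def build_stage3_table(
    world: SyntheticWorld,
    augmented: pd.DataFrame,
    sites: pd.DataFrame,
    aod_fields: dict,
    lagged_by_year: dict,
) -> pd.DataFrame:
    """Assemble the monitor-day Stage-3 table (15 + 27 predictors).

    ``augmented`` is Stage-1 output (monitor_id, date, pm25,
    provenance); ``aod_fields`` maps wavelength to the *imputed*
    :class:`DailyAODField`; ``lagged_by_year`` maps year to the
    monitor-level lagged feature table. The returned frame carries the
    key columns (monitor_id, date, pm25, provenance) followed by the 42
    predictor columns.
    """
    aug = augmented.copy()
    aug["date"] = pd.to_datetime(aug["date"])
    site_ix = sites.set_index("monitor_id")
    cell_ids = site_ix.loc[aug["monitor_id"], "cell_id"].to_numpy(int)
    t_idx = world.dates.get_indexer(aug["date"])
    if (t_idx < 0).any():
        bad = aug["date"].iloc[int(np.argmax(t_idx < 0))]
        raise ValueError(f"date {bad.date()} outside the study period")

    years = aug["date"].dt.year.to_numpy()
    parts = []
    for year in np.unique(years):
        sel = years == year
        if int(year) not in lagged_by_year:
            raise ValueError(f"no lagged features for year {year}")
        pred = _assemble_stage3(
            world,
            t_idx[sel],
            cell_ids[sel],
            aod_fields,
            lagged_by_year[int(year)],
            "monitor_id",
            aug.loc[sel, "monitor_id"].to_numpy(),
        )
        keys = aug.loc[sel, ["monitor_id", "date", "pm25", "provenance"]].reset_index(drop=True)
        parts.append(pd.concat([keys, pred], axis=1))
    return pd.concat(parts, ignore_index=True)


def build_grid_stage3_table(
    world: SyntheticWorld,
    cell_ids: np.ndarray,
    dates,
    aod_fields: dict,
    grid_lagged_by_year: dict,
) -> pd.DataFrame:
    """Assemble the cell-day Stage-3 table for grid reconstruction.

    Same predictor schema as :func:`build_stage3_table`, keyed by
    (cell_id, date); lagged features come from the all-donors grid
    variant.
    """
    cell_ids = np.asarray(cell_ids)
    dates = pd.DatetimeIndex(dates)
    t_of = world.dates.get_indexer(dates)
    if (t_of < 0).any():
        raise ValueError("some dates fall outside the study period")

    parts = []
    for d, t in zip(dates, t_of):
        year = int(d.year)
        if year not in grid_lagged_by_year:
            raise ValueError(f"no grid lagged features for year {year}")
        pred = _assemble_stage3(
            world,
            np.full(len(cell_ids), t),
            cell_ids,
            aod_fields,
            grid_lagged_by_year[year],
            "cell_id",
            cell_ids,
        )
        keys = pd.DataFrame({"cell_id": cell_ids, "date": d})
        parts.append(pd.concat([keys, pred], axis=1))
    return pd.concat(parts, ignore_index=True)


def fit_stage3(
    table: pd.DataFrame,
    year: int,
    spec: LearnerSpec = LearnerSpec(500, 20),
    target_column: str = "pm25",
) -> FittedStageModel:
    """Fit the per-year Stage-3 forest for log PM2.5.

    ``table`` is :func:`build_stage3_table` output; rows of other years
    are ignored so per-year isolation holds by construction.
    """
    df = table[pd.to_datetime(table["date"]).dt.year == year]
    if df.empty:
        raise ValueError(f"no Stage-3 rows in {year}")
    y_nat = df[target_column].to_numpy(float)
    if (y_nat <= 0).any():
        raise ValueError("Stage-3 targets must be strictly positive for the log transform")
    X = df.loc[:, list(STAGE3_COLUMNS)].to_numpy(float)
    rf = _fit_forest(X, np.log(y_nat), spec)
    return FittedStageModel(
        stage=3,
        year=year,
        spec=spec,
        learner=rf,
        schema=STAGE3_COLUMNS,
        target_transform="log",
        oob_pred=rf.oob_prediction_,
        train_index=df.index,
    )


def predict_stage3(model: FittedStageModel, table: pd.DataFrame) -> np.ndarray:
    """Back-transformed (strictly positive) Stage-3 predictions, ug/m3.

    Naive exponentiation of the forest output; no smearing correction.
    """
    if model.stage != 3:
        raise ValueError("predict_stage3 requires a Stage-3 model")
    return model.predict(table)
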