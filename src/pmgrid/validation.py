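"""Monitor-based cross-validation and performance decomposition.

Model skill is summarised the way air-pollution exposure models are
conventionally reported: predicted values are regressed on observed
values by ordinary least squares, and R² (squared Pearson correlation),
RMSE of the raw errors, and the regression intercept and slope are
quoted. Statistics are computed

* **overall** on the pooled series,
* **spatially** on per-monitor means across the series (skill at
  ranking locations by long-term average), and
* **temporally** on per-monitor-centered daily deviations (skill at
  tracking day-to-day variation). Because both centered series have
  exactly zero mean, the temporal intercept is structurally zero.

Cross-validation groups whole monitors: each of k random groups is
predicted by a model fitted on the other k-1, so held-out predictions
measure skill at locations the model has never seen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FoldAssignment",
    "PerformanceStats",
    "make_folds",
    "cross_validate",
    "performance_stats",
    "decompose_spatial_temporal",
    "seasonal_stats",
    "importance_table",
    "season_of",
]

logger = logging.getLogger(__name__)

SEASONS = ("DJF", "MAM", "JJA", "SON")


@dataclass(frozen=True)
class FoldAssignment:
    """Partition of monitors into k cross-validation groups."""

    assignment: dict  # monitor_id -> fold in {1..k}
    k: int
    seed: int

    def monitors_in(self, fold: int) -> list:
        return [m for m, f in self.assignment.items() if f == fold]


@dataclass(frozen=True)
class PerformanceStats:
    """R², RMSE, intercept and slope of predicted-on-observed OLS."""

    r2: float
    rmse: float
    intercept: float
    slope: float
    n: int
    domain: str = "overall"  # overall | spatial | temporal
    method: str = "kfold"  # OOB | kfold
    year: int | None = None
    season: str | None = None

    def as_dict(self) -> dict:
        return {
            "r2": self.r2, "rmse": self.rmse, "intercept": self.intercept,
            "slope": self.slope, "n": self.n, "domain": self.domain,
            "method": self.method, "year": self.year, "season": self.season,
        }


def make_folds(sites: pd.DataFrame, k: int = 10, seed: int = 0) -> FoldAssignment:
    """Uniform random partition of monitors into k folds, reproducible by seed."""
    ids = list(sites["monitor_id"])
    if len(ids) < k:
        raise ValueError(f"need at least {k} monitors for {k}-fold CV, have {len(ids)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    assignment = {}
    for pos, idx in enumerate(order):
        assignment[ids[idx]] = pos % k + 1
    return FoldAssignment(assignment=assignment, k=k, seed=seed)


def cross_validate(
    fit_fn,
    predict_fn,
    data: pd.DataFrame,
    folds: FoldAssignment,
) -> pd.Series:
    """Held-out predictions for every row, aligned to ``data``'s index.

    For each fold, ``fit_fn(train_rows)`` fits a model on all rows of
    monitors outside the fold and ``predict_fn(model, test_rows)``
    predicts the fold's rows; a monitor's predictions therefore never
    come from a model that saw any of its data.
    """
    fold_of = data["monitor_id"].map(folds.assignment)
    if fold_of.isna().any():
        missing = data.loc[fold_of.isna(), "monitor_id"].unique()[:5]
        raise ValueError(f"monitors without fold assignment: {list(missing)}")
    preds = pd.Series(np.nan, index=data.index, dtype=float)
    for fold in range(1, folds.k + 1):
        test = fold_of == fold
        if not test.any():
            continue
        train_rows = data[~test]
        if train_rows.empty:
            raise ValueError(f"fold {fold} leaves no training data")
        model = fit_fn(train_rows)
        preds[test] = predict_fn(model, data[test])
    return preds


def performance_stats(
    pred,
    obs,
    domain: str = "overall",
    method: str = "kfold",
    year: int | None = None,
    season: str | None = None,
    min_n: int = 3,
) -> PerformanceStats:
    """OLS of predicted on observed, R² as squared correlation, raw-error RMSE.

    ``min_n`` is 3 for series statistics; the spatial decomposition
    lowers it to 2, where the two-point regression is still defined.
    """
    pred = np.asarray(pred, float)
    obs = np.asarray(obs, float)
    if pred.shape != obs.shape:
        raise ValueError("pred and obs must be aligned")
    if pred.size < min_n:
        raise ValueError(f"need at least {min_n} pairs, got {pred.size}")
    if np.std(obs) == 0:
        raise ValueError("observed series has zero variance")
    slope, intercept = np.polyfit(obs, pred, 1)
    r = np.corrcoef(obs, pred)[0, 1] if np.std(pred) > 0 else 0.0
    return PerformanceStats(
        r2=float(r**2),
        rmse=float(np.sqrt(np.mean((pred - obs) ** 2))),
        intercept=float(intercept),
        slope=float(slope),
        n=int(pred.size),
        domain=domain,
        method=method,
        year=year,
        season=season,
    )


def decompose_spatial_temporal(
    pred,
    obs,
    monitor_ids,
    method: str = "kfold",
    year: int | None = None,
    season: str | None = None,
) -> tuple[PerformanceStats, PerformanceStats]:
    """Split performance into spatial and temporal components.

    Spatial: OLS of per-monitor mean prediction on per-monitor mean
    observation (one point per monitor). Temporal: OLS on the pooled
    per-monitor-centered deviations; its intercept vanishes up to
    floating point because both centered series average to zero.
    """
    df = pd.DataFrame({
        "pred": np.asarray(pred, float),
        "obs": np.asarray(obs, float),
        "monitor_id": np.asarray(monitor_ids),
    })
    g = df.groupby("monitor_id")[["pred", "obs"]].mean()
    if len(g) < 2:
        raise ValueError("spatial decomposition needs at least 2 monitors")
    spatial = performance_stats(
        g["pred"], g["obs"], domain="spatial", method=method, year=year,
        season=season, min_n=2,
    )
    centered = df[["pred", "obs"]] - df.groupby("monitor_id")[["pred", "obs"]].transform("mean")
    temporal = performance_stats(
        centered["pred"], centered["obs"],
        domain="temporal", method=method, year=year, season=season,
    )
    return spatial, temporal


def season_of(dates) -> pd.Series:
    """Meteorological season (DJF/MAM/JJA/SON) of each date."""
    months = pd.to_datetime(pd.Series(dates)).dt.month
    return months.map(
        lambda m: "DJF" if m in (12, 1, 2)
        else "MAM" if m in (3, 4, 5)
        else "JJA" if m in (6, 7, 8)
        else "SON"
    )


def seasonal_stats(
    pred,
    obs,
    dates,
    monitor_ids,
    method: str = "kfold",
    year: int | None = None,
) -> dict:
    """Overall/spatial/temporal stats per meteorological season.

    Returns ``{season: {domain: PerformanceStats}}``; seasons with no
    data (or too few monitors for a domain) are skipped with a log
    notice.
    """
    df = pd.DataFrame({
        "pred": np.asarray(pred, float),
        "obs": np.asarray(obs, float),
        "monitor_id": np.asarray(monitor_ids),
        "season": season_of(dates).to_numpy(),
    })
    out = {}
    for season in SEASONS:
        sub = df[df["season"] == season]
        if sub.empty:
            logger.info("season %s has no data; skipped", season)
            continue
        entry = {}
        try:
            entry["overall"] = performance_stats(
                sub["pred"], sub["obs"], method=method, year=year, season=season
            )
            spatial, temporal = decompose_spatial_temporal(
                sub["pred"], sub["obs"], sub["monitor_id"],
                method=method, year=year, season=season,
            )
            entry["spatial"] = spatial
            entry["temporal"] = temporal
        except ValueError as err:
            logger.info("season %s: %s", season, err)
        if entry:
            out[season] = entry
    return out


def importance_table(model) -> pd.DataFrame:
    """Split-impurity predictor importances as percentages, descending.

    The forest's impurity-based importances (error reduction credited
    to each predictor's splits, averaged over trees) are normalized to
    sum to 100%.
    """
    learner = getattr(model, "learner", model)
    if not hasattr(learner, "feature_importances_"):
        raise ValueError("model is not a fitted forest")
    schema = getattr(model, "schema", None)
    names = list(schema) if schema is not None else [
        f"x{i}" for i in range(len(learner.feature_importances_))
    ]
    imp = np.asarray(learner.feature_importances_, float)
    pct = 100.0 * imp / imp.sum()
    out = pd.DataFrame({"predictor": names, "importance_pct": pct})
    out = out.sort_values("importance_pct", ascending=False, kind="stable")
    return out.reset_index(drop=True)
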