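"""Monitor network quality control and gridded-product preprocessing.

Covers the record-level cleaning applied before any model fitting:

* deduplication of co-located monitors reported by more than one
  network (identical series at essentially the same coordinates);
* hourly/daily completeness filters (a monitor-day needs at least 18
  hourly values; a monitor-year needs at least 30 surviving days);
* assignment of point locations to 1 km grid cells;
* nearest-centroid linkage of coarse gridded products to the 1 km grid;
* QA-filtered compositing of per-overpass satellite AOD scenes into
  one daily field per wavelength.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import GridSpec

__all__ = [
    "GridSpec",
    "QAPolicy",
    "AODScene",
    "DailyAODField",
    "dedupe_colocated",
    "apply_completeness_filters",
    "assign_cell_id",
    "link_nearest_centroid",
    "composite_daily_aod",
    "composite_all_days",
]

MIN_HOURS_PER_DAY = 18
MIN_DAYS_PER_YEAR = 30

PROVENANCE_MISSING = 0
PROVENANCE_OBSERVED = 1
PROVENANCE_IMPUTED = 2


@dataclass(frozen=True)
class QAPolicy:
    """Quality filter for satellite AOD overpass values.

    A value survives if its QA flag is "best" (when ``require_best_qa``)
    and its retrieval uncertainty does not exceed
    ``uncertainty_threshold``.
    """

    require_best_qa: bool = True
    uncertainty_threshold: float = 0.05


@dataclass
class AODScene:
    """One satellite overpass: per-cell AOD values with QA metadata.

    ``values`` maps wavelength (um) to a 2-D ``(ny, nx)`` array with NaN
    where the retrieval is cloud-masked.
    """

    date: pd.Timestamp
    overpass: str
    values: dict
    uncertainty: np.ndarray
    qa_best: np.ndarray

    def __post_init__(self) -> None:
        for wl, arr in self.values.items():
            if np.isfinite(arr).any() and np.nanmin(arr) < 0:
                raise ValueError(f"negative AOD at wavelength {wl}")


@dataclass
class DailyAODField:
    """Daily per-cell AOD for one wavelength over the study period.

    ``values`` is ``(T, ny, nx)`` with NaN = missing; ``provenance``
    distinguishes observed composites from Stage-2 imputations.
    """

    wavelength: float
    dates: pd.DatetimeIndex
    values: np.ndarray
    provenance: np.ndarray  # uint8: 0 missing, 1 observed, 2 imputed

    @property
    def missing_mask(self) -> np.ndarray:
        return ~np.isfinite(self.values)

    @property
    def missing_fraction(self) -> float:
        return float(self.missing_mask.mean())


def dedupe_colocated(
    sites: pd.DataFrame,
    records: pd.DataFrame,
    preferred_network: str = "A",
    max_distance_km: float = 0.1,
    corr_tol: float = 1e-9,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop non-preferred-network duplicates of co-located monitors.

    Two monitors from different networks are duplicates when their PM
    series correlate to exactly 1 (within ``corr_tol``) on overlapping
    days and they sit less than ``max_distance_km`` apart. Of each
    duplicate pair the monitor from ``preferred_network`` is kept; if
    neither is preferred, the first by monitor id survives.
    """
    sites = sites.reset_index(drop=True)
    xy = sites[["easting", "northing"]].to_numpy(float)
    drop: set[str] = set()

    def series(mid, col):
        r = records[records["monitor_id"] == mid]
        return r.set_index("date")[col].dropna()

    n = len(sites)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = sites.iloc[i], sites.iloc[j]
            if a["network"] == b["network"]:
                continue
            if a["monitor_id"] in drop or b["monitor_id"] in drop:
                continue
            if np.hypot(*(xy[i] - xy[j])) >= max_distance_km:
                continue
            duplicate = False
            for col in ("pm25", "pm10"):
                sa, sb = series(a["monitor_id"], col), series(b["monitor_id"], col)
                common = sa.index.intersection(sb.index)
                if len(common) < 2:
                    continue
                va, vb = sa.loc[common].to_numpy(), sb.loc[common].to_numpy()
                if va.std() == 0 or vb.std() == 0:
                    continue
                if abs(np.corrcoef(va, vb)[0, 1] - 1.0) <= corr_tol:
                    duplicate = True
                    break
            if not duplicate:
                continue
            if a["network"] == preferred_network:
                drop.add(b["monitor_id"])
            elif b["network"] == preferred_network:
                drop.add(a["monitor_id"])
            else:
                drop.add(max(a["monitor_id"], b["monitor_id"]))

    kept_sites = sites[~sites["monitor_id"].isin(drop)].reset_index(drop=True)
    kept_records = records[~records["monitor_id"].isin(drop)].reset_index(drop=True)
    return kept_sites, kept_records


def apply_completeness_filters(records: pd.DataFrame) -> pd.DataFrame:
    """Apply the 18-hour and 30-day completeness rules per pollutant.

    A pollutant value on a monitor-day is dropped (set to NaN) when
    fewer than 18 hourly values contributed to it; after that, a
    monitor-year with fewer than 30 surviving days for a pollutant
    loses that pollutant for the whole year. Rows left with neither
    pollutant are removed. Idempotent.
    """
    rec = records.copy()
    rec["date"] = pd.to_datetime(rec["date"])
    year = rec["date"].dt.year

    for pol in ("pm25", "pm10"):
        hours = rec[f"hours_{pol}"]
        rec.loc[hours < MIN_HOURS_PER_DAY, pol] = np.nan
        valid = rec[pol].notna()
        counts = valid.groupby([rec["monitor_id"], year]).transform("sum")
        rec.loc[valid & (counts < MIN_DAYS_PER_YEAR), pol] = np.nan

    rec = rec[rec["pm25"].notna() | rec["pm10"].notna()]
    return rec.reset_index(drop=True)


def assign_cell_id(points: pd.DataFrame, grid: GridSpec) -> pd.DataFrame:
    """Attach the containing 1 km cell id to each point.

    ``points`` needs ``easting``/``northing`` columns (km). Cell
    membership uses the half-open convention [left, right) x
    [bottom, top); points outside the grid raise ``ValueError``.
    """
    out = points.copy()
    out["cell_id"] = grid.point_to_cell(
        out["easting"].to_numpy(float), out["northing"].to_numpy(float)
    )
    return out


def link_nearest_centroid(
    coarse_values: np.ndarray,
    coarse_x: np.ndarray,
    coarse_y: np.ndarray,
    grid: GridSpec,
) -> np.ndarray:
    """Spread a coarse field onto the 1 km grid by nearest pixel centroid.

    Every 1 km cell receives the value of the coarse pixel whose
    centroid is nearest to the cell centroid (Euclidean distance, ties
    broken by the smallest coarse-pixel index). ``coarse_values`` may
    have leading axes (e.g. time); the last axis enumerates coarse
    pixels aligned with ``coarse_x``/``coarse_y``.

    Returns an array whose last axis has ``grid.n_cells`` entries.
    """
    coarse_x = np.asarray(coarse_x, float).ravel()
    coarse_y = np.asarray(coarse_y, float).ravel()
    if coarse_x.size == 0:
        raise ValueError("empty coarse field")
    cx, cy = grid.centroids()
    d2 = (cx[:, None] - coarse_x[None]) ** 2 + (cy[:, None] - coarse_y[None]) ** 2
    # argmin returns the first (lowest-index) minimiser, which is the tie rule.
    nearest = np.argmin(d2, axis=1)
    values = np.asarray(coarse_values)
    return values[..., nearest]


def composite_daily_aod(
    scenes: list[AODScene],
    qa_policy: QAPolicy | None = None,
) -> dict:
    """Average QA-passing overpass values into one daily field per wavelength.

    Per cell, overpass values failing the QA policy are dropped and the
    survivors averaged; a cell with no survivor is missing (NaN).
    Returns ``{wavelength: 2-D array}``.
    """
    if not scenes:
        raise ValueError("no scenes to composite")
    qa_policy = qa_policy or QAPolicy()
    dates = {pd.Timestamp(s.date) for s in scenes}
    if len(dates) != 1:
        raise ValueError(f"scenes span multiple dates: {sorted(d.date() for d in dates)}")

    out = {}
    wavelengths = scenes[0].values.keys()
    for wl in wavelengths:
        num = np.zeros_like(scenes[0].values[wl], dtype=float)
        cnt = np.zeros_like(num)
        for s in scenes:
            v = s.values[wl]
            ok = np.isfinite(v)
            if qa_policy.require_best_qa:
                ok &= s.qa_best
            ok &= s.uncertainty <= qa_policy.uncertainty_threshold
            num[ok] += v[ok]
            cnt[ok] += 1
        with np.errstate(invalid="ignore"):
            out[wl] = np.where(cnt > 0, num / np.maximum(cnt, 1), np.nan)
    return out


def composite_all_days(world, qa_policy: QAPolicy | None = None) -> dict:
    """Composite every study day of a synthetic world.

    Returns ``{wavelength: DailyAODField}`` with provenance marked
    observed where a composite exists.
    """
    from .synthetic import SATELLITE_WAVELENGTHS

    qa_policy = qa_policy or QAPolicy()
    T = world.n_days
    fields = {}
    for wl in SATELLITE_WAVELENGTHS:
        values = np.full_like(world.truth_pm25, np.nan, dtype=float)
        for t in range(T):
            scenes = [
                AODScene(
                    date=world.dates[t],
                    overpass=str(o),
                    values={wl: world.aod_scene_values[wl][t, o]},
                    uncertainty=world.aod_scene_uncertainty[t, o],
                    qa_best=world.aod_scene_qa_best[t, o],
                )
                for o in (0, 1)
            ]
            values[t] = composite_daily_aod(scenes, qa_policy)[wl]
        provenance = np.where(
            np.isfinite(values), PROVENANCE_OBSERVED, PROVENANCE_MISSING
        ).astype(np.uint8)
        fields[wl] = DailyAODField(
            wavelength=wl, dates=world.dates, values=values, provenance=provenance
        )
    return fields
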