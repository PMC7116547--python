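"""Spatially-lagged annual-average PM2.5 features and nearest-class distances.

Monitors are grouped into two classes — background (urban, suburban,
rural) and hotspot (traffic, industrial). For each target (a monitor or
a grid cell) and year, four inverse-distance-weighted averages of the
other monitors' annual mean PM2.5 are formed: one per class for weight
powers 1 ("regional", favouring broad structure) and 2 ("local",
dominated by nearby monitors). For monitor targets the target monitor
itself is always excluded (leave-one-out); for grid cells all class
monitors contribute. Two further features give the Euclidean distance
to the nearest monitor of each class.

Distances are in km and are floored at half a cell (0.5 km by default)
so co-located donor/target pairs cannot produce infinite weights.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grid import GridSpec

__all__ = [
    "BACKGROUND_TYPES",
    "HOTSPOT_TYPES",
    "monitor_class",
    "annual_class_means",
    "idw_loocv_lagged",
    "idw_grid_lagged",
    "nearest_class_distance",
    "monitor_feature_table",
    "grid_feature_table",
    "LAGGED_FEATURES",
]

BACKGROUND_TYPES = ("urban", "suburban", "rural")
HOTSPOT_TYPES = ("traffic", "industrial")

#: Feature names in schema order: four IDW-lagged + two distances.
LAGGED_FEATURES = (
    "lag_hotspot_regional",
    "lag_background_regional",
    "lag_hotspot_local",
    "lag_background_local",
    "dist_hotspot",
    "dist_background",
)

DISTANCE_FLOOR_KM = 0.5


def monitor_class(monitor_type) -> "pd.Series | str":
    """Map monitor type(s) to the hotspot/background class grouping."""
    if isinstance(monitor_type, str):
        return "hotspot" if monitor_type in HOTSPOT_TYPES else "background"
    s = pd.Series(monitor_type)
    return s.isin(HOTSPOT_TYPES).map({True: "hotspot", False: "background"})


def annual_class_means(
    records: pd.DataFrame, sites: pd.DataFrame, year: int
) -> pd.DataFrame:
    """Annual mean observed PM2.5 per monitor, with class label.

    Monitors without any PM2.5 value in the year are absent from the
    result. Columns: monitor_id, year, cls, mean_pm25, n_days.
    """
    rec = records.copy()
    rec["date"] = pd.to_datetime(rec["date"])
    rec = rec[(rec["date"].dt.year == year) & rec["pm25"].notna()]
    if rec.empty:
        return pd.DataFrame(
            columns=["monitor_id", "year", "cls", "mean_pm25", "n_days"]
        )
    g = rec.groupby("monitor_id")["pm25"].agg(["mean", "size"]).reset_index()
    g.columns = ["monitor_id", "mean_pm25", "n_days"]
    g["year"] = year
    cls = sites.set_index("monitor_id")["monitor_type"].map(
        lambda t: monitor_class(t)
    )
    g["cls"] = g["monitor_id"].map(cls)
    return g[["monitor_id", "year", "cls", "mean_pm25", "n_days"]]


def _idw(
    target_xy: np.ndarray,
    donor_xy: np.ndarray,
    donor_means: np.ndarray,
    power: int,
    floor_km: float = DISTANCE_FLOOR_KM,
) -> float:
    d = np.hypot(donor_xy[:, 0] - target_xy[0], donor_xy[:, 1] - target_xy[1])
    d = np.maximum(d, floor_km)
    w = d ** (-float(power))
    return float(np.sum(w * donor_means) / np.sum(w))


def _donors(means, sites, cls, exclude=None):
    m = means[means["cls"] == cls]
    if exclude is not None:
        m = m[m["monitor_id"] != exclude]
    if m.empty:
        return None, None
    pos = sites.set_index("monitor_id").loc[m["monitor_id"], ["easting", "northing"]]
    return pos.to_numpy(float), m["mean_pm25"].to_numpy(float)


def idw_loocv_lagged(
    means: pd.DataFrame,
    sites: pd.DataFrame,
    target_monitor: str,
    cls: str,
    power: int,
) -> float:
    """IDW mean of the class's annual averages, excluding the target monitor.

    Returns NaN when no other monitor of the class has a mean that year
    (missingness is propagated, never replaced by zero).
    """
    if power not in (1, 2):
        raise ValueError(f"power must be 1 or 2, got {power}")
    donor_xy, donor_means = _donors(means, sites, cls, exclude=target_monitor)
    if donor_xy is None:
        return float("nan")
    t = sites.set_index("monitor_id").loc[target_monitor, ["easting", "northing"]]
    return _idw(t.to_numpy(float), donor_xy, donor_means, power)


def idw_grid_lagged(
    means: pd.DataFrame,
    sites: pd.DataFrame,
    grid: GridSpec,
    cls: str,
    power: int,
) -> np.ndarray:
    """IDW lagged field at every cell centroid, using all class monitors."""
    if power not in (1, 2):
        raise ValueError(f"power must be 1 or 2, got {power}")
    donor_xy, donor_means = _donors(means, sites, cls)
    if donor_xy is None:
        raise ValueError(f"no monitor of class {cls!r} with an annual mean")
    cx, cy = grid.centroids()
    d = np.hypot(cx[:, None] - donor_xy[None, :, 0], cy[:, None] - donor_xy[None, :, 1])
    d = np.maximum(d, DISTANCE_FLOOR_KM)
    w = d ** (-float(power))
    return (w @ donor_means) / w.sum(axis=1)


def nearest_class_distance(
    target_xy: np.ndarray,
    sites: pd.DataFrame,
    cls: str,
    exclude_monitor: str | None = None,
) -> np.ndarray:
    """Euclidean distance (km) from target(s) to the nearest monitor of a class.

    ``target_xy`` is ``(n, 2)`` (or a single pair). For a monitor
    target of the same class, pass ``exclude_monitor`` so the monitor
    does not report distance zero to itself.
    """
    cls_sites = sites[monitor_class(sites["monitor_type"]).to_numpy() == cls]
    if exclude_monitor is not None:
        cls_sites = cls_sites[cls_sites["monitor_id"] != exclude_monitor]
    if cls_sites.empty:
        raise ValueError(f"no monitor of class {cls!r}")
    xy = np.atleast_2d(np.asarray(target_xy, float))
    sxy = cls_sites[["easting", "northing"]].to_numpy(float)
    d = np.hypot(xy[:, 0:1] - sxy[None, :, 0], xy[:, 1:2] - sxy[None, :, 1])
    out = d.min(axis=1)
    return out if out.size > 1 else float(out[0])


def monitor_feature_table(
    records: pd.DataFrame,
    sites: pd.DataFrame,
    year: int,
    donor_ids=None,
) -> pd.DataFrame:
    """All six features for every monitor, leave-one-out, for one year.

    Rows: one per monitor in ``sites``; columns ``LAGGED_FEATURES``.
    Lagged values are NaN for a class with no eligible donor.
    ``donor_ids`` restricts which monitors may contribute annual means
    (used by the strict leakage-controlled cross-validation mode, where
    held-out monitors may not inform the features of others).
    """
    if donor_ids is not None:
        records = records[records["monitor_id"].isin(set(donor_ids))]
    means = annual_class_means(records, sites, year)
    rows = []
    for _, site in sites.iterrows():
        mid = site["monitor_id"]
        xy = np.array([site["easting"], site["northing"]], float)
        own_cls = monitor_class(site["monitor_type"])
        row = {"monitor_id": mid, "year": year}
        row["lag_hotspot_regional"] = idw_loocv_lagged(means, sites, mid, "hotspot", 1)
        row["lag_background_regional"] = idw_loocv_lagged(means, sites, mid, "background", 1)
        row["lag_hotspot_local"] = idw_loocv_lagged(means, sites, mid, "hotspot", 2)
        row["lag_background_local"] = idw_loocv_lagged(means, sites, mid, "background", 2)
        for cls in ("hotspot", "background"):
            row[f"dist_{cls}"] = nearest_class_distance(
                xy, sites, cls, exclude_monitor=mid if own_cls == cls else None
            )
        rows.append(row)
    return pd.DataFrame(rows)


def grid_feature_table(
    records: pd.DataFrame, sites: pd.DataFrame, grid: GridSpec, year: int
) -> pd.DataFrame:
    """All six features at every grid cell centroid for one year."""
    means = annual_class_means(records, sites, year)
    cx, cy = grid.centroids()
    out = pd.DataFrame({"cell_id": grid.cell_ids, "year": year})
    out["lag_hotspot_regional"] = idw_grid_lagged(means, sites, grid, "hotspot", 1)
    out["lag_background_regional"] = idw_grid_lagged(means, sites, grid, "background", 1)
    out["lag_hotspot_local"] = idw_grid_lagged(means, sites, grid, "hotspot", 2)
    out["lag_background_local"] = idw_grid_lagged(means, sites, grid, "background", 2)
    xy = np.column_stack([cx, cy])
    for cls in ("hotspot", "background"):
        out[f"dist_{cls}"] = nearest_class_distance(xy, sites, cls)
    return out
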