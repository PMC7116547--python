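"""Self-contained synthetic study region for the four-stage PM2.5 pipeline.

The generator produces a latent daily PM2.5 field on a km-scale planar
grid and derives from it every observed product the pipeline consumes:

* monitor networks measuring PM10 and (a subset) PM2.5, with hourly
  completeness metadata so the quality-control filters bind;
* satellite aerosol optical depth (AOD) scenes from two daily
  overpasses, cloud-masked so that ~87-94% of daily composites are
  missing, with quality-assurance flags and retrieval uncertainty;
* a coarse multi-wavelength, multi-hour modelled-AOD reanalysis;
* a spatially smoothed, multiplicatively biased model PM2.5 surface
  standing for a chemical-transport-model simulation;
* meteorology (temperature, sea-level pressure, relative humidity,
  precipitation, wind speed/direction, boundary-layer height at 0:00
  and 12:00), monthly vegetation index, and 21 static predictors.

Everything is a deterministic function of the configuration and seed,
so recovery tests can compare pipeline output against the stored truth.

The latent field follows

    log PM2.5(s, t) = mu + regional(s) + hotspot(s) + season(t)
                      + weather(s, t) + eps(s, t)

with a smooth low-frequency regional surface (three broad Gaussian
bumps), sparse narrow hotspot bumps co-located with high road density
and imperviousness, an annual cosine peaking in winter, a linear
weather term (negative in boundary-layer height, wind speed and
precipitation, weakly positive in temperature), and i.i.d. Gaussian
residual noise of scale ``sigma_resid``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import GridSpec

__all__ = [
    "WorldConfig",
    "SyntheticWorld",
    "generate_world",
    "truth_at",
    "export_world",
    "import_world",
    "AOD_WAVELENGTHS",
    "CAMS_HOURS",
    "MET_FIELDS",
    "STATIC_COLUMNS",
    "LAND_COVER_CLASSES",
]

#: AOD wavelengths (um); the first two are retrieved by the satellite
#: product, all five are available from the modelled-AOD reanalysis.
AOD_WAVELENGTHS = (0.47, 0.55, 0.67, 0.865, 1.24)
SATELLITE_WAVELENGTHS = (0.47, 0.55)
#: Sub-day hours at which the modelled-AOD reanalysis reports.
CAMS_HOURS = (3, 6, 9, 12, 15, 18, 21)

MET_FIELDS = (
    "air_temp",
    "slp",
    "rh",
    "precip",
    "wind_speed",
    "wind_dir",
    "blh_00",
    "blh_12",
)

LAND_COVER_CLASSES = (
    "lc_urban_fabric",
    "lc_industrial",
    "lc_road_rail",
    "lc_green_urban",
    "lc_arable",
    "lc_pasture",
    "lc_forest",
    "lc_shrub",
    "lc_water_wetland",
)

#: Static predictor table columns (beyond cell_id); together with the
#: four spatially-lagged and two nearest-distance monitor features these
#: form the 27 spatial predictors of the Stage-3 model.
STATIC_COLUMNS = (
    ("elevation",)
    + LAND_COVER_CLASSES
    + (
        "impervious",
        "night_light",
        "road_dens_highway",
        "road_dens_secondary",
        "road_dens_local",
        "road_invd_highway",
        "road_invd_secondary",
        "road_invd_local",
        "pop_density",
        "airport_invd",
        "seashore_invd",
    )
)

MONITOR_TYPES = ("traffic", "industrial", "urban", "suburban", "rural")
HOTSPOT_TYPES = ("traffic", "industrial")

# Ångström-like multiplicative scaling of 0.55 um AOD to the other
# wavelengths; fixed constants (exponent 1.3, typical of fine-mode
# dominated aerosol), not fitted.
_ANGSTROM_EXPONENT = 1.3
WAVELENGTH_FACTORS = {
    wl: (wl / 0.55) ** (-_ANGSTROM_EXPONENT) for wl in AOD_WAVELENGTHS
}

# Log-scale generative coefficients (weather term uses standardized fields).
_MU_LOG = np.log(9.0)
_SEASON_AMP = 0.22
_BETA_BLH = -0.30
_BETA_WIND = -0.15
_BETA_TEMP = 0.05
_BETA_PRECIP = -0.12
_AOD_SCALE = 0.02  # column AOD per (ug/m3 * km of mixing depth)


@dataclass(frozen=True)
class WorldConfig:
    """Parameters of the synthetic study region.

    Noise scales are on the generative (log or native) scale stated in
    the module docstring; ``aod_missing_target`` is the daily composite
    missing fraction the cloud process is calibrated to.
    """

    grid_nx: int = 40
    grid_ny: int = 40
    cell_size: float = 1.0
    years: tuple[int, ...] = (2016,)
    n_monitors: int = 120
    frac_pm25_monitors: float = 0.5
    aod_missing_target: float = 0.90
    sigma_resid: float = 0.20
    sigma_pm10_ratio: float = 0.07
    sigma_aod: float = 0.015
    sigma_ctm: float = 0.25
    sigma_obs: float = 0.02
    coarse_factor: int = 10
    n_duplicate_pairs: int = 1
    identity_aod: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_nx < 8 or self.grid_ny < 8:
            raise ValueError(
                f"grid_nx/grid_ny must be >= 8, got {self.grid_nx}x{self.grid_ny}"
            )
        if not (0 < self.frac_pm25_monitors <= 1):
            raise ValueError(
                f"frac_pm25_monitors must lie in (0, 1], got {self.frac_pm25_monitors}"
            )
        if not (0.5 <= self.aod_missing_target <= 0.99):
            raise ValueError(
                f"aod_missing_target must lie in [0.5, 0.99], got {self.aod_missing_target}"
            )
        if self.n_monitors < 4:
            raise ValueError(f"n_monitors must be >= 4, got {self.n_monitors}")
        for name in ("sigma_resid", "sigma_pm10_ratio", "sigma_aod", "sigma_ctm", "sigma_obs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        object.__setattr__(self, "years", tuple(int(y) for y in self.years))
        if not self.years:
            raise ValueError("years must be non-empty")


@dataclass
class SyntheticWorld:
    """All generated fields of a synthetic study region.

    Gridded arrays have shape ``(n_days, ny, nx)`` unless noted; the
    AOD scene arrays carry an extra overpass axis of length 2.
    """

    config: WorldConfig
    grid: GridSpec
    dates: pd.DatetimeIndex
    truth_pm25: np.ndarray  # (T, ny, nx), ug/m3
    sites: pd.DataFrame  # monitor_id, easting, northing, network, monitor_type, cell_id
    records: pd.DataFrame  # monitor_id, date, pm25, pm10, hours_pm25, hours_pm10
    aod_scene_values: dict  # wavelength -> (T, 2, ny, nx), NaN = cloud-masked
    aod_scene_qa_best: np.ndarray  # (T, 2, ny, nx) bool
    aod_scene_uncertainty: np.ndarray  # (T, 2, ny, nx)
    aod_true: dict  # wavelength -> (T, ny, nx)
    cams: np.ndarray  # (T, 5, 7, cy, cx): wavelength x hour on the coarse grid
    coarse_grid: GridSpec
    ctm_pm25: np.ndarray  # (T, ny, nx)
    met: dict  # name -> (T, ny, nx)
    ndvi: np.ndarray  # (n_months, ny, nx)
    months: pd.PeriodIndex  # month labels aligned to ndvi's first axis
    statics: pd.DataFrame  # cell_id + STATIC_COLUMNS

    @property
    def n_days(self) -> int:
        return len(self.dates)

    def day_index(self, date) -> int:
        date = pd.Timestamp(date)
        idx = self.dates.get_indexer([date])
        if idx[0] < 0:
            raise KeyError(f"date {date.date()} outside the study period")
        return int(idx[0])

    def month_index(self, date) -> int:
        period = pd.Timestamp(date).to_period("M")
        idx = self.months.get_indexer([period])
        if idx[0] < 0:
            raise KeyError(f"month of {date} outside the study period")
        return int(idx[0])


def _smooth_field(rng: np.random.Generator, ny: int, nx: int, sigma: float) -> np.ndarray:
    """Unit-variance spatially correlated Gaussian field."""
    f = ndimage.gaussian_filter(rng.standard_normal((ny, nx)), sigma, mode="nearest")
    sd = f.std()
    return f / sd if sd > 0 else f


def _gaussian_bump(xx, yy, cx, cy, width) -> np.ndarray:
    return np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * width**2))


def _ar1(rng: np.random.Generator, n: int, rho: float, sigma: float) -> np.ndarray:
    eps = rng.normal(0.0, sigma, n)
    out = np.empty(n)
    out[0] = eps[0] / np.sqrt(max(1.0 - rho**2, 1e-12))
    for t in range(1, n):
        out[t] = rho * out[t - 1] + eps[t]
    return out


def _standardize(a: np.ndarray) -> np.ndarray:
    sd = a.std()
    return (a - a.mean()) / sd if sd > 0 else a - a.mean()


def _make_statics(rng, grid: GridSpec, xx, yy):
    """Static predictor table plus the hotspot bump field and population weights."""
    ny, nx = grid.ny, grid.nx
    extent = max(nx, ny) * grid.cell_size

    # Narrow hotspot bumps: urban/industrial sources.
    n_hot = max(3, grid.n_cells // 150)
    hot_cx = rng.uniform(grid.x0, grid.x0 + nx * grid.cell_size, n_hot)
    hot_cy = rng.uniform(grid.y0, grid.y0 + ny * grid.cell_size, n_hot)
    hot_amp = rng.uniform(0.3, 0.6, n_hot)
    hotspot = np.zeros((ny, nx))
    for cx, cy, amp in zip(hot_cx, hot_cy, hot_amp):
        hotspot += amp * _gaussian_bump(xx, yy, cx, cy, rng.uniform(1.0, 1.8))

    hot_norm = hotspot / max(hotspot.max(), 1e-12)
    pop_log = 2.5 * hot_norm + 0.8 * _smooth_field(rng, ny, nx, extent / 8)
    pop = np.exp(pop_log)
    pop_density = 5000.0 * pop / pop.mean()

    urban_intensity = _standardize(np.log(pop_density))

    # Land cover shares: softmax over smooth fields, urban classes tied to
    # population, so hotspot cells really are built-up.
    logits = []
    for i, _name in enumerate(LAND_COVER_CLASSES):
        base = _smooth_field(rng, ny, nx, extent / 10)
        if i < 3:  # urban fabric / industrial / road-rail
            base = base + 1.6 * urban_intensity + 2.2 * hot_norm - 1.0
        elif i == 3:  # green urban
            base = base + 0.5 * urban_intensity - 0.5
        logits.append(base)
    logits = np.stack(logits)
    shares = np.exp(logits - logits.max(axis=0))
    shares /= shares.sum(axis=0)

    impervious = np.clip(
        shares[0] + shares[1] + 0.06 * _smooth_field(rng, ny, nx, extent / 12), 0.0, 1.0
    )
    elevation = 120.0 + 90.0 * _smooth_field(rng, ny, nx, extent / 5) - 60.0 * urban_intensity
    elevation = np.clip(elevation, 0.0, None)
    night_light = np.clip(
        8.0 * hot_norm + 2.0 * np.log1p(pop_density / 1000.0)
        + 0.5 * _smooth_field(rng, ny, nx, extent / 12),
        0.0,
        None,
    )

    road = {}
    for kind, weight in (("highway", 0.6), ("secondary", 0.8), ("local", 1.0)):
        dens = np.clip(
            weight * (1.5 * hot_norm + 0.8 * np.log1p(pop_density / 2000.0))
            + 0.3 * _smooth_field(rng, ny, nx, extent / 10),
            0.0,
            None,
        )
        present = dens > np.quantile(dens, 0.75 if kind == "highway" else 0.6)
        if not present.any():
            present = dens >= dens.max()
        # Distance (km) from each cell centre to the nearest road-carrying cell.
        dist = ndimage.distance_transform_edt(~present, sampling=grid.cell_size)
        road[f"road_dens_{kind}"] = dens
        road[f"road_invd_{kind}"] = 1.0 / (dist + 0.5)

    n_airports = 2
    air_ix = rng.choice(grid.n_cells, n_airports, replace=False, p=(pop / pop.sum()).ravel())
    ax, ay = grid.centroid(air_ix)
    airport_d = np.min(
        np.sqrt((xx[None] - np.asarray(ax)[:, None, None]) ** 2
                + (yy[None] - np.asarray(ay)[:, None, None]) ** 2),
        axis=0,
    )
    airport_invd = 1.0 / (airport_d + 1.0)

    # Seashore = the grid boundary of the island-like domain.
    edge_d = np.minimum.reduce([
        xx - grid.x0,
        grid.x0 + nx * grid.cell_size - xx,
        yy - grid.y0,
        grid.y0 + ny * grid.cell_size - yy,
    ])
    seashore_invd = 1.0 / (edge_d + 1.0)

    cols = {
        "elevation": elevation,
        **{name: shares[i] for i, name in enumerate(LAND_COVER_CLASSES)},
        "impervious": impervious,
        "night_light": night_light,
        **road,
        "pop_density": pop_density,
        "airport_invd": airport_invd,
        "seashore_invd": seashore_invd,
    }
    statics = pd.DataFrame({"cell_id": np.arange(grid.n_cells)})
    for name in STATIC_COLUMNS:
        statics[name] = cols[name].ravel()
    return statics, hotspot, pop


def _make_meteorology(rng, grid: GridSpec, dates: pd.DatetimeIndex):
    """Daily meteorology: national seasonal/AR(1) series + smooth spatial structure."""
    ny, nx, T = grid.ny, grid.nx, len(dates)
    extent = max(nx, ny) * grid.cell_size
    doy = dates.dayofyear.to_numpy()
    season = np.cos(2 * np.pi * (doy - 15) / 365.25)

    def st(base, anom_amp, pat_amp, rho, sig):
        """base(t) + static spatial anomaly + AR(1)-weighted spatial pattern."""
        anom = anom_amp * _smooth_field(rng, ny, nx, extent / 6)
        pattern = pat_amp * _smooth_field(rng, ny, nx, extent / 6)
        w = _ar1(rng, T, rho, sig)
        return base[:, None, None] + anom[None] + w[:, None, None] * pattern[None]

    temp = st(10.0 - 7.0 * season + _ar1(rng, T, 0.8, 1.5), 1.5, 1.0, 0.6, 1.0)
    slp = st(1013.0 + _ar1(rng, T, 0.85, 4.0), 1.0, 2.0, 0.7, 1.0)
    rh = np.clip(st(78.0 + 6.0 * season + _ar1(rng, T, 0.7, 3.0), 3.0, 2.0, 0.6, 1.0), 25, 100)
    precip_z = st(_ar1(rng, T, 0.5, 1.0) - 0.3, 0.2, 0.6, 0.5, 1.0)
    precip = np.clip(precip_z, 0.0, None) ** 2 * 3.0
    wind = np.clip(st(4.5 + 1.2 * season + _ar1(rng, T, 0.7, 1.0), 0.6, 0.5, 0.6, 1.0), 0.3, None)
    wdir = (220.0 + 50.0 * _ar1(rng, T, 0.8, 1.0)[:, None, None]
            + 15.0 * _smooth_field(rng, ny, nx, extent / 6)[None]) % 360.0
    blh00 = np.exp(np.clip(st(np.log(350.0) + 0.10 * season + _ar1(rng, T, 0.75, 0.25),
                              0.08, 0.08, 0.6, 1.0), np.log(50), np.log(2500)))
    blh12 = np.exp(np.clip(st(np.log(850.0) - 0.25 * season + _ar1(rng, T, 0.75, 0.25),
                              0.08, 0.08, 0.6, 1.0), np.log(100), np.log(3000)))
    return {
        "air_temp": temp, "slp": slp, "rh": rh, "precip": precip,
        "wind_speed": wind, "wind_dir": wdir, "blh_00": blh00, "blh_12": blh12,
    }


def _weather_term(met: dict) -> np.ndarray:
    return (
        _BETA_BLH * _standardize(np.log(met["blh_12"]))
        + _BETA_WIND * _standardize(met["wind_speed"])
        + _BETA_TEMP * _standardize(met["air_temp"])
        + _BETA_PRECIP * _standardize(np.minimum(met["precip"], 8.0))
    )


def _place_monitors(rng, cfg: WorldConfig, grid: GridSpec, hotspot, pop):
    """Monitor sites placed preferentially in populated cells, typed by local statics."""
    weights = (pop**1.2).ravel()
    weights /= weights.sum()
    cells = rng.choice(grid.n_cells, size=cfg.n_monitors, replace=False, p=weights)
    cx, cy = grid.centroid(cells)
    # Jitter inside the cell so sites are not exactly on centroids.
    half = grid.cell_size / 2
    ex = cx + rng.uniform(-0.9 * half, 0.9 * half, cfg.n_monitors)
    no = cy + rng.uniform(-0.9 * half, 0.9 * half, cfg.n_monitors)

    hot_level = hotspot.ravel()[cells]
    hot_cut = np.quantile(hotspot, 0.85)
    pop_level = pop.ravel()[cells]
    pop_terciles = np.quantile(pop, [1 / 3, 2 / 3])
    types = []
    for h, p in zip(hot_level, pop_level):
        if h > hot_cut:
            types.append("traffic" if rng.random() < 0.7 else "industrial")
        elif p > pop_terciles[1]:
            types.append("urban")
        elif p > pop_terciles[0]:
            types.append("suburban")
        else:
            types.append("rural")
    # Guarantee both classes exist so class-based features are defined.
    if not any(t in HOTSPOT_TYPES for t in types):
        types[int(np.argmax(hot_level))] = "traffic"
    if all(t in HOTSPOT_TYPES for t in types):
        types[int(np.argmin(hot_level))] = "rural"

    networks = rng.choice(["A", "B", "C"], size=cfg.n_monitors, p=[0.55, 0.30, 0.15])
    sites = pd.DataFrame({
        "monitor_id": [f"M{i:04d}" for i in range(cfg.n_monitors)],
        "easting": ex,
        "northing": no,
        "network": networks,
        "monitor_type": types,
        "cell_id": cells,
    })
    return sites


def _draw_hours(rng, n_days: int) -> np.ndarray:
    """Hourly completeness mixture: most days full, some partial, some failing."""
    u = rng.random(n_days)
    hours = np.full(n_days, 24, dtype=int)
    partial = u > 0.87
    hours[partial] = rng.integers(18, 24, partial.sum())
    bad = u > 0.94
    hours[bad] = rng.integers(0, 18, bad.sum())
    return hours


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Generate the full synthetic study region.

    Deterministic: identical configuration (including seed) yields a
    bit-identical world.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    grid = GridSpec(x0=0.0, y0=0.0, cell_size=cfg.cell_size, nx=cfg.grid_nx, ny=cfg.grid_ny)
    ny, nx = grid.ny, grid.nx
    xs, ys = grid.centroids()
    xx = xs.reshape(ny, nx)
    yy = ys.reshape(ny, nx)

    dates = pd.DatetimeIndex(
        np.concatenate([
            pd.date_range(f"{y}-01-01", f"{y}-12-31", freq="D").to_numpy()
            for y in cfg.years
        ])
    )
    T = len(dates)
    doy = dates.dayofyear.to_numpy()

    statics, hotspot, pop = _make_statics(rng, grid, xx, yy)

    extent = max(nx, ny) * grid.cell_size
    regional = np.zeros((ny, nx))
    for _ in range(3):
        cx = rng.uniform(grid.x0, grid.x0 + nx * grid.cell_size)
        cy = rng.uniform(grid.y0, grid.y0 + ny * grid.cell_size)
        regional += rng.uniform(-0.25, 0.30) * _gaussian_bump(xx, yy, cx, cy, extent / 3)

    met = _make_meteorology(rng, grid, dates)
    season_t = _SEASON_AMP * np.cos(2 * np.pi * (doy - 10) / 365.25)
    weather = _weather_term(met)

    log_pm_smooth = (
        _MU_LOG
        + regional[None]
        + hotspot[None]
        + season_t[:, None, None]
        + weather
    )
    truth = np.exp(log_pm_smooth + rng.normal(0.0, cfg.sigma_resid, (T, ny, nx)))

    # ---- coarse modelled AOD --------------------------------------------
    # Column AOD tracks the regional aerosol burden (the smooth component
    # of the field scaled by mixing depth), not cell-day surface noise.
    aod55_true = _AOD_SCALE * np.exp(log_pm_smooth) * (met["blh_12"] / 1000.0)
    aod_true = {wl: WAVELENGTH_FACTORS[wl] * aod55_true for wl in AOD_WAVELENGTHS}

    fac = max(2, min(cfg.coarse_factor, nx // 2, ny // 2))
    cyn, cxn = int(np.ceil(ny / fac)), int(np.ceil(nx / fac))
    coarse_grid = GridSpec(x0=grid.x0, y0=grid.y0, cell_size=grid.cell_size * fac, nx=cxn, ny=cyn)

    def block_mean(a2d):
        pad_y, pad_x = cyn * fac - ny, cxn * fac - nx
        p = np.pad(a2d, ((0, pad_y), (0, pad_x)), mode="edge")
        return p.reshape(cyn, fac, cxn, fac).mean(axis=(1, 3))

    diurnal = 1.0 + 0.12 * np.sin(2 * np.pi * (np.asarray(CAMS_HOURS) - 9.0) / 24.0)
    cams_bias = {
        wl: 0.03 * WAVELENGTH_FACTORS[wl] * _smooth_field(rng, cyn, cxn, max(cyn, cxn) / 4)
        for wl in AOD_WAVELENGTHS
    }
    cams = np.empty((T, len(AOD_WAVELENGTHS), len(CAMS_HOURS), cyn, cxn))
    for wi, wl in enumerate(AOD_WAVELENGTHS):
        coarse_true = np.stack([block_mean(aod_true[wl][t]) for t in range(T)])
        for hi in range(len(CAMS_HOURS)):
            cams[:, wi, hi] = np.clip(coarse_true * diurnal[hi] + cams_bias[wl][None], 1e-4, None)

    # ---- satellite AOD scenes -------------------------------------------
    # Shared daily cloud field (clouds persist across the two overpasses);
    # the per-day masked fraction is set by thresholding the field at the
    # quantile of a seasonally modulated target, which calibrates realized
    # missingness to aod_missing_target.
    amp = min(0.04, 0.99 - cfg.aod_missing_target, cfg.aod_missing_target - 0.505)
    p_t = np.clip(
        cfg.aod_missing_target + amp * np.cos(2 * np.pi * (doy - 20) / 365.25),
        0.5,
        0.995,
    )
    cloud_mask = np.empty((T, ny, nx), dtype=bool)
    for t in range(T):
        c = ndimage.gaussian_filter(rng.standard_normal((ny, nx)), 4.0, mode="nearest")
        cloud_mask[t] = c < np.quantile(c, p_t[t])

    qa_best = rng.random((T, 2, ny, nx)) < 0.95
    uncertainty = np.abs(rng.normal(0.025, 0.012, (T, 2, ny, nx)))
    scene_noise = rng.normal(0.0, cfg.sigma_aod, (T, 2, ny, nx))

    if cfg.identity_aod:
        # Satellite value = modelled AOD at 12:00 linked from the coarse
        # pixel containing the cell: Stage-2's predictors then contain the
        # target exactly (noise-free recovery world).
        h12 = CAMS_HOURS.index(12)
        cell_x, cell_y = grid.centroids()
        coarse_of_cell = coarse_grid.point_to_cell(cell_x, cell_y)
        scene_values = {}
        for wl in SATELLITE_WAVELENGTHS:
            wi = AOD_WAVELENGTHS.index(wl)
            per_cell = cams[:, wi, h12].reshape(T, -1)[:, coarse_of_cell].reshape(T, ny, nx)
            scene_values[wl] = np.repeat(per_cell[:, None], 2, axis=1)
        uncertainty = np.full((T, 2, ny, nx), 0.01)
        qa_best = np.ones((T, 2, ny, nx), dtype=bool)
    else:
        scene_values = {
            wl: np.clip(aod_true[wl][:, None] + scene_noise, 1e-4, None)
            for wl in SATELLITE_WAVELENGTHS
        }
    for wl in SATELLITE_WAVELENGTHS:
        scene_values[wl] = np.where(cloud_mask[:, None], np.nan, scene_values[wl])

    # ---- model PM2.5 surface --------------------------------------------
    log_bias = _smooth_field(rng, ny, nx, extent / 6) * cfg.sigma_ctm
    smoothed = np.stack([
        ndimage.uniform_filter(truth[t], size=5, mode="nearest") for t in range(T)
    ])
    ctm = smoothed * np.exp(log_bias)[None]

    # ---- NDVI -------------------------------------------------------------
    months = pd.period_range(dates[0], dates[-1], freq="M")
    urban_share = statics[list(LAND_COVER_CLASSES[:3])].sum(axis=1).to_numpy().reshape(ny, nx)
    green_base = 0.55 * (1.0 - urban_share) + 0.05 * _smooth_field(rng, ny, nx, extent / 8)
    ndvi = np.clip(
        green_base[None]
        + 0.18 * np.cos(2 * np.pi * (months.month.to_numpy() - 7.5) / 12.0)[:, None, None],
        -1.0,
        1.0,
    )

    # ---- monitors ----------------------------------------------------------
    sites = _place_monitors(rng, cfg, grid, hotspot, pop)
    n_pm25 = max(2, int(round(cfg.frac_pm25_monitors * cfg.n_monitors)))
    pm25_ids = set(rng.choice(sites["monitor_id"], size=min(n_pm25, len(sites)), replace=False))

    rows = []
    date_year = dates.year.to_numpy()
    row_i, col_i = grid.cell_to_rowcol(sites["cell_id"].to_numpy())
    for k, site in sites.iterrows():
        tr = truth[:, row_i[k], col_i[k]]
        obs25 = tr * np.exp(rng.normal(0.0, cfg.sigma_obs, T))
        ratio = np.clip(rng.normal(0.6, cfg.sigma_pm10_ratio, T), 0.3, 0.95)
        obs10 = obs25 / ratio
        h10 = np.concatenate([
            _draw_hours(rng, (date_year == y).sum())
            if rng.random() > 0.06 else rng.integers(0, 18, (date_year == y).sum())
            for y in cfg.years
        ])
        h25 = np.concatenate([
            _draw_hours(rng, (date_year == y).sum())
            if rng.random() > 0.06 else rng.integers(0, 18, (date_year == y).sum())
            for y in cfg.years
        ])
        measures_pm25 = site["monitor_id"] in pm25_ids
        if not measures_pm25:
            h25 = np.zeros(T, dtype=int)
        rows.append(pd.DataFrame({
            "monitor_id": site["monitor_id"],
            "date": dates,
            "pm25": np.where(measures_pm25, obs25, np.nan),
            "pm10": obs10,
            "hours_pm25": h25,
            "hours_pm10": h10,
        }))
    records = pd.concat(rows, ignore_index=True)

    # Optional co-located duplicate monitors under a non-preferred network,
    # so the deduplication rule has something to find in pipeline runs.
    for d in range(cfg.n_duplicate_pairs):
        src = sites[sites["network"] == "A"]
        if src.empty:
            break
        orig = src.iloc[d % len(src)]
        dup_id = f"D{d:04d}"
        dup = orig.copy()
        dup["monitor_id"] = dup_id
        dup["network"] = "B"
        dup["easting"] = orig["easting"] + 0.02
        sites = pd.concat([sites, dup.to_frame().T], ignore_index=True)
        dup_rec = records[records["monitor_id"] == orig["monitor_id"]].copy()
        dup_rec["monitor_id"] = dup_id
        records = pd.concat([records, dup_rec], ignore_index=True)
    sites = sites.astype({"easting": float, "northing": float, "cell_id": int})

    return SyntheticWorld(
        config=cfg,
        grid=grid,
        dates=dates,
        truth_pm25=truth,
        sites=sites,
        records=records,
        aod_scene_values=scene_values,
        aod_scene_qa_best=qa_best,
        aod_scene_uncertainty=uncertainty,
        aod_true=aod_true,
        cams=cams,
        coarse_grid=coarse_grid,
        ctm_pm25=ctm,
        met=met,
        ndvi=ndvi,
        months=months,
        statics=statics,
    )


def truth_at(world: SyntheticWorld, cell_id: int, date) -> float:
    """Latent truth PM2.5 (ug/m3) at one cell and day, for recovery tests."""
    if not (0 <= cell_id < world.grid.n_cells):
        raise ValueError(f"cell_id {cell_id} outside the grid")
    t = world.day_index(date)
    row, col = world.grid.cell_to_rowcol(cell_id)
    return float(world.truth_pm25[t, row, col])


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------

def _field_dataset(world: SyntheticWorld) -> "object":
    import xarray as xr

    coords = {
        "time": world.dates,
        "y": np.unique(world.grid.centroids()[1]),
        "x": np.unique(world.grid.centroids()[0]),
    }
    data = {"truth_pm25": (("time", "y", "x"), world.truth_pm25),
            "ctm_pm25": (("time", "y", "x"), world.ctm_pm25),
            "aod_055_true": (("time", "y", "x"), world.aod_true[0.55])}
    for name, arr in world.met.items():
        data[name] = (("time", "y", "x"), arr)
    ds = xr.Dataset(data, coords=coords)
    ds["truth_pm25"].attrs["units"] = "ug m-3"
    ds["ctm_pm25"].attrs["units"] = "ug m-3"
    return ds


def export_world(world: SyntheticWorld, directory) -> dict:
    """Write the world to CSV (tables) and NetCDF (fields).

    Returns a dict of the paths written. ``import_world`` on the same
    directory round-trips all values to better than 1e-6.
    """
    import xarray as xr

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}

    sites = world.sites.copy()
    paths["sites"] = directory / "monitor_sites.csv"
    sites.to_csv(paths["sites"], index=False)

    rec = world.records.copy()
    rec["date"] = pd.to_datetime(rec["date"]).dt.strftime("%Y-%m-%d")
    paths["records"] = directory / "monitor_records.csv"
    rec.to_csv(paths["records"], index=False)

    paths["statics"] = directory / "static_predictors.csv"
    world.statics.to_csv(paths["statics"], index=False)

    paths["fields"] = directory / "fields.nc"
    _field_dataset(world).to_netcdf(paths["fields"], engine="scipy")

    scene_ds = xr.Dataset(
        {
            **{
                f"aod_{int(round(wl * 100)):03d}": (
                    ("time", "overpass", "y", "x"), world.aod_scene_values[wl])
                for wl in SATELLITE_WAVELENGTHS
            },
            "uncertainty": (("time", "overpass", "y", "x"), world.aod_scene_uncertainty),
            "qa_best": (("time", "overpass", "y", "x"),
                        world.aod_scene_qa_best.astype(np.int8)),
        },
        coords={"time": world.dates, "overpass": [0, 1]},
    )
    paths["aod_scenes"] = directory / "aod_scenes.nc"
    scene_ds.to_netcdf(paths["aod_scenes"], engine="scipy")

    cams_ds = xr.Dataset(
        {"cams_aod": (("time", "wavelength", "hour", "yc", "xc"), world.cams)},
        coords={"time": world.dates, "wavelength": list(AOD_WAVELENGTHS),
                "hour": list(CAMS_HOURS)},
    )
    paths["cams"] = directory / "cams_aod.nc"
    cams_ds.to_netcdf(paths["cams"], engine="scipy")

    ndvi_ds = xr.Dataset(
        {"ndvi": (("month", "y", "x"), world.ndvi)},
        coords={"month": world.months.to_timestamp()},
    )
    paths["ndvi"] = directory / "ndvi.nc"
    ndvi_ds.to_netcdf(paths["ndvi"], engine="scipy")

    meta = {
        "config": dataclasses.asdict(world.config),
        "grid": dataclasses.asdict(world.grid),
        "coarse_grid": dataclasses.asdict(world.coarse_grid),
    }
    paths["meta"] = directory / "world.json"
    paths["meta"].write_text(json.dumps(meta, indent=1))
    return paths


def import_world(directory) -> SyntheticWorld:
    """Rebuild a :class:`SyntheticWorld` from :func:`export_world` output."""
    import xarray as xr

    directory = Path(directory)
    meta = json.loads((directory / "world.json").read_text())
    cfg = WorldConfig(**{**meta["config"], "years": tuple(meta["config"]["years"])})
    grid = GridSpec(**meta["grid"])
    coarse = GridSpec(**meta["coarse_grid"])

    sites = pd.read_csv(directory / "monitor_sites.csv")
    records = pd.read_csv(directory / "monitor_records.csv", parse_dates=["date"])

    with xr.open_dataset(directory / "fields.nc", engine="scipy") as ds:
        ds = ds.load()
    dates = pd.DatetimeIndex(ds["time"].values)
    met = {name: ds[name].values for name in MET_FIELDS}

    with xr.open_dataset(directory / "aod_scenes.nc", engine="scipy") as sc:
        sc = sc.load()
    scene_values = {
        wl: sc[f"aod_{int(round(wl * 100)):03d}"].values
        for wl in SATELLITE_WAVELENGTHS
    }

    with xr.open_dataset(directory / "cams_aod.nc", engine="scipy") as cd:
        cams = cd["cams_aod"].values.copy()
    with xr.open_dataset(directory / "ndvi.nc", engine="scipy") as nd:
        ndvi = nd["ndvi"].values.copy()
        months = pd.DatetimeIndex(nd["month"].values).to_period("M")

    aod55 = ds["aod_055_true"].values
    aod_true = {
        wl: (WAVELENGTH_FACTORS[wl] / WAVELENGTH_FACTORS[0.55]) * aod55
        for wl in AOD_WAVELENGTHS
    }

    return SyntheticWorld(
        config=cfg,
        grid=grid,
        dates=dates,
        truth_pm25=ds["truth_pm25"].values,
        sites=sites,
        records=records,
        aod_scene_values=scene_values,
        aod_scene_qa_best=sc["qa_best"].values.astype(bool),
        aod_scene_uncertainty=sc["uncertainty"].values,
        aod_true=aod_true,
        cams=cams,
        coarse_grid=coarse,
        ctm_pm25=ds["ctm_pm25"].values,
        met=met,
        ndvi=ndvi,
        months=months,
        statics=pd.read_csv(directory / "static_predictors.csv"),
    )


def true_aod_fields(world: SyntheticWorld) -> dict:
    """Complete (gap-free) daily AOD fields taken from the generator truth.

    Useful to exercise the main prediction model in isolation from the
    gap-filling stage: the returned fields have no missing cells and
    provenance marked observed.
    """
    from .preprocess import DailyAODField, PROVENANCE_OBSERVED

    out = {}
    for wl in SATELLITE_WAVELENGTHS:
        vals = world.aod_true[wl].copy()
        out[wl] = DailyAODField(
            wavelength=wl,
            dates=world.dates,
            values=vals,
            provenance=np.full(vals.shape, PROVENANCE_OBSERVED, dtype=np.uint8),
        )
    return out
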