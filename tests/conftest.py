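import numpy as np
import pandas as pd
import pytest

from pmgrid.pipeline import PipelineConfig, run_pipeline
from pmgrid.stages import LearnerSpec
from pmgrid.synthetic import WorldConfig, generate_world


SMALL_CONFIG = WorldConfig(
    grid_nx=16, grid_ny=16, n_monitors=24, years=(2016,), seed=3
)


@pytest.fixture(scope="session")
def small_world():
    """A 16x16, 24-monitor, one-year world shared across unit tests."""
    return generate_world(SMALL_CONFIG)


@pytest.fixture(scope="session")
def mini_result():
    """A complete (small-forest) pipeline run on the small world."""
    cfg = PipelineConfig(
        world=SMALL_CONFIG,
        stage1=LearnerSpec(30, 4, seed=5),
        stage2=LearnerSpec(20, 20, seed=6),
        stage3=LearnerSpec(30, 20, seed=7),
        cv_k=5,
        cv_seed=9,
        stage4_day_stride=45,
    )
    return run_pipeline(cfg)


def make_sites(coords, networks=None, types=None):
    """Small hand-built site table: coords = [(easting, northing), ...]."""
    n = len(coords)
    return pd.DataFrame({
        "monitor_id": [f"S{i}" for i in range(n)],
        "easting": [c[0] for c in coords],
        "northing": [c[1] for c in coords],
        "network": networks or ["A"] * n,
        "monitor_type": types or ["urban"] * n,
    })


def make_records(series, start="2016-01-01", hours=24):
    """Records from {monitor_id: [pm25 values]} with full completeness."""
    rows = []
    for mid, values in series.items():
        dates = pd.date_range(start, periods=len(values), freq="D")
        rows.append(pd.DataFrame({
            "monitor_id": mid,
            "date": dates,
            "pm25": np.asarray(values, float),
            "pm10": np.asarray(values, float) / 0.6,
            "hours_pm25": hours,
            "hours_pm10": hours,
        }))
    return pd.concat(rows, ignore_index=True)
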