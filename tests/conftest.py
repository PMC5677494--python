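"""Shared fixtures: tiny synthetic survey file sets and a small fitted model.

Everything is generated at test time from seeds; the heavy fixtures are
session-scoped so the MCMC cost is paid once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from wfdisp import inference, synthetic
from wfdisp.cli import RunConfig, build_segments
from wfdisp.utm import utm_to_lonlat

TINY = dict(
    n_transects=4,
    transect_length_m=3_000.0,
    spacing_m=2_000.0,
    surveys_per_phase=2,
    footprint_half_m=700.0,
    shared_surface=True,
    sigma_survey=0.1,
    sigma_transect=0.1,
    seed=7,
)


def track_from_utm(points_m, t0=0.0, dt=30.0, survey="S01", transect="T01"):
    """Build a track DataFrame from UTM points visited at fixed intervals."""
    pts = np.asarray(points_m, dtype=float)
    lon, lat = utm_to_lonlat(pts[:, 0], pts[:, 1])
    ts = pd.to_datetime(t0 + np.arange(len(pts)) * dt, unit="s", utc=True)
    df = pd.DataFrame(
        {
            "survey_id": survey,
            "transect_id": transect,
            "timestamp_iso8601": [t.isoformat() for t in ts],
            "lon": lon,
            "lat": lat,
            "t": t0 + np.arange(len(pts)) * dt,
            "x": pts[:, 0],
            "y": pts[:, 1],
        }
    )
    return df


@pytest.fixture(scope="session")
def tiny_files(tmp_path_factory):
    out = tmp_path_factory.mktemp("tiny")
    cfg = synthetic.ScenarioConfig(**TINY)
    truth = synthetic.simulate(cfg, out)
    return out, cfg, truth


@pytest.fixture(scope="session")
def tiny_table(tiny_files):
    out, cfg, truth = tiny_files
    rc = RunConfig(
        track=str(out / "track.csv"),
        sightings=str(out / "sightings.csv"),
        seastate=str(out / "seastate.csv"),
        phases=str(out / "phases.csv"),
        footprint=str(out / "footprint.geojson"),
        species="guillemot",
    )
    return build_segments(rc)


@pytest.fixture(scope="session")
def tiny_fit(tiny_table):
    spec = inference.ModelSpec(
        family="NB", knots=8, chains=2, warmup=200, draws=250, seed=3
    )
    post, diag = inference.fit(tiny_table, spec)
    return post, diag
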