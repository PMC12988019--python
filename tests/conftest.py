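"""Shared fixtures: synthetic track factories around the study geometry."""

from __future__ import annotations

import numpy as np
import pytest

from routemem.geo import EARTH_RADIUS_M, GeoPoint
from routemem.simulate import HOME_LOFT, STANTON_HARCOURT, SimConfig
from routemem.trackio import Trajectory

K = np.pi / 180.0 * EARTH_RADIUS_M  # metres per degree latitude


def enu_track(
    xy: np.ndarray,
    origin: GeoPoint = HOME_LOFT,
    times: np.ndarray | None = None,
    **ids,
) -> Trajectory:
    """Build a Trajectory from local east/north metre offsets around origin."""
    xy = np.asarray(xy, dtype=np.float64)
    lats = origin.lat + xy[:, 1] / K
    lons = origin.lon + xy[:, 0] / (K * np.cos(np.radians(origin.lat)))
    if times is None:
        times = np.arange(len(xy), dtype=np.float64)
    return Trajectory(times, lats, lons, **ids)


@pytest.fixture
def rng():
    return np.random.default_rng(20240501)


@pytest.fixture
def home():
    return HOME_LOFT


@pytest.fixture
def release_site():
    return STANTON_HARCOURT


@pytest.fixture
def track_factory():
    return enu_track


@pytest.fixture(scope="session")
def small_config():
    """A reduced experiment for smoke/unit tests (full design per pair)."""
    return SimConfig(n_pairs=4, seed=11)


@pytest.fixture(scope="session")
def small_experiment(small_config):
    from routemem.simulate import generate_experiment

    return generate_experiment(small_config)
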