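"""Shared fixtures: one small synthetic session reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from batflight import wingbeats as wbm
from batflight.synthetic import GeneratorConfig, generate_session


@pytest.fixture(scope="session")
def session_and_truth():
    """Default two-path session (6 flights each) with planted ground truth."""
    cfg = GeneratorConfig(seed=11, flights_per_path=6)
    return generate_session(cfg)


@pytest.fixture(scope="session")
def detected(session_and_truth):
    """Wingbeat table + phase detected from the shared session."""
    session, gt = session_and_truth
    table, theta = wbm.detect_wingbeats(session.t, session.accel[:, 2],
                                        session.sample_rate, gt.flights,
                                        pos=session.pos)
    table = table.merge(gt.flights[["flight_id", "path"]], on="flight_id")
    return table, theta


@pytest.fixture(scope="session")
def noiseless_session():
    """Same structure but with every noise source off (except period jitter)."""
    cfg = GeneratorConfig(seed=12, flights_per_path=4,
                          trajectory_noise_sd=0.0, position_noise_sd=0.0,
                          keypoint_noise_sd=0.0, accel_noise_sd=0.0)
    return generate_session(cfg)


def jittered_oscillation(seed=7, n_cycles=500, f0=8.0, jitter_s=0.003,
                         fs=120.0, noise=0.05):
    """Accelerometer-like trace with known per-cycle periods."""
    rng = np.random.default_rng(seed)
    periods = np.clip(rng.normal(1 / f0, jitter_s, n_cycles),
                      1 / f0 - 3 * jitter_s, 1 / f0 + 3 * jitter_s)
    bounds = np.concatenate([[0.0], np.cumsum(periods)])
    t = np.arange(0, bounds[-1], 1 / fs)
    theta = np.interp(t, bounds, 2 * np.pi * np.arange(len(bounds)))
    az = 1 + 2 * np.sin(theta) + rng.normal(0, noise, len(t))
    flights = pd.DataFrame([dict(flight_id=0, start=0.0,
                                 end=float(bounds[-1]))])
    return t, az, flights, periods, bounds
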