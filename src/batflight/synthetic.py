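"""Synthetic flying-bat session generator with planted ground truth.

Emulates the statistical structure the downstream analyses assume: bats fly
reproducible 3D paths at ~4–5 m/s while beating their wings at ~8 Hz
(~125 ms per cycle), wing keypoints oscillate in the body frame with
envelopes that couple to angular velocity around turns (with opposite-signed
left/right gains), a dorsoventral accelerometer carries the wingbeat rhythm,
and motor-cortical units fall into four regimes:

* ``tonic_phase_locked`` — fire throughout flight with von Mises phase
  concentration ``kappa`` around a preferred wingbeat phase;
* ``kinematic_glm`` — per-cycle Poisson counts driven by a log-linear model
  of per-cycle kinematic features (planted weight vector);
* ``group_selective`` — emit a few millisecond-jittered spikes at a fixed
  phase, only on specific wingbeat groups (ordinal cycles), silent elsewhere;
* ``unmodulated`` — homogeneous Poisson.

A shared low-rank latent process (squared-exponential Gaussian processes)
can additionally modulate the log-rates of the tonic/unmodulated units.
Every planted parameter is returned in :class:`GroundTruth` so recovery can
be scored by the analysis stages.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import i0
from scipy.ndimage import gaussian_filter1d

from .core import GRAVITY, SessionData, smooth_series, spawn_rng

# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

KEYPOINT_NAMES = [
    "body", "head", "tail", "spine",
    "shoulder_L", "shoulder_R", "elbow_L", "elbow_R",
    "wrist_L", "wrist_R", "wingtip_L", "wingtip_R",
    "digit2_L", "digit2_R", "digit3_L", "digit3_R",
    "knee_L", "knee_R", "foot_L", "foot_R",
]

# resting body-frame positions (m): x forward, y left, z up
_KP_BASE = {
    # head/tail share z and shoulders are mirror-symmetric so the body
    # axes reconstructed from them coincide with the generative frame
    "body": (0.0, 0.0, 0.0), "head": (0.08, 0.0, 0.02),
    "tail": (-0.08, 0.0, 0.02), "spine": (0.0, 0.0, 0.01),
    "shoulder_L": (0.03, 0.04, 0.01), "shoulder_R": (0.03, -0.04, 0.01),
    "elbow_L": (0.0, 0.10, 0.0), "elbow_R": (0.0, -0.10, 0.0),
    "wrist_L": (0.02, 0.18, 0.0), "wrist_R": (0.02, -0.18, 0.0),
    "wingtip_L": (0.0, 0.30, 0.0), "wingtip_R": (0.0, -0.30, 0.0),
    "digit2_L": (0.04, 0.24, 0.0), "digit2_R": (0.04, -0.24, 0.0),
    "digit3_L": (-0.02, 0.26, 0.0), "digit3_R": (-0.02, -0.26, 0.0),
    "knee_L": (-0.06, 0.03, -0.01), "knee_R": (-0.06, -0.03, -0.01),
    "foot_L": (-0.09, 0.03, -0.02), "foot_R": (-0.09, -0.03, -0.02),
}

# dorsoventral oscillation amplitude (m) per keypoint; distal points flap more
_KP_AMP = {
    "body": 0.0, "head": 0.0, "tail": 0.0, "spine": 0.0,
    "shoulder_L": 0.0, "shoulder_R": 0.0, "elbow_L": 0.04, "elbow_R": 0.04,
    "wrist_L": 0.08, "wrist_R": 0.08, "wingtip_L": 0.13, "wingtip_R": 0.13,
    "digit2_L": 0.11, "digit2_R": 0.11, "digit3_L": 0.12, "digit3_R": 0.12,
    "knee_L": 0.01, "knee_R": 0.01, "foot_L": 0.01, "foot_R": 0.01,
}

FEATURE_NAMES = [
    "speed", "g_force", "angular_velocity", "flight_path_angle",
    "vx", "vy", "vz", "ax", "ay", "az", "curvature",
    "env_upper_wrist_L", "env_upper_wrist_R",
    "env_upper_wingtip_L", "env_upper_wingtip_R",
    "asym_wrist", "period_ms",
]


@dataclass
class UnitSpec:
    """Parameters for one synthetic unit."""

    unit_class: str                       # tonic_phase_locked | kinematic_glm
    #                                     # | group_selective | unmodulated
    baseline_rate: float = 5.0            # Hz, mean rate during flight
    kappa: float = 0.0                    # von Mises concentration
    preferred_phase: float = 0.0          # radians
    glm_weights: Optional[np.ndarray] = None   # over FEATURE_NAMES
    active_groups: tuple[int, ...] = ()   # ordinal wingbeat groups
    jitter_ms: float = 2.0                # group-selective spike-time jitter
    spikes_per_event: int = 2

    def __post_init__(self):
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.jitter_ms <= 0:
            raise ValueError("jitter sd must be > 0")


@dataclass
class LatentSpec:
    """Shared low-rank latent structure added to unit log-rates."""

    n_factors: int = 3
    timescale_ms: tuple[float, ...] = (150.0, 300.0, 600.0)
    loading_scale: float = 0.2


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_paths: int = 2
    flights_per_path: int = 10
    sample_rate_hz: float = 120.0
    wingbeat_hz: float = 8.0
    period_jitter_ms: float = 3.0
    flight_speed: float = 4.5             # m/s
    keypoint_count: int = 20
    envelope_turn_gain: float = 0.5       # envelope/asymmetry coupling to turn
    trajectory_noise_sd: float = 0.04     # m, smooth per-flight perturbation
    position_noise_sd: float = 0.002      # m, white measurement noise
    accel_noise_sd: float = 0.05          # g
    accel_wingbeat_amp: float = 2.0       # g, dorsoventral oscillation
    keypoint_noise_sd: float = 0.002      # m
    rest_duration_s: float = 2.0          # perch rest between flights
    path_templates: Optional[Sequence[str]] = None
    units: Optional[list[UnitSpec]] = None
    latent: Optional[LatentSpec] = field(default_factory=LatentSpec)

    def __post_init__(self):
        if self.n_paths < 1 or self.flights_per_path < 1:
            raise ValueError("counts must be >= 1")
        if self.sample_rate_hz < 2 * self.wingbeat_hz:
            raise ValueError("sample rate must be >= 2x wingbeat rate")


@dataclass
class GroundTruth:
    """Everything planted by the generator, for recovery scoring."""

    flights: pd.DataFrame          # flight_id, start, end, path, template, split_time
    theta: np.ndarray              # (n,) true phase in [0, 2pi), NaN at rest
    wingbeats: pd.DataFrame        # flight_id, onset, offset, ordinal
    units: list[UnitSpec]
    norm_angvel: np.ndarray        # (n,) signed normalized angular velocity
    envelope_gain: float
    glm_features: Optional[pd.DataFrame]   # per-cycle z-scored features
    latent_factors: Optional[np.ndarray]   # (n, q)
    latent_loadings: Optional[np.ndarray]  # (n_units, q)
    config: GeneratorConfig


# --------------------------------------------------------------------------
# flight path templates
# --------------------------------------------------------------------------

def _dense(points: np.ndarray, n: int = 2000) -> np.ndarray:
    """Resample a waypoint polyline to uniform arc length."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    grid = np.linspace(0, s[-1], n)
    return np.column_stack([np.interp(grid, s, points[:, k]) for k in range(3)])


def _smooth_waypoints(way: np.ndarray) -> np.ndarray:
    dense = _dense(np.asarray(way, float), 400)
    dense = gaussian_filter1d(dense, 12, axis=0, mode="nearest")
    return _dense(dense, 2000)


def _arc(cx, cy, r, a0, a1, z, n=40):
    a = np.linspace(a0, a1, n)
    return np.column_stack([cx + r * np.cos(a), cy + r * np.sin(a),
                            np.full(n, z)])


def _template_points(name: str) -> tuple[np.ndarray, float]:
    """Return (dense arc-length-uniform points, shared-prefix arclength)."""
    if name == "straight":
        way = np.array([[0, 0, 1.5], [8, 0, 1.5]])
        split = np.nan
    elif name == "straight_reverse":
        way = np.array([[8, 0, 1.5], [0, 0, 1.5]])
        split = np.nan
    elif name == "climb":
        way = np.array([[0, 0, 1.0], [3.5, 0, 1.2], [7, 0, 2.5]])
        split = np.nan
    elif name == "uturn":
        lead = np.array([[0, 0, 1.5], [3, 0, 1.5]])
        arc = _arc(3, 1.2, 1.2, -np.pi / 2, np.pi / 2, 1.5)
        back = np.array([[3, 2.4, 1.5], [0, 2.4, 1.5]])
        way = np.vstack([lead, arc[1:], back[1:]])
        split = np.nan
    elif name in ("fork_turn", "fork_climb"):
        prefix = np.array([[0, 0, 1.2], [1.8, 0, 1.2], [3.5, 0, 1.2]])
        if name == "fork_turn":
            arc = _arc(3.5, 1.5, 1.5, -np.pi / 2, np.pi / 2, 1.2, 60)
            tail = np.array([[3.5, 3.0, 1.2], [1.0, 3.0, 1.3]])
            way = np.vstack([prefix, arc[1:], tail[1:]])
        else:
            way = np.vstack([prefix,
                             np.array([[5.5, 0, 1.6], [7.5, 0.3, 2.6]])])
        split = 3.5
    else:
        raise ValueError(f"unknown template '{name}'")
    pts = _smooth_waypoints(way)
    return pts, split


_DEFAULT_TEMPLATE_ORDER = ["fork_turn", "fork_climb", "uturn", "straight",
                           "climb", "straight_reverse"]


def default_templates(n_paths: int) -> list[str]:
    if n_paths > len(_DEFAULT_TEMPLATE_ORDER):
        raise ValueError("at most 6 built-in templates")
    return _DEFAULT_TEMPLATE_ORDER[:n_paths]


# --------------------------------------------------------------------------
# default unit population
# --------------------------------------------------------------------------

def default_units(rng: np.random.Generator,
                  n_tonic: int = 12, n_glm: int = 10,
                  n_group: int = 10, n_unmod: int = 8,
                  n_groups_hint: int = 18) -> list[UnitSpec]:
    units: list[UnitSpec] = []
    for i in range(n_tonic):
        units.append(UnitSpec(
            "tonic_phase_locked",
            baseline_rate=float(rng.uniform(6, 12)),
            kappa=float(np.exp(rng.uniform(np.log(2), np.log(6)))),
            preferred_phase=float(rng.uniform(0, 2 * np.pi)),
        ))
    for i in range(n_glm):
        w = np.zeros(len(FEATURE_NAMES))
        idx = rng.choice(len(FEATURE_NAMES), size=3, replace=False)
        w[idx] = rng.uniform(0.4, 0.8, 3) * rng.choice([-1, 1], 3)
        units.append(UnitSpec("kinematic_glm",
                              baseline_rate=float(rng.uniform(3, 8)),
                              glm_weights=w))
    for i in range(n_group):
        k = int(rng.integers(1, 4))
        groups = tuple(sorted(rng.choice(n_groups_hint, size=k,
                                         replace=False).tolist()))
        units.append(UnitSpec("group_selective", baseline_rate=0.0,
                              preferred_phase=float(rng.uniform(0, 2 * np.pi)),
                              active_groups=groups, jitter_ms=2.0,
                              spikes_per_event=2))
    for i in range(n_unmod):
        units.append(UnitSpec("unmodulated",
                              baseline_rate=float(rng.uniform(2, 5))))
    return units


# --------------------------------------------------------------------------
# trajectories
# --------------------------------------------------------------------------

def generate_trajectories(cfg: GeneratorConfig):
    """Assemble the session timeline: rests, repositioning walks, flights.

    Returns ``(t, pos, flights)`` where flights is a DataFrame with columns
    flight_id, start, end, path, template, split_time (session time at which
    shared-prefix templates diverge, NaN otherwise).
    """
    rng = spawn_rng(cfg.seed, "trajectories")
    fs = cfg.sample_rate_hz
    dt = 1.0 / fs
    templates = list(cfg.path_templates or default_templates(cfg.n_paths))
    if len(templates) != cfg.n_paths:
        raise ValueError("need one template per path")
    tmpl_pts = {}
    for name in templates:
        pts, split = _template_points(name)
        L = np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()
        if L / cfg.flight_speed < 2 * (2.0 / cfg.wingbeat_hz):
            raise ValueError(f"template '{name}' shorter than 2 wingbeat periods")
        tmpl_pts[name] = (pts, split, L)

    # interleave paths so flights of a path are spread through the session
    order = [templates[i % cfg.n_paths]
             for i in range(cfg.n_paths * cfg.flights_per_path)]

    chunks: list[np.ndarray] = []
    rows = []
    t_cursor = 0.0
    cur_pos = tmpl_pts[order[0]][0][0]

    def hold(duration, point):
        nonlocal t_cursor
        n = max(1, int(round(duration * fs)))
        chunks.append(np.tile(point, (n, 1)))
        t_cursor += n * dt

    hold(cfg.rest_duration_s / 2, cur_pos)
    ramp_t = 0.3  # s, takeoff/landing speed ramp

    for fid, name in enumerate(order):
        pts, split_arc, L = tmpl_pts[name]
        start_pt = pts[0]
        if np.linalg.norm(cur_pos - start_pt) > 1e-6:
            # slow repositioning walk, below any flight speed threshold
            d = np.linalg.norm(cur_pos - start_pt)
            walk_T = d / 0.5
            n = int(round(walk_T * fs))
            frac = np.linspace(0, 1, n, endpoint=False)[:, None]
            chunks.append(cur_pos + frac * (start_pt - cur_pos))
            t_cursor += n * dt
            cur_pos = start_pt
            hold(cfg.rest_duration_s, cur_pos)

        # trapezoidal speed profile along the arc
        v = cfg.flight_speed
        n_guess = int(np.ceil((L / v + ramp_t) * fs)) + 10
        tt = dt * np.arange(n_guess)
        speed = np.minimum(v, np.minimum(tt / ramp_t * v,
                                         np.inf))
        s = np.cumsum(speed) * dt
        # apply landing ramp symmetrically: mirror the takeoff profile
        n_fl = int(np.searchsorted(s, L - (v * ramp_t / 2)))
        n_land = int(round(ramp_t * fs))
        land_speed = v * (1 - np.arange(1, n_land + 1) / n_land)
        speed = np.concatenate([speed[:n_fl], land_speed])
        s = np.cumsum(speed) * dt
        s = s * (L / s[-1])
        grid = np.linspace(0, L, len(pts))
        traj = np.column_stack([np.interp(s, grid, pts[:, k])
                                for k in range(3)])
        n = len(traj)

        # smooth per-flight perturbation, tapered at the endpoints
        if cfg.trajectory_noise_sd > 0:
            noise = rng.standard_normal((n, 3))
            noise = gaussian_filter1d(noise, 0.3 * fs, axis=0, mode="nearest")
            sdn = noise.std(axis=0, keepdims=True)
            sdn[sdn == 0] = 1.0
            noise = noise / sdn * cfg.trajectory_noise_sd
            taper = np.minimum(1.0, np.minimum(
                np.arange(n) / (0.5 * fs), (n - 1 - np.arange(n)) / (0.5 * fs)))
            traj = traj + noise * taper[:, None]

        start = t_cursor
        chunks.append(traj)
        t_cursor += n * dt
        end = t_cursor
        split_time = np.nan
        if np.isfinite(split_arc):
            split_time = start + float(np.interp(split_arc, s, dt * np.arange(n)))
        rows.append(dict(flight_id=fid, start=start, end=end,
                         path=templates.index(name), template=name,
                         split_time=split_time))
        cur_pos = traj[-1]
        hold(cfg.rest_duration_s, cur_pos)

    pos = np.vstack(chunks)
    if cfg.position_noise_sd > 0:
        pos = pos + rng.normal(0, cfg.position_noise_sd, pos.shape)
    t = dt * np.arange(len(pos))
    flights = pd.DataFrame(rows)
    return t, pos, flights


# --------------------------------------------------------------------------
# wingbeat phase, keypoints, accelerometer
# --------------------------------------------------------------------------

def _signed_angular_velocity(pos, fs):
    v = np.gradient(smooth_series(pos, 0.05, fs, axis=0), 1.0 / fs, axis=0)
    psi = np.unwrap(np.arctan2(v[:, 1], v[:, 0]))
    return np.gradient(psi, 1.0 / fs)


def generate_wingbeat_streams(cfg: GeneratorConfig, t, pos, flights):
    """Plant the wingbeat phase, keypoint oscillations and accelerometer.

    Phase convention: theta = 0 at the upward zero-crossing of the
    band-limited dorsoventral acceleration (the accelerometer carries
    ``amp * sin(theta)`` on top of gravity).
    """
    rng = spawn_rng(cfg.seed, "wingbeats")
    fs = cfg.sample_rate_hz
    n = len(t)
    theta = np.full(n, np.nan)
    wb_rows = []
    T0 = 1.0 / cfg.wingbeat_hz
    jit = cfg.period_jitter_ms / 1000.0

    for fl in flights.itertuples():
        cursor = fl.start
        ordinal = 0
        while True:
            period = T0 + np.clip(rng.normal(0, jit), -3 * jit, 3 * jit) \
                if jit > 0 else T0
            if cursor + period > fl.end:
                break
            sel = (t >= cursor) & (t < cursor + period)
            theta[sel] = 2 * np.pi * (t[sel] - cursor) / period
            wb_rows.append(dict(flight_id=fl.flight_id, onset=cursor,
                                offset=cursor + period, ordinal=ordinal))
            cursor += period
            ordinal += 1
    wingbeats = pd.DataFrame(wb_rows)

    # signed angular velocity, normalized over flight samples
    omega = _signed_angular_velocity(pos, fs)
    in_flight = np.zeros(n, bool)
    for fl in flights.itertuples():
        in_flight |= (t >= fl.start) & (t < fl.end)
    omega = np.where(in_flight, omega, 0.0)
    scale = np.percentile(np.abs(omega[in_flight]), 95) if in_flight.any() else 1.0
    norm_angvel = omega / scale if scale > 0 else omega

    flapping = ~np.isnan(theta)
    sin_th = np.where(flapping, np.sin(np.nan_to_num(theta)), 0.0)

    # keypoints in the body frame
    names = KEYPOINT_NAMES[: cfg.keypoint_count]
    K = len(names)
    kp = np.zeros((n, K, 3))
    env_left = 1.0 + cfg.envelope_turn_gain * norm_angvel
    env_right = 1.0 - cfg.envelope_turn_gain * norm_angvel
    for k, name in enumerate(names):
        base = np.array(_KP_BASE[name])
        kp[:, k, :] = base
        amp = _KP_AMP[name]
        if amp > 0:
            env = env_left if name.endswith("_L") else env_right
            kp[:, k, 2] += amp * env * sin_th
    if cfg.keypoint_noise_sd > 0:
        kp = kp + rng.normal(0, cfg.keypoint_noise_sd, kp.shape)

    accel = rng.normal(0, cfg.accel_noise_sd, (n, 3))
    accel[:, 2] += 1.0 + cfg.accel_wingbeat_amp * sin_th

    return theta, wingbeats, kp, names, accel, norm_angvel


# --------------------------------------------------------------------------
# per-cycle kinematic features (generator-side truth)
# --------------------------------------------------------------------------

def _true_cycle_features(cfg, t, pos, flights, wingbeats, norm_angvel):
    fs = cfg.sample_rate_hz
    sm = smooth_series(pos, 0.025, fs, axis=0)
    v = np.gradient(sm, 1.0 / fs, axis=0)
    a = np.gradient(v, 1.0 / fs, axis=0)
    speed = np.linalg.norm(v, axis=1)
    g_force = np.linalg.norm(a, axis=1) / GRAVITY
    with np.errstate(invalid="ignore", divide="ignore"):
        fpa = np.arcsin(np.clip(v[:, 2] / np.where(speed > 0.1, speed, np.nan),
                                -1, 1))
        curv = np.abs(norm_angvel) / np.where(speed > 0.1, speed, np.nan)
    angv = np.abs(norm_angvel)
    env_L = 1.0 + cfg.envelope_turn_gain * norm_angvel
    env_R = 1.0 - cfg.envelope_turn_gain * norm_angvel

    rows = []
    for wb in wingbeats.itertuples():
        sel = (t >= wb.onset) & (t < wb.offset)
        if not sel.any():
            continue
        feat = dict(flight_id=wb.flight_id, ordinal=wb.ordinal,
                    speed=speed[sel].mean(), g_force=g_force[sel].mean(),
                    angular_velocity=angv[sel].mean(),
                    flight_path_angle=np.nanmean(fpa[sel]),
                    vx=v[sel, 0].mean(), vy=v[sel, 1].mean(),
                    vz=v[sel, 2].mean(), ax=a[sel, 0].mean(),
                    ay=a[sel, 1].mean(), az=a[sel, 2].mean(),
                    curvature=np.nanmean(curv[sel]),
                    env_upper_wrist_L=_KP_AMP["wrist_L"] * env_L[sel].mean(),
                    env_upper_wrist_R=_KP_AMP["wrist_R"] * env_R[sel].mean(),
                    env_upper_wingtip_L=_KP_AMP["wingtip_L"] * env_L[sel].mean(),
                    env_upper_wingtip_R=_KP_AMP["wingtip_R"] * env_R[sel].mean(),
                    asym_wrist=_KP_AMP["wrist_R"] * (env_R[sel].mean()
                                                     - env_L[sel].mean()),
                    period_ms=(wb.offset - wb.onset) * 1000.0)
        rows.append(feat)
    df = pd.DataFrame(rows)
    path_of = flights.set_index("flight_id")["path"]
    df["path"] = df["flight_id"].map(path_of)
    # z-score per path
    for col in FEATURE_NAMES:
        grp = df.groupby("path")[col]
        mu, sd = grp.transform("mean"), grp.transform("std").replace(0, 1.0)
        df[col] = ((df[col] - mu) / sd).fillna(0.0)
    return df


# --------------------------------------------------------------------------
# spikes
# --------------------------------------------------------------------------

def _sample_latents(cfg, t, flights, rng):
    spec = cfg.latent
    if spec is None or spec.n_factors == 0:
        return None
    fs = cfg.sample_rate_hz
    n = len(t)
    F = np.zeros((n, spec.n_factors))
    in_flight = np.zeros(n, bool)
    for fl in flights.itertuples():
        in_flight |= (t >= fl.start) & (t < fl.end)
    for q in range(spec.n_factors):
        tau = spec.timescale_ms[q % len(spec.timescale_ms)] / 1000.0
        w = rng.standard_normal(n)
        # Gaussian filter of white noise has squared-exponential covariance
        f = gaussian_filter1d(w, tau / np.sqrt(2) * fs, mode="nearest")
        sd = f.std()
        F[:, q] = f / (sd if sd > 0 else 1.0)
    F[~in_flight] = 0.0
    return F


def generate_spikes(cfg: GeneratorConfig, t, theta, flights, wingbeats,
                    features: pd.DataFrame, units: list[UnitSpec],
                    latents=None, loadings=None):
    """Draw spike trains for every unit given the planted drives."""
    rng = spawn_rng(cfg.seed, "spikes")
    fs = cfg.sample_rate_hz
    dt = 1.0 / fs
    n = len(t)
    in_flight = np.zeros(n, bool)
    for fl in flights.itertuples():
        in_flight |= (t >= fl.start) & (t < fl.end)
    feat_lookup = None
    if features is not None and len(features):
        feat_lookup = features.set_index(["flight_id", "ordinal"])

    spikes: dict[int, np.ndarray] = {}
    for uid, spec in enumerate(units):
        urng = spawn_rng(cfg.seed, f"unit{uid}")
        if spec.unit_class == "group_selective":
            out = []
            for wb in wingbeats.itertuples():
                if wb.ordinal in spec.active_groups:
                    period = wb.offset - wb.onset
                    t_ev = wb.onset + spec.preferred_phase / (2 * np.pi) * period
                    jit = urng.normal(0, spec.jitter_ms / 1000.0,
                                      spec.spikes_per_event)
                    out.extend(np.clip(t_ev + jit, wb.onset,
                                       np.nextafter(wb.offset, wb.onset)))
            spikes[uid] = np.sort(np.asarray(out))
            continue
        if spec.unit_class == "kinematic_glm":
            out = []
            for wb in wingbeats.itertuples():
                period = wb.offset - wb.onset
                try:
                    x = feat_lookup.loc[(wb.flight_id, wb.ordinal),
                                        FEATURE_NAMES].to_numpy(float)
                except KeyError:
                    x = np.zeros(len(FEATURE_NAMES))
                # drive clipped at +/-3.5 so rare extreme cycles stay
                # physiological (< ~35x baseline)
                drive = float(np.clip(spec.glm_weights @ x, -3.5, 3.5))
                lam = spec.baseline_rate * period * np.exp(drive)
                if lam > 1000 * period:
                    raise ValueError("rate overflow (> 1 kHz); reject spec")
                c = urng.poisson(lam)
                if c:
                    out.extend(np.sort(urng.uniform(wb.onset, wb.offset, c)))
            # low homogeneous rate outside flight
            rest_rate = 0.5
            lam_rest = np.where(in_flight, 0.0, rest_rate) * dt
            counts = urng.poisson(lam_rest)
            idx = np.nonzero(counts)[0]
            for i in idx:
                out.extend(t[i] + urng.uniform(0, dt, counts[i]))
            spikes[uid] = np.sort(np.asarray(out))
            continue

        # rate-based classes on the sample grid
        log_rate = np.full(n, np.log(max(spec.baseline_rate, 1e-12)))
        if spec.unit_class == "tonic_phase_locked":
            drive = np.zeros(n)
            ok = ~np.isnan(theta)
            drive[ok] = spec.kappa * np.cos(theta[ok] - spec.preferred_phase)
            log_rate = log_rate + drive - np.log(i0(spec.kappa))
            log_rate[~ok] = np.log(max(spec.baseline_rate, 1e-12))
        elif spec.unit_class != "unmodulated":
            raise ValueError(f"unknown unit class '{spec.unit_class}'")
        if latents is not None and loadings is not None \
                and np.any(loadings[uid] != 0):
            log_rate = log_rate + latents @ loadings[uid]
        rate = np.exp(log_rate)
        if np.any(rate > 1000):
            raise ValueError("rate overflow (> 1 kHz); reject spec")
        counts = urng.poisson(rate * dt)
        idx = np.nonzero(counts)[0]
        out = []
        for i in idx:
            out.extend(t[i] + urng.uniform(0, dt, counts[i]))
        spikes[uid] = np.sort(np.asarray(out))
    for uid in spikes:
        spikes[uid] = np.clip(spikes[uid], t[0], t[-1])
    return spikes


# --------------------------------------------------------------------------
# full session
# --------------------------------------------------------------------------

def generate_session(cfg: GeneratorConfig) -> tuple[SessionData, GroundTruth]:
    """Generate a complete synthetic session plus its ground truth."""
    t, pos, flights = generate_trajectories(cfg)
    theta, wingbeats, kp, kp_names, accel, norm_angvel = \
        generate_wingbeat_streams(cfg, t, pos, flights)
    features = _true_cycle_features(cfg, t, pos, flights, wingbeats,
                                    norm_angvel)
    rng = spawn_rng(cfg.seed, "units")
    n_groups = int(wingbeats.groupby("flight_id")["ordinal"].max().median()) + 1
    units = cfg.units if cfg.units is not None else \
        default_units(rng, n_groups_hint=max(2, n_groups))

    latents = _sample_latents(cfg, t, flights, spawn_rng(cfg.seed, "latents"))
    loadings = None
    if latents is not None:
        lrng = spawn_rng(cfg.seed, "loadings")
        loadings = np.zeros((len(units), latents.shape[1]))
        for uid, spec in enumerate(units):
            if spec.unit_class in ("tonic_phase_locked", "unmodulated"):
                loadings[uid] = lrng.normal(0, cfg.latent.loading_scale,
                                            latents.shape[1])

    spikes = generate_spikes(cfg, t, theta, flights, wingbeats, features,
                             units, latents, loadings)
    session = SessionData(
        t=t, pos=pos, accel=accel, spikes=spikes,
        sample_rate=cfg.sample_rate_hz, keypoints=kp,
        keypoint_names=kp_names, keypoint_frame="body",
        meta=dict(seed=cfg.seed, n_units=len(units),
                  sample_rate_hz=cfg.sample_rate_hz,
                  wingbeat_hz=cfg.wingbeat_hz),
    )
    gt = GroundTruth(flights=flights, theta=theta, wingbeats=wingbeats,
                     units=units, norm_angvel=norm_angvel,
                     envelope_gain=cfg.envelope_turn_gain,
                     glm_features=features, latent_factors=latents,
                     latent_loadings=loadings, config=cfg)
    return session, gt


# --------------------------------------------------------------------------
# focused low-rank population constructors (dimensionality recovery)
# --------------------------------------------------------------------------

def make_factor_population(n_units: int, k: int, n_groups: int, n_bins: int,
                           noise_sd: float, rng: np.random.Generator,
                           n_trials: int = 1):
    """Trial data whose group-mean matrix has rank ~k plus isotropic noise.

    Returns an array (n_trials, n_units, n_groups * n_bins).  Factor time
    courses are smooth per group; loadings are random orthonormal columns.
    """
    T = n_groups * n_bins
    F = rng.standard_normal((k, T))
    F = gaussian_filter1d(F, max(1.0, n_bins / 5), axis=1, mode="wrap")
    F = F / F.std(axis=1, keepdims=True)
    C = np.linalg.qr(rng.standard_normal((n_units, k)))[0]
    signal = C @ F
    trials = signal[None] + rng.normal(0, noise_sd,
                                       (n_trials, n_units, T))
    return trials, signal


def make_dpca_dataset(n_units: int, n_groups: int, n_bins: int,
                      specific_invariant_ratio: float,
                      noise_sd: float, rng: np.random.Generator,
                      n_trials: int = 8):
    """Tensor with planted condition-specific vs condition-invariant variance.

    The invariant part is a time-only signal shared by all groups; the
    specific part is an independent signal per group, scaled so that the
    variance ratio specific/invariant equals the requested value.
    Returns (trials[trial, unit, group, time], planted_ratio).
    """
    inv_t = gaussian_filter1d(rng.standard_normal(n_bins), n_bins / 10,
                              mode="wrap")
    inv_t = inv_t - inv_t.mean()   # pure time-varying (invariant) signal
    inv_t = inv_t / inv_t.std()
    a_inv = rng.standard_normal(n_units)
    X_inv = np.einsum("u,t->ut", a_inv, inv_t)[:, None, :].repeat(n_groups, 1)

    spec = gaussian_filter1d(rng.standard_normal((n_groups, n_bins)),
                             n_bins / 10, axis=1, mode="wrap")
    spec = spec - spec.mean(axis=0, keepdims=True)   # pure group-varying part
    spec = spec / spec.std()
    a_spec = rng.standard_normal(n_units)
    X_spec = np.einsum("u,gt->ugt", a_spec, spec)

    var_inv = np.var(X_inv)
    var_spec = np.var(X_spec)
    X_spec = X_spec * np.sqrt(specific_invariant_ratio * var_inv / var_spec)
    X = X_inv + X_spec
    trials = X[None] + rng.normal(0, noise_sd,
                                  (n_trials, n_units, n_groups, n_bins))
    return trials, float(np.sum(X_spec ** 2) / np.sum(X_inv ** 2))


def make_gpfa_dataset(n_units: int, k: int, n_trials: int, n_bins: int,
                      bin_ms: float, timescales_ms: Sequence[float],
                      loading_scale: float, noise_sd: float,
                      rng: np.random.Generator):
    """Gaussian observations driven by k shared GP factors.

    Returns (trials[trial, unit, bin], C, taus).
    """
    tgrid = bin_ms * np.arange(n_bins)
    C = rng.standard_normal((n_units, k)) * loading_scale
    trials = np.empty((n_trials, n_units, n_bins))
    Ls = []
    for q in range(k):
        tau = timescales_ms[q % len(timescales_ms)]
        K = np.exp(-0.5 * ((tgrid[:, None] - tgrid[None, :]) / tau) ** 2)
        Ls.append(np.linalg.cholesky(K + 1e-8 * np.eye(n_bins)))
    for tr in range(n_trials):
        X = np.stack([Ls[q] @ rng.standard_normal(n_bins) for q in range(k)])
        trials[tr] = C @ X + rng.normal(0, noise_sd, (n_units, n_bins))
    return trials, C, np.asarray(timescales_ms[:k], float)


def make_selective_barcodes(n_units: int, n_groups: int, n_flights: int,
                            rng: np.random.Generator,
                            groups_per_unit: tuple[int, int] = (1, 3),
                            flip_prob: float = 0.0):
    """Noise-free (or flipped-noise) group-selective barcode matrix.

    Each unit is active on a fixed random subset of wingbeat groups in
    every flight; ``flip_prob`` optionally flips entries.  Returns
    (barcodes[wingbeats, units], group_labels, flight_ids).
    """
    memberships = np.zeros((n_units, n_groups), int)
    for u in range(n_units):
        k = int(rng.integers(groups_per_unit[0], groups_per_unit[1] + 1))
        memberships[u, rng.choice(n_groups, k, replace=False)] = 1
    groups = np.tile(np.arange(n_groups), n_flights)
    flights = np.repeat(np.arange(n_flights), n_groups)
    B = memberships.T[groups % n_groups]
    if flip_prob > 0:
        flips = rng.random(B.shape) < flip_prob
        B = np.where(flips, 1 - B, B)
    return B.astype(float), groups, flights


def make_drifting_barcodes(n_units: int, n_groups: int, n_flights: int,
                           sigma: float, rng: np.random.Generator):
    """Barcodes whose recruited subset drifts smoothly across groups.

    Unit u is active on a cycle of ordinal o with probability
    exp(-(o - o_u)^2 / (2 sigma^2)) for a preferred ordinal o_u spread
    evenly over the path, so adjacent wingbeat groups recruit overlapping
    subsets and decoder errors should concentrate near the diagonal.
    """
    pref = np.linspace(0, n_groups - 1, n_units)
    groups = np.tile(np.arange(n_groups), n_flights)
    flights = np.repeat(np.arange(n_flights), n_groups)
    p = np.exp(-0.5 * ((groups[:, None] - pref[None, :]) / sigma) ** 2)
    B = (rng.random(p.shape) < p).astype(float)
    return B, groups, flights


# --------------------------------------------------------------------------
# on-disk round trip
# --------------------------------------------------------------------------

def write_session(session: SessionData, gt: Optional[GroundTruth],
                  out_dir: str) -> None:
    """Write the session directory (CSV tables + JSON metadata)."""
    os.makedirs(out_dir, exist_ok=True)
    fmt = "%.9g"
    pd.DataFrame(dict(t=session.t, x=session.pos[:, 0],
                      y=session.pos[:, 1], z=session.pos[:, 2])) \
        .to_csv(os.path.join(out_dir, "trajectory.csv"), index=False,
                float_format=fmt)
    pd.DataFrame(dict(t=session.t, ax=session.accel[:, 0],
                      ay=session.accel[:, 1], az=session.accel[:, 2])) \
        .to_csv(os.path.join(out_dir, "accel.csv"), index=False,
                float_format=fmt)
    if session.keypoints is not None:
        n, K, _ = session.keypoints.shape
        df = pd.DataFrame(dict(
            t=np.repeat(session.t, K),
            keypoint_id=np.tile(np.arange(K), n),
            x=session.keypoints[:, :, 0].ravel(),
            y=session.keypoints[:, :, 1].ravel(),
            z=session.keypoints[:, :, 2].ravel(),
        ))
        df.to_csv(os.path.join(out_dir, "keypoints.csv"), index=False,
                  float_format=fmt)
    rows = [(uid, st) for uid, st in sorted(session.spikes.items())]
    pd.DataFrame(dict(
        unit_id=np.concatenate([np.full(len(st), uid) for uid, st in rows])
        if rows else [],
        t=np.concatenate([st for _, st in rows]) if rows else [],
    )).to_csv(os.path.join(out_dir, "spikes.csv"), index=False,
              float_format=fmt)
    meta = dict(session.meta)
    meta.update(sample_rate_hz=session.sample_rate,
                keypoint_frame=session.keypoint_frame,
                keypoint_names=session.keypoint_names,
                n_units=session.n_units)
    with open(os.path.join(out_dir, "meta.json"), "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
    if gt is not None:
        write_ground_truth(gt, out_dir)


def write_ground_truth(gt: GroundTruth, out_dir: str) -> None:
    gdir = os.path.join(out_dir, "ground_truth")
    os.makedirs(gdir, exist_ok=True)
    gt.flights.to_csv(os.path.join(gdir, "flights.csv"), index=False)
    gt.wingbeats.to_csv(os.path.join(gdir, "wingbeats.csv"), index=False)
    if gt.glm_features is not None:
        gt.glm_features.to_csv(os.path.join(gdir, "glm_features.csv"),
                               index=False)
    np.savetxt(os.path.join(gdir, "theta.csv"), gt.theta, fmt="%.9g")
    np.savetxt(os.path.join(gdir, "norm_angvel.csv"), gt.norm_angvel,
               fmt="%.9g")
    units = []
    for spec in gt.units:
        d = asdict(spec)
        if d["glm_weights"] is not None:
            d["glm_weights"] = list(np.asarray(d["glm_weights"], float))
        d["active_groups"] = list(d["active_groups"])
        units.append(d)
    payload = dict(units=units, envelope_gain=gt.envelope_gain,
                   seed=gt.config.seed,
                   config=dict(n_paths=gt.config.n_paths,
                               flights_per_path=gt.config.flights_per_path,
                               wingbeat_hz=gt.config.wingbeat_hz,
                               period_jitter_ms=gt.config.period_jitter_ms,
                               flight_speed=gt.config.flight_speed))
    with open(os.path.join(out_dir, "ground_truth.json"), "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
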