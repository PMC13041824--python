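"""Flight segmentation, path clustering, derived kinematics, reproducibility.

Flights are epochs where the smoothed body speed exceeds a threshold for a
minimum duration; they are clustered into *paths* by the RMS distance
between time-resampled trajectories (direction-sensitive: the same corridor
flown in opposite directions counts as two paths).  Position-derived
kinematics are speed, g-force, angular velocity of the velocity direction,
and flight-path angle.  Reproducibility of a path is the distribution of
Pearson correlations between each flight's feature traces and the
leave-one-out mean across the other flights of that path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, fcluster
from scipy.spatial.distance import squareform

from .core import GRAVITY, SessionData, smooth_series, frame_from_keypoints

log = logging.getLogger(__name__)

RESAMPLE_POINTS = 200          # per flight, for clustering / correlation
SMOOTH_SD_S = 0.025            # position smoothing before differentiation


@dataclass
class Flight:
    flight_id: int
    start: float
    end: float
    resampled: np.ndarray          # (RESAMPLE_POINTS, 3)
    path_label: int = -1


@dataclass
class KinematicSeries:
    """Per-sample kinematics for one flight (uniform time base)."""

    t: np.ndarray
    speed: np.ndarray              # m/s
    g_force: np.ndarray            # g
    angular_velocity: np.ndarray   # rad/s, magnitude
    flight_path_angle: np.ndarray  # rad
    velocity: np.ndarray           # (n, 3)
    acceleration: np.ndarray       # (n, 3)
    valid: np.ndarray = field(default=None)  # mask where |v| well defined


def _resample(traj: np.ndarray, n: int = RESAMPLE_POINTS) -> np.ndarray:
    src = np.linspace(0, 1, len(traj))
    dst = np.linspace(0, 1, n)
    return np.column_stack([np.interp(dst, src, traj[:, k]) for k in range(3)])


def segment_flights(t: np.ndarray, pos: np.ndarray, sample_rate: float,
                    speed_threshold: float = 1.0,
                    min_duration: float = 1.0) -> list[Flight]:
    """Find disjoint flight intervals from the speed profile.

    Intervals where the smoothed speed exceeds ``speed_threshold`` for at
    least ``min_duration`` are kept and padded outward to the nearest local
    speed minima (takeoff/landing).
    """
    if len(t) == 0:
        raise ValueError("empty input")
    sm = smooth_series(pos, SMOOTH_SD_S, sample_rate, axis=0)
    v = np.gradient(sm, 1.0 / sample_rate, axis=0)
    speed = smooth_series(np.linalg.norm(v, axis=1), 0.05, sample_rate)
    above = speed > speed_threshold
    flights: list[Flight] = []
    edges = np.flatnonzero(np.diff(above.astype(int)))
    starts = [0] if above[0] else []
    starts += [e + 1 for e in edges if not above[e]]
    ends = [e + 1 for e in edges if above[e]]
    if above[-1]:
        ends.append(len(above))
    fid = 0
    for s, e in zip(starts, ends):
        if (t[e - 1] - t[s]) < min_duration:
            continue
        # pad outward to the local speed minima at takeoff/landing; keep
        # walking through small noise upticks while speed is still well
        # above the stationary floor
        floor = 0.25 * speed_threshold
        stop = 0.1 * speed_threshold
        while s > 0 and speed[s - 1] > stop and \
                (speed[s - 1] < speed[s] or speed[s - 1] > floor):
            s -= 1
        while e < len(speed) and speed[e] > stop and \
                (speed[e] < speed[e - 1] or speed[e] > floor):
            e += 1
        flights.append(Flight(flight_id=fid, start=float(t[s]),
                              end=float(t[e - 1]),
                              resampled=_resample(pos[s:e])))
        fid += 1
    return flights


def cluster_paths(flights: list[Flight], distance_cutoff: float = 0.5,
                  min_flights: int = 2) -> np.ndarray:
    """Agglomerative (average linkage) clustering on pairwise RMS distance.

    Trajectories are compared in their recorded temporal orientation, so a
    path flown in reverse lands in a different cluster.  Clusters smaller
    than ``min_flights`` are labeled -1 (unclustered).  Labels are assigned
    in the flights' order of first appearance.
    """
    n = len(flights)
    if n == 0:
        return np.array([], int)
    if n == 1:
        flights[0].path_label = 0
        return np.array([0])
    X = np.stack([f.resampled.ravel() for f in flights])
    d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).mean(axis=2))
    Z = linkage(squareform(d, checks=False), method="average")
    raw = fcluster(Z, t=distance_cutoff, criterion="distance")
    labels = np.full(n, -1)
    next_label = 0
    for lab in raw[np.sort(np.unique(raw, return_index=True)[1])]:
        members = raw == lab
        if members.sum() >= min_flights:
            labels[members] = next_label
            next_label += 1
    for f, lab in zip(flights, labels):
        f.path_label = int(lab)
    return labels


def derive_kinematics(t: np.ndarray, pos: np.ndarray,
                      sample_rate: float) -> KinematicSeries:
    """Speed, g-force, angular velocity and flight-path angle.

    Derivatives are taken on zero-phase Gaussian-smoothed positions
    (sd 25 ms, well below the ~125 ms wingbeat period).
    """
    sm = smooth_series(pos, SMOOTH_SD_S, sample_rate, axis=0)
    v = np.gradient(sm, 1.0 / sample_rate, axis=0)
    a = np.gradient(v, 1.0 / sample_rate, axis=0)
    speed = np.linalg.norm(v, axis=1)
    g = np.linalg.norm(a, axis=1) / GRAVITY
    valid = speed > 1e-6
    with np.errstate(invalid="ignore", divide="ignore"):
        fpa = np.arcsin(np.clip(np.where(valid, v[:, 2], np.nan)
                                / np.where(valid, speed, 1.0), -1, 1))
        vhat = v / np.where(valid, speed, 1.0)[:, None]
    dvhat = np.gradient(vhat, 1.0 / sample_rate, axis=0)
    angvel = np.linalg.norm(np.cross(vhat, dvhat), axis=1)
    angvel[~valid] = np.nan
    return KinematicSeries(t=t, speed=speed, g_force=g,
                           angular_velocity=angvel, flight_path_angle=fpa,
                           velocity=v, acceleration=a, valid=valid)


def _range_normalize(x: np.ndarray) -> np.ndarray:
    lo, hi = np.nanmin(x), np.nanmax(x)
    if hi - lo == 0:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def flight_feature_traces(session: SessionData, flight: Flight,
                          n_points: int = RESAMPLE_POINTS) -> dict[str, np.ndarray]:
    """Default per-flight feature traces, resampled to a common length.

    Positions are range-normalized 0–1; derived kinematics are used as-is.
    """
    sel = (session.t >= flight.start) & (session.t <= flight.end)
    kin = derive_kinematics(session.t[sel], session.pos[sel],
                            session.sample_rate)
    src = np.linspace(0, 1, sel.sum())
    dst = np.linspace(0, 1, n_points)

    def rs(x):
        return np.interp(dst, src, np.nan_to_num(x, nan=np.nanmean(x)))

    feats = {
        "x": rs(_range_normalize(session.pos[sel, 0])),
        "y": rs(_range_normalize(session.pos[sel, 1])),
        "z": rs(_range_normalize(session.pos[sel, 2])),
        "speed": rs(kin.speed), "g_force": rs(kin.g_force),
        "angular_velocity": rs(kin.angular_velocity),
        "flight_path_angle": rs(kin.flight_path_angle),
        "vx": rs(kin.velocity[:, 0]), "vy": rs(kin.velocity[:, 1]),
        "vz": rs(kin.velocity[:, 2]),
        "ax": rs(kin.acceleration[:, 0]), "ay": rs(kin.acceleration[:, 1]),
        "az": rs(kin.acceleration[:, 2]),
    }
    return feats


def path_reproducibility(feature_traces: list[dict[str, np.ndarray]]) -> np.ndarray:
    """Pearson correlation of each flight with the leave-one-out path mean.

    ``feature_traces`` holds one dict of equal-length traces per flight of a
    single path.  Correlations are pooled over features; constant traces are
    excluded (logged).
    """
    if len(feature_traces) < 2:
        raise ValueError("need >= 2 flights")
    names = list(feature_traces[0])
    out = []
    for name in names:
        M = np.stack([ft[name] for ft in feature_traces])  # flights x points
        total = M.sum(axis=0)
        for i in range(len(M)):
            loo_mean = (total - M[i]) / (len(M) - 1)
            a, b = M[i], loo_mean
            if np.std(a) == 0 or np.std(b) == 0:
                log.info("constant trace for feature %s, flight %d excluded",
                         name, i)
                continue
            out.append(np.corrcoef(a, b)[0, 1])
    return np.asarray(out)


def body_frame_transform(keypoints: np.ndarray, names: list[str],
                         origin: str = "body", head: str = "head",
                         tail: str = "tail", left: str = "shoulder_L",
                         right: str = "shoulder_R"):
    """Re-project world-frame keypoints into the body reference frame.

    The frame is built per sample from anatomical keypoints: forward =
    head − tail, lateral = left − right shoulder, up completes the frame;
    the origin keypoint maps to (0,0,0).  Frames with collinear axis
    keypoints are masked.  Returns (body_kp, ok_mask).
    """
    ix = {nm: names.index(nm) for nm in (origin, head, tail, left, right)}
    R, ok = frame_from_keypoints(keypoints[:, ix[head]], keypoints[:, ix[tail]],
                                 keypoints[:, ix[left]], keypoints[:, ix[right]])
    centered = keypoints - keypoints[:, ix[origin]][:, None, :]
    body = np.einsum("nij,nkj->nki", np.transpose(R, (0, 2, 1)), centered)
    body[~ok] = np.nan
    return body, ok


def world_from_body(body_kp: np.ndarray, R: np.ndarray,
                    origin_world: np.ndarray) -> np.ndarray:
    """Inverse of :func:`body_frame_transform` given the frame matrices."""
    return np.einsum("nij,nkj->nki", R, body_kp) + origin_world[:, None, :]
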