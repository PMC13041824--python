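"""Shared containers and small numeric helpers used across the pipeline.

A *session* is a set of synchronized streams recorded while a bat flies
freely in a room: 3D body position (~120 Hz), optional 3D keypoints on the
body and wings, a 3-axis accelerometer carried by the animal, and spike
times for a population of motor-cortical units.  All analysis modules
consume the :class:`SessionData` container defined here; the synthetic
generator additionally produces a :class:`GroundTruth` holding every
planted parameter so downstream stages can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

GRAVITY = 9.81  # m/s^2; accelerometer traces are expressed in g units


@dataclass
class SessionData:
    """Synchronized recording streams on a common uniform time base."""

    t: np.ndarray                      # (n,) seconds
    pos: np.ndarray                    # (n, 3) meters, world frame
    accel: np.ndarray                  # (n, 3) g units; az is dorsoventral
    spikes: dict[int, np.ndarray]      # unit_id -> sorted spike times (s)
    sample_rate: float                 # Hz
    keypoints: Optional[np.ndarray] = None   # (n, K, 3) meters
    keypoint_names: list[str] = field(default_factory=list)
    keypoint_frame: str = "body"       # 'body' or 'world'
    meta: dict = field(default_factory=dict)

    @property
    def n_units(self) -> int:
        return len(self.spikes)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self.t) else 0.0

    def validate(self) -> None:
        if self.t.ndim != 1 or len(self.t) < 2:
            raise ValueError("time base must be a 1-D array with >= 2 samples")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            bad = int(np.argmax(dt <= 0))
            raise ValueError(f"non-monotone timestamps at row {bad}")
        if self.pos.shape != (len(self.t), 3):
            raise ValueError("positions must be (n, 3)")
        t0, t1 = self.t[0], self.t[-1]
        for uid, st in self.spikes.items():
            if len(st) and (st[0] < t0 - 1e-9 or st[-1] > t1 + 1e-9):
                row = 0 if st[0] < t0 - 1e-9 else len(st) - 1
                raise ValueError(
                    f"unit {uid}: spike time outside recording at row {row}"
                )


def smooth_series(x: np.ndarray, sd_s: float, sample_rate: float,
                  axis: int = 0) -> np.ndarray:
    """Zero-phase Gaussian smoothing with sd given in seconds."""
    sd = sd_s * sample_rate
    if sd <= 0:
        return np.asarray(x, float)
    return gaussian_filter1d(np.asarray(x, float), sd, axis=axis, mode="nearest")


def spawn_rng(seed: int, *names: str) -> np.random.Generator:
    """Named, order-independent substream of a root seed.

    Every stochastic stage draws from its own substream so that toggling one
    stage never perturbs another's random numbers.
    """
    h = 0
    for name in names:
        for ch in name:
            h = (h * 31 + ord(ch)) % (2 ** 31)
    return np.random.default_rng(np.random.SeedSequence([int(seed), h]))


def resultant_vector(phases: np.ndarray) -> tuple[float, float]:
    """Resultant vector length and mean direction of circular data.

    RVL is 0 for a uniform phase distribution and 1 when all phases
    coincide; the preferred phase is the argument of the complex mean.
    """
    phases = np.asarray(phases, float)
    if phases.size == 0:
        raise ValueError("RVL undefined for zero phases")
    z = np.exp(1j * phases).mean()
    return float(np.abs(z)), float(np.mod(np.angle(z), 2 * np.pi))


def participation_ratio(values: np.ndarray) -> float:
    """(sum v)^2 / sum v^2 over a nonnegative spectrum (or squared weights)."""
    v = np.asarray(values, float)
    denom = np.sum(v ** 2)
    if denom == 0:
        raise ValueError("participation ratio undefined for all-zero input")
    return float(np.sum(v) ** 2 / denom)


def bh_fdr(pvals: np.ndarray, q: float) -> np.ndarray:
    """Benjamini–Hochberg step-up rejections at level q.

    Returns a boolean mask. NaN p-values are never rejected and do not count
    toward the number of tests.
    """
    p = np.asarray(pvals, float)
    ok = ~np.isnan(p)
    m = int(ok.sum())
    reject = np.zeros(p.shape, bool)
    if m == 0:
        return reject
    idx = np.argsort(np.where(ok, p, np.inf))
    sorted_p = p[idx][:m]
    thresh = q * (np.arange(1, m + 1) / m)
    below = sorted_p <= thresh
    if below.any():
        k = int(np.max(np.nonzero(below)[0]))
        reject[idx[: k + 1]] = True
    return reject


def permutation_pvalue(observed: float, null: np.ndarray) -> float:
    """(1 + #null >= observed) / (1 + N) — never returns 0."""
    null = np.asarray(null, float)
    return float((1 + np.sum(null >= observed)) / (1 + len(null)))


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return np.nan
    return float(np.dot(a, b) / (na * nb))


def bin_spikes(spike_times: np.ndarray, t0: float, t1: float,
               bin_s: float) -> np.ndarray:
    """Spike counts on a uniform grid covering [t0, t1)."""
    n = max(1, int(np.ceil((t1 - t0) / bin_s)))
    edges = t0 + bin_s * np.arange(n + 1)
    counts, _ = np.histogram(spike_times, bins=edges)
    return counts.astype(float)


def frame_from_keypoints(head: np.ndarray, tail: np.ndarray,
                         left: np.ndarray, right: np.ndarray):
    """Body axes (forward, left, up) from four anatomical keypoints.

    forward = head - tail; lateral = left - right (shoulders); up completes
    the right-handed frame.  Returns (R, ok) where R is (n, 3, 3) with axis
    columns and ok flags frames where the axes are well defined.
    """
    f = head - tail
    l = left - right
    fn = np.linalg.norm(f, axis=-1, keepdims=True)
    ok = fn[..., 0] > 1e-9
    f = np.divide(f, np.where(fn > 1e-9, fn, 1.0))
    l = l - np.sum(l * f, axis=-1, keepdims=True) * f
    ln = np.linalg.norm(l, axis=-1, keepdims=True)
    ok &= ln[..., 0] > 1e-9
    l = np.divide(l, np.where(ln > 1e-9, ln, 1.0))
    u = np.cross(f, l)
    R = np.stack([f, l, u], axis=-1)
    return R, ok
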