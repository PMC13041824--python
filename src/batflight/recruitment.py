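"""Wingbeat barcodes, group decoding, similarity curves, path divergence.

A *barcode* is the binary vector saying which units fired at least one
spike during a wingbeat cycle.  If successive wingbeats recruit distinct
unit subsets, a linear classifier can recover the wingbeat *group* (the
ordinal-matched cluster of cycles across flights of a path) from the
barcode alone, with confusions concentrated near the diagonal when
recruitment drifts smoothly.  Population similarity as a function of
wingbeat lag quantifies that drift directly.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .core import bin_spikes, smooth_series

log = logging.getLogger(__name__)


def build_barcodes(spikes: dict[int, np.ndarray],
                   table: pd.DataFrame) -> pd.DataFrame:
    """Binary wingbeats x units activity matrix (>= 1 spike in the cycle).

    Returns a DataFrame indexed like ``table`` with one u{unit} column per
    unit plus the wingbeat_id / flight_id / group columns carried over.
    """
    onsets = table["onset"].to_numpy()
    offsets = table["offset"].to_numpy()
    cols = {}
    for uid, st in sorted(spikes.items()):
        counts = (np.searchsorted(st, offsets) - np.searchsorted(st, onsets))
        cols[f"u{uid}"] = (counts > 0).astype(int)
    out = table[[c for c in ("wingbeat_id", "flight_id", "ordinal", "group")
                 if c in table.columns]].copy().reset_index(drop=True)
    return pd.concat([out, pd.DataFrame(cols)], axis=1)


def cycle_counts(spikes: dict[int, np.ndarray],
                 table: pd.DataFrame) -> np.ndarray:
    """Per-cycle spike-count population vectors (wingbeats x units)."""
    onsets = table["onset"].to_numpy()
    offsets = table["offset"].to_numpy()
    M = np.zeros((len(table), len(spikes)))
    for j, (uid, st) in enumerate(sorted(spikes.items())):
        M[:, j] = np.searchsorted(st, offsets) - np.searchsorted(st, onsets)
    return M


def _merge_small_groups(labels: np.ndarray, k: int) -> np.ndarray:
    """Merge groups with < k members into the nearest ordinal neighbor."""
    labels = labels.copy()
    while True:
        vals, counts = np.unique(labels, return_counts=True)
        small = vals[counts < k]
        if len(small) == 0 or len(vals) <= 2:
            return labels
        g = small[0]
        others = vals[vals != g]
        target = others[np.argmin(np.abs(others - g))]
        log.info("group %s (<%d members) merged into %s", g, k, target)
        labels[labels == g] = target


def decode_wingbeat_group(X: np.ndarray, groups: np.ndarray,
                          k_folds: int = 5, C: float = 1.0,
                          seed: int = 0):
    """Linear SVM (one-vs-rest, class-balanced) with stratified k-fold CV.

    Returns (confusion, accuracy, group_values): confusion counts are
    accumulated over held-out folds; rows = true group, columns = predicted.
    """
    groups = _merge_small_groups(np.asarray(groups), k_folds)
    vals = np.unique(groups)
    if len(vals) < 2:
        raise ValueError("need >= 2 groups")
    gi = np.searchsorted(vals, groups)
    conf = np.zeros((len(vals), len(vals)), int)
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    for tr, te in skf.split(X, gi):
        clf = LinearSVC(C=C, class_weight="balanced", max_iter=5000)
        clf.fit(X[tr], gi[tr])
        pred = clf.predict(X[te])
        np.add.at(conf, (gi[te], pred), 1)
    acc = np.trace(conf) / conf.sum()
    return conf, float(acc), vals


def band_accuracy(confusion: np.ndarray, band: int) -> float:
    """Fraction of predictions within +/- band groups of the true group."""
    G = confusion.shape[0]
    if confusion.shape[0] != confusion.shape[1]:
        raise ValueError("confusion must be square")
    if band >= G:
        log.warning("band >= number of groups: accuracy trivially 1")
    i, j = np.indices(confusion.shape)
    return float(confusion[np.abs(i - j) <= band].sum() / confusion.sum())


def shuffle_null(X: np.ndarray, groups: np.ndarray, n_iter: int = 100,
                 k_folds: int = 5, bands: tuple[int, ...] = (0, 1),
                 seed: int = 0) -> pd.DataFrame:
    """Full decode pipeline re-run on label permutations.

    Returns one row per iteration with band accuracies.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for it in range(n_iter):
        perm = rng.permutation(np.asarray(groups))
        conf, acc, _ = decode_wingbeat_group(X, perm, k_folds, seed=seed + it)
        rows.append({f"band{b}": band_accuracy(conf, b) for b in bands})
    return pd.DataFrame(rows)


def barcode_similarity_curve(M: np.ndarray, flight_ids: np.ndarray,
                             ordinals: np.ndarray,
                             max_lag: int = 10) -> np.ndarray:
    """Mean cosine similarity of population vectors vs wingbeat lag.

    ``M`` is wingbeats x units (counts or binary), rows ordered arbitrarily;
    flight_ids/ordinals locate each cycle.  Zero rows are excluded.
    """
    sums = np.zeros(max_lag + 1)
    counts = np.zeros(max_lag + 1)
    for f in np.unique(flight_ids):
        sel = flight_ids == f
        V = M[sel][np.argsort(ordinals[sel])]
        norms = np.linalg.norm(V, axis=1)
        bad = norms == 0
        for lag in range(max_lag + 1):
            if lag >= len(V):
                break
            ok = ~(bad[: len(V) - lag] | bad[lag:])
            if not ok.any():
                continue
            cs = np.einsum("ij,ij->i", V[: len(V) - lag][ok], V[lag:][ok])
            cs = cs / (norms[: len(V) - lag][ok] * norms[lag:][ok])
            sums[lag] += cs.sum()
            counts[lag] += len(cs)
    with np.errstate(invalid="ignore"):
        return sums / counts


def similarity_decay_constant(curve: np.ndarray) -> float:
    """Lag constant of an exponential fit to (curve - asymptote).

    Least squares on log(curve - floor) over lags where the excess is
    positive; the floor is the mean of the last two lags.
    """
    floor = np.nanmean(curve[-2:])
    y = curve - floor
    lags = np.arange(len(curve))
    ok = np.isfinite(y) & (y > 1e-12)
    ok[int(len(curve) * 0.7):] = False
    if ok.sum() < 2:
        return np.nan
    slope, _ = np.polyfit(lags[ok], np.log(y[ok]), 1)
    return float(-1.0 / slope) if slope < 0 else np.inf


def cross_path_divergence(spikes: dict[int, np.ndarray],
                          flights_a: pd.DataFrame, flights_b: pd.DataFrame,
                          window_s: float = 0.250, step_s: float = 0.005,
                          bin_s: float = 0.010):
    """Mean |z-scored| rate difference between two takeoff-aligned paths.

    For each unit, rates are averaged across flights on a common time base
    from takeoff (truncated to the shorter path), z-scored with the pooled
    mean/sd across both paths, and the absolute difference is averaged over
    units in sliding windows.  The within-path control repeats the
    computation between odd and even flights of path A.

    Returns (times, divergence, control).
    """
    dur_a = (flights_a["end"] - flights_a["start"]).min()
    dur_b = (flights_b["end"] - flights_b["start"]).min()
    dur = min(dur_a, dur_b)
    n_bins = int(dur / bin_s)
    unit_ids = sorted(spikes)

    def mean_traces(fls):
        R = np.zeros((len(unit_ids), n_bins))
        for fl in fls.itertuples():
            for j, uid in enumerate(unit_ids):
                sel = (spikes[uid] >= fl.start) & (spikes[uid] < fl.end)
                c = bin_spikes(spikes[uid][sel] - fl.start, 0.0,
                               n_bins * bin_s, bin_s)[:n_bins] / bin_s
                R[j] += c
        R /= len(fls)
        return smooth_series(R, 0.025, 1.0 / bin_s, axis=1)

    Ra, Rb = mean_traces(flights_a), mean_traces(flights_b)

    def z_pair(A, B):
        both = np.concatenate([A, B], axis=1)
        mu = both.mean(axis=1, keepdims=True)
        sd = both.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        return (A - mu) / sd, (B - mu) / sd

    za, zb = z_pair(Ra, Rb)
    diff = np.abs(za - zb).mean(axis=0)

    odd = flights_a.iloc[1::2]
    even = flights_a.iloc[0::2]
    zo, ze = z_pair(mean_traces(odd), mean_traces(even))
    ctrl = np.abs(zo - ze).mean(axis=0)

    w = max(1, int(window_s / bin_s))
    step = max(1, int(step_s / bin_s))
    starts = np.arange(0, n_bins - w + 1, step)
    times = (starts + w / 2) * bin_s
    div_w = np.array([diff[s:s + w].mean() for s in starts])
    ctrl_w = np.array([ctrl[s:s + w].mean() for s in starts])
    return times, div_w, ctrl_w
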