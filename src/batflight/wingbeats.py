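"""Wingbeat cycle detection, phase, envelopes, adaptation vectors, grouping.

The dorsoventral accelerometer carries the ~8 Hz wingbeat rhythm.  Cycles
are segmented by band-passing that channel (default 4–14 Hz), taking the
analytic-signal phase, and cutting at phase zero — the upward zero-crossing
of the band-passed oscillation.  Per-cycle upper/lower envelopes of
body-frame keypoint displacement and their left–right asymmetries summarize
the cycle-specific kinematic adjustments ("adaptation vectors"); wingbeats
of one path are clustered into ordinal-preserving *groups* by kinematic
similarity.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt, hilbert
from scipy.stats import spearmanr
from sklearn.cluster import KMeans

from .core import cosine_similarity

log = logging.getLogger(__name__)

AMPLITUDE_GATE = 0.2   # cycles below 20% of flight-median amplitude rejected


def bandpass(x: np.ndarray, sample_rate: float, band=(4.0, 14.0),
             order: int = 3) -> np.ndarray:
    b, a = butter(order, [band[0] / (sample_rate / 2),
                          band[1] / (sample_rate / 2)], btype="band")
    return filtfilt(b, a, x)


def detect_wingbeats(t: np.ndarray, accel_dv: np.ndarray, sample_rate: float,
                     flights: pd.DataFrame | None = None,
                     band=(4.0, 14.0), pos: np.ndarray | None = None):
    """Segment wingbeat cycles and assign instantaneous phase.

    Returns ``(table, theta)``: a WingbeatTable DataFrame (wingbeat_id,
    flight_id, onset, offset, period_ms, ordinal, x, y, z) and the per-sample
    phase in [0, 2pi) (NaN outside accepted cycles).  If ``flights`` is None
    the whole trace is treated as one flight.
    """
    filt = bandpass(accel_dv, sample_rate, band)
    if flights is None:
        flights = pd.DataFrame([dict(flight_id=0, start=t[0], end=t[-1])])
    theta = np.full(len(t), np.nan)
    rows = []
    wb_id = 0
    min_period = 1.0 / band[1] * 0.6
    for fl in flights.itertuples():
        sel = (t >= fl.start) & (t <= fl.end)
        if sel.sum() < 4:
            continue
        seg = filt[np.flatnonzero(sel)]
        tseg = t[sel]
        if (fl.end - fl.start) < 2.0 / band[0]:
            warnings.warn(f"flight {fl.flight_id} shorter than 2 cycles")
            continue
        # coherence gate: flapping concentrates power in the wingbeat band,
        # whereas broadband noise leaves most variance outside it
        raw = accel_dv[np.flatnonzero(sel)]
        total_var = np.var(raw - raw.mean())
        if total_var == 0 or np.var(seg) / total_var < 0.3:
            warnings.warn(f"flight {fl.flight_id}: no coherent wingbeat "
                          "band oscillation")
            continue
        phase = np.unwrap(np.angle(hilbert(seg)))
        # zero of the cycle = upward zero-crossing of the band-passed signal,
        # where the analytic phase crosses -pi/2 (signal ~ sin -> angle-pi/2)
        phase = phase + np.pi / 2
        kfloor = np.floor(phase / (2 * np.pi))
        crossings = []
        for i in np.flatnonzero(np.diff(kfloor) > 0):
            target = 2 * np.pi * kfloor[i + 1]
            # linear interpolation for sub-sample boundary
            f = (target - phase[i]) / (phase[i + 1] - phase[i])
            crossings.append(tseg[i] + f * (tseg[i + 1] - tseg[i]))
        amp_med = np.median(np.abs(seg)) * np.sqrt(2)
        ordinal = 0
        first_row = len(rows)
        for onset, offset in zip(crossings[:-1], crossings[1:]):
            period = offset - onset
            if period < min_period:
                continue
            csel = (tseg >= onset) & (tseg < offset)
            amp = np.max(np.abs(seg[csel])) if csel.any() else 0.0
            if amp < AMPLITUDE_GATE * amp_med:
                continue
            row = dict(wingbeat_id=wb_id, flight_id=fl.flight_id,
                       onset=float(onset), offset=float(offset),
                       period_ms=period * 1000.0, ordinal=ordinal)
            if pos is not None:
                psel = (t >= onset) & (t < offset)
                row.update(x=pos[psel, 0].mean(), y=pos[psel, 1].mean(),
                           z=pos[psel, 2].mean())
            rows.append(row)
            wb_id += 1
            ordinal += 1
        # per-sample phase inside accepted cycles
        idx = np.flatnonzero(sel)
        ph_mod = np.mod(phase, 2 * np.pi)
        for row in rows[first_row:]:
            csel = (tseg >= row["onset"]) & (tseg < row["offset"])
            theta[idx[csel]] = ph_mod[csel]
    table = pd.DataFrame(rows)
    return table, theta


def period_statistics(table: pd.DataFrame) -> dict:
    """Median and IQR of cycle periods (ms)."""
    if len(table) == 0:
        raise ValueError("no wingbeats")
    p = table["period_ms"].to_numpy()
    q25, q75 = np.percentile(p, [25, 75])
    return dict(median_ms=float(np.median(p)), iqr_ms=float(q75 - q25),
                n=len(p))


def extract_envelopes(t: np.ndarray, displacement: np.ndarray,
                      table: pd.DataFrame):
    """Upper/lower envelopes of a keypoint displacement trace.

    Per cycle the envelope values are the max (upper) and min (lower) of the
    displacement; a cubic spline through the per-cycle extrema gives a
    smooth envelope at every sample.  Returns a DataFrame (wingbeat_id,
    upper, lower) and ``(upper_t, lower_t)`` interpolated traces.
    """
    rows = []
    centers = []
    for wb in table.itertuples():
        sel = (t >= wb.onset) & (t < wb.offset)
        if not sel.any() or np.all(np.isnan(displacement[sel])):
            rows.append(dict(wingbeat_id=wb.wingbeat_id,
                             upper=np.nan, lower=np.nan))
            centers.append(0.5 * (wb.onset + wb.offset))
            continue
        rows.append(dict(wingbeat_id=wb.wingbeat_id,
                         upper=float(np.nanmax(displacement[sel])),
                         lower=float(np.nanmin(displacement[sel]))))
        centers.append(0.5 * (wb.onset + wb.offset))
    df = pd.DataFrame(rows)
    centers = np.asarray(centers)
    up_t = np.full(len(t), np.nan)
    lo_t = np.full(len(t), np.nan)
    good = ~df["upper"].isna().to_numpy()
    if good.sum() >= 2:
        span = (t >= centers[good][0]) & (t <= centers[good][-1])
        if good.sum() >= 4:
            up_t[span] = CubicSpline(centers[good], df["upper"][good])(t[span])
            lo_t[span] = CubicSpline(centers[good], df["lower"][good])(t[span])
        else:
            up_t[span] = np.interp(t[span], centers[good], df["upper"][good])
            lo_t[span] = np.interp(t[span], centers[good], df["lower"][good])
    return df, (up_t, lo_t)


def left_right_asymmetry(env_left: pd.DataFrame,
                         env_right: pd.DataFrame) -> pd.DataFrame:
    """Right minus left per-cycle envelope difference (upper and lower)."""
    m = env_left.merge(env_right, on="wingbeat_id",
                       suffixes=("_left", "_right"))
    return pd.DataFrame(dict(
        wingbeat_id=m["wingbeat_id"],
        upper=m["upper_right"] - m["upper_left"],
        lower=m["lower_right"] - m["lower_left"],
    ))


def adaptation_vectors(env_tables: dict[str, pd.DataFrame],
                       asym_tables: dict[str, pd.DataFrame],
                       table: pd.DataFrame) -> pd.DataFrame:
    """Per-wingbeat adaptation vector: envelope means plus asymmetries."""
    out = table[["wingbeat_id", "flight_id", "ordinal"]].copy()
    for name, env in env_tables.items():
        out = out.merge(env.rename(columns={"upper": f"{name}_upper",
                                            "lower": f"{name}_lower"}),
                        on="wingbeat_id", how="left")
    for name, asym in asym_tables.items():
        out = out.merge(asym.rename(columns={"upper": f"{name}_asym_upper",
                                             "lower": f"{name}_asym_lower"}),
                        on="wingbeat_id", how="left")
    return out


def adaptation_similarity_curve(vectors: pd.DataFrame,
                                max_lag: int = 10) -> np.ndarray:
    """Mean cosine similarity between cycle vectors at each wingbeat lag.

    Averaged over reference wingbeats within each flight, then over
    flights.  Lag 0 is identically 1 for nonzero vectors.  Zero vectors are
    excluded (logged).
    """
    cols = [c for c in vectors.columns
            if c not in ("wingbeat_id", "flight_id", "ordinal")]
    sums = np.zeros(max_lag + 1)
    counts = np.zeros(max_lag + 1)
    for _, fl in vectors.groupby("flight_id"):
        V = fl.sort_values("ordinal")[cols].to_numpy(float)
        norms = np.linalg.norm(V, axis=1)
        bad = (norms == 0) | np.isnan(norms)
        if bad.any():
            log.info("excluded %d zero/NaN adaptation vectors", int(bad.sum()))
        for lag in range(0, max_lag + 1):
            if lag >= len(V):
                break
            a, b = V[: len(V) - lag], V[lag:]
            na, nb = norms[: len(V) - lag], norms[lag:]
            ok = ~(bad[: len(V) - lag] | bad[lag:])
            if not ok.any():
                continue
            cs = np.einsum("ij,ij->i", a[ok], b[ok]) / (na[ok] * nb[ok])
            sums[lag] += np.nansum(cs)
            counts[lag] += np.sum(~np.isnan(cs))
    with np.errstate(invalid="ignore"):
        return sums / counts


def group_wingbeats(table: pd.DataFrame, vectors: pd.DataFrame,
                    kinematic_features: pd.DataFrame | None = None,
                    n_groups: int | None = None, ordinal_weight: float = 50.0,
                    seed: int = 0):
    """Cluster the wingbeats of one path into temporally ordered groups.

    K-means on [adaptation vector; per-cycle kinematics; normalized ordinal]
    with k = median cycle count per flight.  The normalized ordinal enters
    with a weight chosen so that the noiseless case reproduces grouping by
    ordinal position.  Groups are relabeled by mean ordinal so labels run in
    temporal order; the order-preservation score is the Spearman correlation
    of label vs ordinal.

    Returns (labels, order_score).
    """
    df = table.merge(vectors, on=["wingbeat_id", "flight_id", "ordinal"],
                     how="left")
    if kinematic_features is not None:
        df = df.merge(kinematic_features, on="wingbeat_id", how="left")
    if n_groups is None:
        n_groups = int(df.groupby("flight_id")["ordinal"].count().median())
    if n_groups > len(df):
        raise ValueError("more groups than wingbeats")
    feat_cols = [c for c in df.columns
                 if c not in ("wingbeat_id", "flight_id", "ordinal", "onset",
                              "offset", "x", "y", "z")]
    X = df[feat_cols].to_numpy(float)
    X = np.where(np.isnan(X), 0.0, X)
    sd = X.std(axis=0)
    X = X / np.where(sd > 0, sd, 1.0)
    # scale the kinematic block to unit total variance so the ordinal
    # term's influence is independent of how many features are supplied
    X = X / np.sqrt(max(X.shape[1], 1))
    # common denominator across flights so the i-th cycle of every flight
    # lands at the same ordinal coordinate
    ord_norm = df["ordinal"] / max(int(df["ordinal"].max()), 1)
    X = np.column_stack([X, ordinal_weight * ord_norm])
    if df["flight_id"].nunique() == 1:
        labels = df["ordinal"].to_numpy() % n_groups
        return labels, 1.0
    # initialize at per-ordinal centroids: wingbeat groups are expected to
    # track the i-th cycle of each flight, which k-means then refines by
    # kinematic similarity
    ord_clip = np.minimum(df["ordinal"].to_numpy(), n_groups - 1)
    centers = np.stack([X[ord_clip == g].mean(axis=0)
                        if np.any(ord_clip == g) else X.mean(axis=0)
                        for g in range(n_groups)])
    km = KMeans(n_clusters=n_groups, init=centers, n_init=1,
                random_state=seed)
    raw = km.fit_predict(X)
    mean_ord = pd.Series(df["ordinal"].to_numpy()).groupby(raw).mean()
    remap = {old: new for new, old in
             enumerate(mean_ord.sort_values().index)}
    labels = np.array([remap[r] for r in raw])
    score = spearmanr(labels, df["ordinal"]).statistic
    return labels, float(score)
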