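"""Per-unit activity, sparsity and wingbeat-phase statistics.

Two permutation tests are central here, both using the (1 + #null >= obs) /
(1 + N) convention so p-values never reach zero:

* *flight modulation* — the statistic is the mean pairwise Pearson
  correlation of a unit's smoothed rate traces across flights of a path;
  the null circularly shifts each flight's spike train by an independent
  uniform offset (minimum one wingbeat period).  Benjamini–Hochberg FDR is
  applied across units at q = 0.01.
* *phase locking* — the statistic is the resultant vector length (RVL) of
  spike wingbeat phases; the null adds an independent uniform circular
  offset per flight (preserving within-flight phase structure).  BH is
  applied within each path at q = 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (bh_fdr, bin_spikes, permutation_pvalue, resultant_vector,
                   smooth_series)

log = logging.getLogger(__name__)

RATE_BIN_S = 0.010
RATE_SMOOTH_S = 0.025
COMMON_POINTS = 200
MIN_SPIKES_PHASE = 20


@dataclass
class UnitStats:
    unit_id: int
    flight_active: bool
    modulation_p: float
    modulated: bool
    mean_flight_rate: float
    silent_wingbeat_fraction: float


# --------------------------------------------------------------------------
# flight activity / modulation
# --------------------------------------------------------------------------

def flight_active(spike_times: np.ndarray, flights: pd.DataFrame,
                  min_rate: float = 0.2, min_frac: float = 0.05) -> bool:
    """At least one spike in >= 5% of flights and mean flight rate >= 0.2 Hz."""
    n_with = 0
    total_spikes = 0
    total_dur = 0.0
    for fl in flights.itertuples():
        c = np.sum((spike_times >= fl.start) & (spike_times < fl.end))
        n_with += c > 0
        total_spikes += c
        total_dur += fl.end - fl.start
    if total_dur == 0:
        return False
    return (n_with / len(flights) >= min_frac
            and total_spikes / total_dur >= min_rate)


def _flight_rate_traces(rel_spikes: list[np.ndarray], durs: np.ndarray,
                        sample_rate_hint: float = 1.0 / RATE_BIN_S):
    traces = []
    dst = np.linspace(0, 1, COMMON_POINTS)
    for rel, dur in zip(rel_spikes, durs):
        counts = bin_spikes(rel, 0.0, dur, RATE_BIN_S) / RATE_BIN_S
        sm = smooth_series(counts, RATE_SMOOTH_S, 1.0 / RATE_BIN_S)
        src = np.linspace(0, 1, len(sm))
        traces.append(np.interp(dst, src, sm))
    return np.stack(traces)


def _mean_pairwise_corr(traces: np.ndarray) -> float:
    sd = traces.std(axis=1)
    ok = sd > 0
    if ok.sum() < 2:
        return 0.0
    C = np.corrcoef(traces[ok])
    iu = np.triu_indices(ok.sum(), 1)
    return float(C[iu].mean())


def flight_modulation_test(spike_times: np.ndarray, flights: pd.DataFrame,
                           n_shuffles: int = 1000,
                           min_shift_s: float = 0.125,
                           rng: np.random.Generator | None = None) -> float:
    """Permutation p-value for across-flight rate-trace consistency.

    Silent units get p = 1 by convention (logged).
    """
    if len(flights) < 3:
        raise ValueError("need >= 3 flights")
    rng = rng or np.random.default_rng(0)
    rel_spikes, durs = [], []
    for fl in flights.itertuples():
        sel = (spike_times >= fl.start) & (spike_times < fl.end)
        rel_spikes.append(spike_times[sel] - fl.start)
        durs.append(fl.end - fl.start)
    durs = np.asarray(durs)
    if sum(len(r) for r in rel_spikes) == 0:
        log.info("silent unit: modulation p = 1 by convention")
        return 1.0
    obs = _mean_pairwise_corr(_flight_rate_traces(rel_spikes, durs))
    null = np.empty(n_shuffles)
    for it in range(n_shuffles):
        shifted = []
        for rel, dur in zip(rel_spikes, durs):
            lo = min(min_shift_s, dur / 4)
            off = rng.uniform(lo, dur - lo)
            shifted.append(np.mod(rel + off, dur))
        null[it] = _mean_pairwise_corr(_flight_rate_traces(shifted, durs))
    return permutation_pvalue(obs, null)


def silent_wingbeat_fraction(spike_times: np.ndarray,
                             table: pd.DataFrame) -> float:
    """Fraction of wingbeat cycles in which the unit emitted no spikes."""
    if len(table) == 0:
        raise ValueError("no wingbeats")
    onsets = table["onset"].to_numpy()
    offsets = table["offset"].to_numpy()
    counts = (np.searchsorted(spike_times, offsets)
              - np.searchsorted(spike_times, onsets))
    return float(np.mean(counts == 0))


# --------------------------------------------------------------------------
# phase locking
# --------------------------------------------------------------------------

def spike_phases(spike_times: np.ndarray, t: np.ndarray,
                 theta: np.ndarray) -> np.ndarray:
    """Wingbeat phase at each spike time (NaN outside accepted cycles).

    Interpolates the unwrapped phase; spikes falling in samples without a
    defined phase are NaN.
    """
    defined = ~np.isnan(theta)
    phase = np.full(len(spike_times), np.nan)
    if not defined.any() or len(spike_times) == 0:
        return phase
    idx = np.clip(np.searchsorted(t, spike_times) - 1, 0, len(t) - 2)
    ok = defined[idx] & defined[idx + 1]
    th0, th1 = theta[idx[ok]], theta[idx[ok] + 1]
    dth = np.mod(th1 - th0, 2 * np.pi)
    frac = (spike_times[ok] - t[idx[ok]]) / (t[idx[ok] + 1] - t[idx[ok]])
    phase[ok] = np.mod(th0 + frac * dth, 2 * np.pi)
    return phase


def resultant_vector_length(phases: np.ndarray) -> tuple[float, float]:
    """RVL and preferred phase of the spike phase sample."""
    phases = np.asarray(phases, float)
    phases = phases[~np.isnan(phases)]
    return resultant_vector(phases)


def phase_locking_test(phases_by_flight: list[np.ndarray],
                       n_shuffles: int = 1000,
                       rng: np.random.Generator | None = None) -> float:
    """Permutation p-value for phase concentration (RVL statistic).

    The null rotates each flight's spike phases by an independent uniform
    circular offset, preserving within-flight structure.
    """
    rng = rng or np.random.default_rng(0)
    zs = np.array([np.exp(1j * p[~np.isnan(p)]).sum()
                   for p in phases_by_flight])
    n = sum(int(np.sum(~np.isnan(p))) for p in phases_by_flight)
    if n == 0:
        return 1.0
    obs = np.abs(zs.sum()) / n
    rot = np.exp(1j * rng.uniform(0, 2 * np.pi,
                                  (n_shuffles, len(zs))))
    null = np.abs((rot * zs[None, :]).sum(axis=1)) / n
    return permutation_pvalue(obs, null)


def phase_locking_table(spikes: dict[int, np.ndarray], t: np.ndarray,
                        theta: np.ndarray, flights: pd.DataFrame,
                        n_shuffles: int = 1000, q: float = 0.05,
                        min_spikes: int = MIN_SPIKES_PHASE,
                        seed: int = 0) -> pd.DataFrame:
    """Per unit-path RVL, preferred phase and BH decision (within path).

    Paths are taken from the ``path`` column of ``flights``; units with
    fewer than ``min_spikes`` phase-defined spikes in a path are excluded
    from testing (logged, sig = NaN).
    """
    rows = []
    for path, fls in flights.groupby("path"):
        for uid, st in spikes.items():
            per_flight = []
            for fl in fls.itertuples():
                sel = (st >= fl.start) & (st < fl.end)
                per_flight.append(spike_phases(st[sel], t, theta))
            allp = np.concatenate(per_flight) if per_flight else np.array([])
            allp = allp[~np.isnan(allp)]
            if len(allp) < min_spikes:
                log.info("unit %d path %s: %d spikes < %d, excluded",
                         uid, path, len(allp), min_spikes)
                rows.append(dict(unit_id=uid, path=path, n_spikes=len(allp),
                                 rvl=np.nan, pref_phase=np.nan, p=np.nan,
                                 sig=False, tested=False))
                continue
            rvl, pref = resultant_vector(allp)
            rng = np.random.default_rng(
                np.random.SeedSequence([seed, int(path), uid]))
            p = phase_locking_test(per_flight, n_shuffles, rng)
            rows.append(dict(unit_id=uid, path=path, n_spikes=len(allp),
                             rvl=rvl, pref_phase=pref, p=p, sig=False,
                             tested=True))
    df = pd.DataFrame(rows)
    for path in df["path"].unique():
        sel = (df["path"] == path) & df["tested"]
        if sel.any():
            df.loc[sel, "sig"] = bh_fdr(df.loc[sel, "p"].to_numpy(), q)
    return df


def unit_statistics(spikes: dict[int, np.ndarray], flights: pd.DataFrame,
                    wingbeat_table: pd.DataFrame, n_shuffles: int = 1000,
                    q: float = 0.01, seed: int = 0) -> pd.DataFrame:
    """Flight-activity flags, modulation test with BH across units, sparsity."""
    rows = []
    for uid, st in sorted(spikes.items()):
        active = flight_active(st, flights)
        dur = (flights["end"] - flights["start"]).sum()
        nsp = sum(int(np.sum((st >= fl.start) & (st < fl.end)))
                  for fl in flights.itertuples())
        rng = np.random.default_rng(np.random.SeedSequence([seed, 1, uid]))
        # modulation is assessed within each path, best (min) p kept per
        # unit after Bonferroni across that unit's paths
        ps = []
        for path, fls in flights.groupby("path"):
            if len(fls) < 3:
                continue
            ps.append(flight_modulation_test(st, fls, n_shuffles, rng=rng))
        p = min(1.0, min(ps) * len(ps)) if ps else np.nan
        rows.append(dict(unit_id=uid, flight_active=active,
                         modulation_p=p,
                         mean_flight_rate=nsp / dur if dur > 0 else 0.0,
                         silent_wingbeat_fraction=silent_wingbeat_fraction(
                             st, wingbeat_table)))
    df = pd.DataFrame(rows)
    df["modulated"] = bh_fdr(df["modulation_p"].to_numpy(), q)
    return df


# --------------------------------------------------------------------------
# sliding window traces and cross-path phase decoding
# --------------------------------------------------------------------------

def sliding_phase_raster(spikes: dict[int, np.ndarray],
                         table: pd.DataFrame, unit_ids: list[int],
                         window: int = 5, overlap: int = 4) -> np.ndarray:
    """Per-unit z-scored mean rate in sliding wingbeat windows.

    Windows advance by ``window - overlap`` wingbeat groups; rates are
    averaged across flights at matching ordinals.  Returns an array
    (units x windows).
    """
    step = window - overlap
    if step < 1:
        raise ValueError("overlap must be < window")
    n_ord = int(table.groupby("flight_id")["ordinal"].count().median())
    if window > n_ord:
        raise ValueError("window longer than path")
    starts = list(range(0, n_ord - window + 1, step))
    out = np.zeros((len(unit_ids), len(starts)))
    for ui, uid in enumerate(unit_ids):
        st = spikes[uid]
        per_ord = np.zeros(n_ord)
        per_dur = np.zeros(n_ord)
        for wb in table.itertuples():
            if wb.ordinal >= n_ord:
                continue
            c = np.sum((st >= wb.onset) & (st < wb.offset))
            per_ord[wb.ordinal] += c
            per_dur[wb.ordinal] += wb.offset - wb.onset
        rate = per_ord / np.where(per_dur > 0, per_dur, 1.0)
        vals = np.array([rate[s:s + window].mean() for s in starts])
        sd = vals.std()
        out[ui] = (vals - vals.mean()) / sd if sd > 0 else 0.0
    return out


def _circular_r2(theta_true: np.ndarray, theta_hat: np.ndarray) -> float:
    """1 - residual circular variance relative to the circular mean."""
    z = np.exp(1j * theta_true).mean()
    mu = np.angle(z)
    resid = np.mean(1 - np.cos(theta_true - theta_hat))
    base = np.mean(1 - np.cos(theta_true - mu))
    if base == 0:
        return np.nan
    return float(1 - resid / base)


def _phase_design(spikes, unit_ids, t, theta, flights, bin_s=RATE_BIN_S):
    """Binned, smoothed, z-scored population rates + phase per bin."""
    X_rows, th_rows, fold = [], [], []
    for fi, fl in enumerate(flights.itertuples()):
        sel = (t >= fl.start) & (t < fl.end)
        tt = t[sel]
        th = theta[sel]
        edges = np.arange(fl.start, fl.end, bin_s)
        if len(edges) < 3:
            continue
        centers = edges[:-1] + bin_s / 2
        R = np.stack([
            smooth_series(np.histogram(spikes[u], bins=edges)[0] / bin_s,
                          RATE_SMOOTH_S, 1.0 / bin_s)
            for u in unit_ids])
        defined = ~np.isnan(th)
        if defined.sum() < 2:
            continue
        th_c = np.interp(centers, tt[defined], np.unwrap(th[defined]))
        inside = (centers >= tt[defined][0]) & (centers <= tt[defined][-1])
        X_rows.append(R[:, inside].T)
        th_rows.append(np.mod(th_c[inside], 2 * np.pi))
        fold.append(np.full(inside.sum(), fi))
    X = np.vstack(X_rows)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    X = (X - mu) / np.where(sd > 0, sd, 1.0)
    return X, np.concatenate(th_rows), np.concatenate(fold)


def _fit_predict(Xtr, th_tr, Xte):
    A = np.column_stack([Xtr, np.ones(len(Xtr))])
    Y = np.column_stack([np.sin(th_tr), np.cos(th_tr)])
    W, *_ = np.linalg.lstsq(A, Y, rcond=None)
    P = np.column_stack([Xte, np.ones(len(Xte))]) @ W
    return np.arctan2(P[:, 0], P[:, 1])


def cross_path_phase_decoder(spikes: dict[int, np.ndarray],
                             unit_ids: list[int], t: np.ndarray,
                             theta: np.ndarray, flights_train: pd.DataFrame,
                             flights_test: pd.DataFrame) -> dict:
    """Train a sine/cosine phase regression on one path, test on another.

    Score is the circular R^2 on the test path divided by the
    within-train-path cross-validated R^2 (leave-one-flight-out folds) — the
    "normed" denominator.  Returns a dict with r2_cross, r2_within_cv and
    normed_r2 (NaN, flagged, when the denominator is <= 0).
    """
    Xtr, th_tr, fold = _phase_design(spikes, unit_ids, t, theta,
                                     flights_train)
    Xte, th_te, _ = _phase_design(spikes, unit_ids, t, theta, flights_test)
    # within-train CV by leave-one-flight-out
    r2s = []
    for f in np.unique(fold):
        tr, te = fold != f, fold == f
        if tr.sum() < 10 or te.sum() < 5:
            continue
        r2s.append(_circular_r2(th_tr[te],
                                _fit_predict(Xtr[tr], th_tr[tr], Xtr[te])))
    r2_within = float(np.mean(r2s)) if r2s else np.nan
    r2_cross = _circular_r2(th_te, _fit_predict(Xtr, th_tr, Xte))
    if not np.isfinite(r2_within) or r2_within <= 0:
        log.warning("within-path CV R^2 <= 0; normed score undefined")
        normed = np.nan
    else:
        normed = r2_cross / r2_within
    return dict(r2_cross=float(r2_cross), r2_within_cv=r2_within,
                normed_r2=normed)
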