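"""Wingbeat detection, envelopes, adaptation vectors and grouping."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from batflight import wingbeats as wbm
from conftest import jittered_oscillation


# --------------------------------------------------------------------------
# cycle detection
# --------------------------------------------------------------------------

def test_pure_tone_cycle_count_and_period():
    fs = 120.0
    t = np.arange(0, 10, 1 / fs)
    az = 1 + 2 * np.sin(2 * np.pi * 8 * t)
    table, theta = wbm.detect_wingbeats(t, az, fs)
    assert 77 <= len(table) <= 80
    # first/last cycles carry analytic-signal edge effects; interior
    # periods are exact
    assert np.allclose(table["period_ms"][1:-1], 125.0, atol=1.0)
    assert np.median(table["period_ms"]) == pytest.approx(125.0, abs=0.5)


def test_jittered_periods_recovered_within_2ms():
    t, az, flights, periods, bounds = jittered_oscillation(seed=7)
    table, _ = wbm.detect_wingbeats(t, az, 120.0, flights)
    onsets = bounds[:-1]
    n_match, errs = 0, []
    for wb in table.itertuples():
        i = int(np.argmin(np.abs(onsets - wb.onset)))
        if abs(onsets[i] - wb.onset) < 0.03:
            n_match += 1
            errs.append(abs(periods[i] * 1000 - wb.period_ms))
    assert n_match / len(periods) >= 0.99
    assert np.mean(errs) <= 2.0


def test_white_noise_yields_no_cycles():
    rng = np.random.default_rng(0)
    fs = 120.0
    t = np.arange(0, 10, 1 / fs)
    az = rng.normal(1, 0.05, len(t))
    with pytest.warns(UserWarning, match="no coherent"):
        table, _ = wbm.detect_wingbeats(t, az, fs)
    assert len(table) == 0


def test_short_flight_warns_and_is_skipped():
    fs = 120.0
    t = np.arange(0, 2, 1 / fs)
    az = 1 + 2 * np.sin(2 * np.pi * 8 * t)
    flights = pd.DataFrame([dict(flight_id=0, start=0.0, end=0.3)])
    with pytest.warns(UserWarning):
        table, _ = wbm.detect_wingbeats(t, az, fs, flights)
    assert len(table) == 0


def test_phase_monotone_and_cycle_count(detected):
    """Phase increases within cycles (wrapping), count matches phase range."""
    table, theta = detected
    ok = ~np.isnan(theta)
    idx = np.flatnonzero(ok)
    jumps = np.diff(theta[idx])
    frac_increasing = np.mean((jumps > 0) | (jumps < -np.pi))
    assert frac_increasing > 0.99
    # per flight, the number of accepted cycles matches the unwrapped span
    for fid, sub in table.groupby("flight_id"):
        span_cycles = (sub["offset"].max() - sub["onset"].min()) \
            / (sub["period_ms"].mean() / 1000.0)
        assert abs(len(sub) - span_cycles) <= 1 + 0.05 * len(sub)


# --------------------------------------------------------------------------
# period statistics
# --------------------------------------------------------------------------

@pytest.mark.parametrize("periods,median,iqr", [
    (np.full(50, 125.0), 125.0, 0.0),
    (np.array([120.0, 125.0, 130.0]), 125.0, 5.0),
])
def test_period_statistics_known_values(periods, median, iqr):
    table = pd.DataFrame(dict(period_ms=periods))
    stats = wbm.period_statistics(table)
    assert stats["median_ms"] == pytest.approx(median)
    assert stats["iqr_ms"] == pytest.approx(iqr)


def test_period_statistics_against_sort_oracle():
    rng = np.random.default_rng(1)
    p = 125 + 3 * rng.standard_normal(1000)
    stats = wbm.period_statistics(pd.DataFrame(dict(period_ms=p)))
    srt = np.sort(p)
    med = 0.5 * (srt[499] + srt[500])
    assert stats["median_ms"] == pytest.approx(med)
    q25, q75 = np.percentile(p, [25, 75])
    assert stats["iqr_ms"] == pytest.approx(q75 - q25)


# --------------------------------------------------------------------------
# envelopes & asymmetry
# --------------------------------------------------------------------------

def _tone_table(fs=120.0, dur=10.0, f0=8.0):
    t = np.arange(0, dur, 1 / fs)
    az = 1 + 2 * np.sin(2 * np.pi * f0 * t)
    table, _ = wbm.detect_wingbeats(t, az, fs)
    return t, table


def test_constant_amplitude_envelopes():
    t, table = _tone_table()
    disp = 0.08 * np.sin(2 * np.pi * 8 * t)
    env, _ = wbm.extract_envelopes(t, disp, table)
    assert np.allclose(env["upper"], 0.08, atol=1e-3)
    assert np.allclose(env["lower"], -0.08, atol=1e-3)


def test_amplitude_step_doubles_envelope():
    t, table = _tone_table()
    amp = np.where(t < 5.0, 0.05, 0.10)
    disp = amp * np.sin(2 * np.pi * 8 * t)
    env, _ = wbm.extract_envelopes(t, disp, table)
    centers = 0.5 * (table["onset"] + table["offset"])
    early = env["upper"][(centers < 4.5).to_numpy()]
    late = env["upper"][(centers > 5.5).to_numpy()]
    assert np.allclose(late.mean() / early.mean(), 2.0, rtol=0.02)


def test_envelope_scaling_commutes():
    t, table = _tone_table()
    rng = np.random.default_rng(0)
    disp = np.sin(2 * np.pi * 8 * t) * (1 + 0.3 * np.sin(0.5 * t))
    e1, _ = wbm.extract_envelopes(t, disp, table)
    e2, _ = wbm.extract_envelopes(t, 3.0 * disp, table)
    assert np.allclose(e2["upper"], 3.0 * e1["upper"], atol=1e-12)
    assert np.allclose(e2["lower"], 3.0 * e1["lower"], atol=1e-12)


def test_masked_cycle_gives_nan_envelope():
    t, table = _tone_table()
    disp = 0.08 * np.sin(2 * np.pi * 8 * t)
    wb = table.iloc[10]
    disp[(t >= wb["onset"]) & (t < wb["offset"])] = np.nan
    env, _ = wbm.extract_envelopes(t, disp, table)
    assert np.isnan(env["upper"].iloc[10])
    assert np.isfinite(env["upper"].iloc[11])


def test_planted_envelope_recovered(session_and_truth, detected):
    """Extracted wrist envelope tracks the planted A(t) at r > 0.95."""
    session, gt = session_and_truth
    table, _ = detected
    iw = session.keypoint_names.index("wrist_L")
    env, _ = wbm.extract_envelopes(session.t, session.keypoints[:, iw, 2],
                                   table)
    planted = []
    for wb in table.itertuples():
        sel = (session.t >= wb.onset) & (session.t < wb.offset)
        planted.append(
            (1 + gt.envelope_gain * gt.norm_angvel[sel]).mean())
    ok = ~env["upper"].isna().to_numpy()
    r = np.corrcoef(env["upper"][ok], np.asarray(planted)[ok])[0, 1]
    assert r > 0.95


def test_asymmetry_antisymmetric_and_zero_for_symmetric():
    t, table = _tone_table()
    disp = 0.08 * np.sin(2 * np.pi * 8 * t)
    env, _ = wbm.extract_envelopes(t, disp, table)
    asym = wbm.left_right_asymmetry(env, env)
    assert np.allclose(asym["upper"], 0.0)
    env2 = env.copy()
    env2["upper"] = env2["upper"] * 1.5
    a12 = wbm.left_right_asymmetry(env, env2)
    a21 = wbm.left_right_asymmetry(env2, env)
    assert np.allclose(a12["upper"], -a21["upper"])


def test_planted_turn_asymmetry_sign(session_and_truth, detected):
    """Right-minus-left wrist envelope keeps one sign through a left turn."""
    session, gt = session_and_truth
    table, _ = detected
    iL = session.keypoint_names.index("wrist_L")
    iR = session.keypoint_names.index("wrist_R")
    eL, _ = wbm.extract_envelopes(session.t, session.keypoints[:, iL, 2],
                                  table)
    eR, _ = wbm.extract_envelopes(session.t, session.keypoints[:, iR, 2],
                                  table)
    asym = wbm.left_right_asymmetry(eL, eR)
    turn = []
    for wb in table.itertuples():
        sel = (session.t >= wb.onset) & (session.t < wb.offset)
        turn.append(gt.norm_angvel[sel].mean())
    strong = np.asarray(turn) > 0.6
    assert strong.sum() >= 5
    assert np.mean(asym["upper"][strong] < 0) > 0.9


# --------------------------------------------------------------------------
# adaptation vectors & similarity
# --------------------------------------------------------------------------

def _vec_df(V, flight_id=0):
    n, d = V.shape
    df = pd.DataFrame(V, columns=[f"v{i}" for i in range(d)])
    df.insert(0, "ordinal", np.arange(n))
    df.insert(0, "flight_id", flight_id)
    df.insert(0, "wingbeat_id", np.arange(n))
    return df


def test_similarity_curve_identical_vectors():
    V = np.tile([1.0, 2.0, 3.0], (10, 1))
    curve = wbm.adaptation_similarity_curve(_vec_df(V), max_lag=5)
    assert np.allclose(curve, 1.0)


def test_similarity_curve_orthogonal_consecutive():
    V = np.zeros((6, 6))
    V[np.arange(6), np.arange(6)] = 1.0
    curve = wbm.adaptation_similarity_curve(_vec_df(V), max_lag=2)
    assert curve[0] == pytest.approx(1.0)
    assert curve[1] == pytest.approx(0.0, abs=1e-12)


def test_similarity_curve_dot_product_oracle():
    V = np.array([[1.0, 1.0, 0.0], [1.0, 0.0, 0.0]])
    curve = wbm.adaptation_similarity_curve(_vec_df(V), max_lag=1)
    assert curve[1] == pytest.approx(1 / np.sqrt(2))


# --------------------------------------------------------------------------
# grouping
# --------------------------------------------------------------------------

def _session_vectors(session, gt, table):
    iL = session.keypoint_names.index("wrist_L")
    iR = session.keypoint_names.index("wrist_R")
    eL, _ = wbm.extract_envelopes(session.t, session.keypoints[:, iL, 2],
                                  table)
    eR, _ = wbm.extract_envelopes(session.t, session.keypoints[:, iR, 2],
                                  table)
    asym = wbm.left_right_asymmetry(eL, eR)
    return wbm.adaptation_vectors({"wrist_L": eL, "wrist_R": eR},
                                  {"wrist": asym}, table)


def test_grouping_recovers_ordinals(session_and_truth, detected):
    session, gt = session_and_truth
    table, _ = detected
    vecs = _session_vectors(session, gt, table)
    sub = table[table["path"] == 0]
    labels, score = wbm.group_wingbeats(
        sub, vecs[vecs["wingbeat_id"].isin(sub["wingbeat_id"])])
    assert adjusted_rand_score(sub["ordinal"], labels) >= 0.9
    assert score >= 0.99


def test_single_flight_groups_are_ordinals():
    V = np.random.default_rng(0).standard_normal((12, 3))
    df = _vec_df(V)
    table = pd.DataFrame(dict(wingbeat_id=np.arange(12), flight_id=0,
                              ordinal=np.arange(12),
                              onset=np.arange(12) * 0.125,
                              offset=(np.arange(12) + 1) * 0.125))
    labels, score = wbm.group_wingbeats(table, df, n_groups=12)
    assert np.array_equal(labels, np.arange(12))
    assert score == 1.0


def test_shuffled_features_destroy_order(session_and_truth, detected):
    session, gt = session_and_truth
    table, _ = detected
    vecs = _session_vectors(session, gt, table)
    sub = table[table["path"] == 0].reset_index(drop=True)
    v = vecs[vecs["wingbeat_id"].isin(sub["wingbeat_id"])] \
        .reset_index(drop=True)
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(v))
    cols = [c for c in v.columns
            if c not in ("wingbeat_id", "flight_id", "ordinal")]
    v_shuf = v.copy()
    v_shuf[cols] = v[cols].to_numpy()[perm]
    # also shuffle the ordinal/flight identity so no ordering cue remains
    v_shuf["ordinal"] = v["ordinal"].to_numpy()[perm]
    sub_shuf = sub.copy()
    sub_shuf["ordinal"] = sub["ordinal"].to_numpy()[perm]
    labels, score = wbm.group_wingbeats(sub_shuf, v_shuf)
    ari = adjusted_rand_score(sub["ordinal"], labels)
    assert ari < 0.2


def test_too_many_groups_raises():
    V = np.zeros((5, 2))
    table = pd.DataFrame(dict(wingbeat_id=np.arange(5), flight_id=0,
                              ordinal=np.arange(5),
                              onset=np.arange(5.0), offset=np.arange(5.0) + 1))
    with pytest.raises(ValueError):
        wbm.group_wingbeats(table, _vec_df(V), n_groups=10)
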