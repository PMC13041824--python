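"""Permutation tests, circular statistics, sparsity and phase decoding."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from batflight.core import bh_fdr, permutation_pvalue, resultant_vector
from batflight import unitstats as us


# --------------------------------------------------------------------------
# BH step-up vs brute force
# --------------------------------------------------------------------------

def _bh_bruteforce(p, q):
    """Textbook step-up: find the largest k with p_(k) <= k q / m, reject
    the k smallest p-values."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_star = k
    reject = np.zeros(m, bool)
    reject[order[:k_star]] = True
    return reject


@settings(max_examples=200, derandomize=True, deadline=None)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                max_size=10),
       st.sampled_from([0.01, 0.05, 0.1, 0.25]))
def test_bh_matches_bruteforce(pvals, q):
    p = np.asarray(pvals)
    assert np.array_equal(bh_fdr(p, q), _bh_bruteforce(p, q))


def test_bh_handles_nan():
    p = np.array([0.001, np.nan, 0.5])
    rej = bh_fdr(p, 0.05)
    assert rej[0] and not rej[1] and not rej[2]


# --------------------------------------------------------------------------
# RVL
# --------------------------------------------------------------------------

def test_rvl_known_values():
    rvl, pref = resultant_vector(np.full(10, 1.3))
    assert rvl == pytest.approx(1.0)
    assert pref == pytest.approx(1.3)
    rvl, _ = resultant_vector(np.array([0, np.pi / 2, np.pi, 3 * np.pi / 2]))
    assert rvl == pytest.approx(0.0, abs=1e-12)
    rvl, pref = resultant_vector(np.array([0.0, 0.0, np.pi / 2]))
    assert rvl == pytest.approx(np.sqrt(5) / 3)
    assert pref == pytest.approx(np.arctan2(1, 2))


def test_rvl_against_pingouin():
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(0)
    for _ in range(5):
        ph = rng.uniform(0, 2 * np.pi, 50)
        rvl, _ = resultant_vector(ph)
        assert rvl == pytest.approx(float(pingouin.circ_r(ph)), abs=1e-12)


def test_rvl_converges_to_bessel_ratio():
    from scipy.special import i0, i1
    rng = np.random.default_rng(1)
    for kappa in (1.0, 4.0):
        ph = rng.vonmises(0.7, kappa, 10_000)
        rvl, _ = resultant_vector(ph)
        assert abs(rvl - i1(kappa) / i0(kappa)) < 0.02


@settings(max_examples=50, derandomize=True, deadline=None)
@given(st.floats(min_value=-np.pi, max_value=np.pi))
def test_rvl_rotation_invariance(offset):
    rng = np.random.default_rng(2)
    ph = rng.uniform(0, 2 * np.pi, 40)
    r1, _ = resultant_vector(ph)
    r2, _ = resultant_vector(np.mod(ph + offset, 2 * np.pi))
    assert r1 == pytest.approx(r2, abs=1e-9)


# --------------------------------------------------------------------------
# permutation p-value convention
# --------------------------------------------------------------------------

@settings(max_examples=50, derandomize=True, deadline=None)
@given(st.integers(min_value=1, max_value=500))
def test_pvalue_floor(n):
    null = np.zeros(n)
    p = permutation_pvalue(1.0, null)
    assert p >= 1 / (1 + n)
    assert permutation_pvalue(-1.0, null) == pytest.approx(1.0)


# --------------------------------------------------------------------------
# flight modulation test
# --------------------------------------------------------------------------

def _flights(n=6, dur=2.5, gap=3.0):
    starts = gap * np.arange(n)
    return pd.DataFrame(dict(flight_id=np.arange(n), start=starts,
                             end=starts + dur, path=0))


def test_modulation_detects_repeated_pattern():
    fls = _flights()
    spikes = np.concatenate([fl.start + np.array([0.4, 0.41, 1.2, 1.21])
                             for fl in fls.itertuples()])
    p = us.flight_modulation_test(np.sort(spikes), fls, n_shuffles=200,
                                  rng=np.random.default_rng(0))
    assert p == pytest.approx(1 / 201)


def test_modulation_silent_unit_p_one():
    assert us.flight_modulation_test(np.array([]), _flights(),
                                     n_shuffles=50) == 1.0


def test_modulation_statistic_invariant_to_common_shift():
    fls = _flights()
    rng = np.random.default_rng(3)
    base = np.sort(rng.uniform(0, 2.5, 40))
    sp1 = np.sort(np.concatenate([fl.start + base
                                  for fl in fls.itertuples()]))
    sp2 = np.sort(np.concatenate([fl.start + np.mod(base + 0.7, 2.5)
                                  for fl in fls.itertuples()]))
    tr1 = us._flight_rate_traces([base] * 6, np.full(6, 2.5))
    tr2 = us._flight_rate_traces([np.mod(base + 0.7, 2.5)] * 6,
                                 np.full(6, 2.5))
    assert us._mean_pairwise_corr(tr1) == pytest.approx(
        us._mean_pairwise_corr(tr2), abs=0.05)


def test_modulation_requires_three_flights():
    with pytest.raises(ValueError):
        us.flight_modulation_test(np.array([1.0]), _flights(n=2))


# --------------------------------------------------------------------------
# silent wingbeats
# --------------------------------------------------------------------------

def test_silent_wingbeat_fraction_cases():
    table = pd.DataFrame(dict(onset=np.arange(10.0),
                              offset=np.arange(10.0) + 0.9))
    every = np.arange(10) + 0.5
    assert us.silent_wingbeat_fraction(every, table) == 0.0
    assert us.silent_wingbeat_fraction(np.array([]), table) == 1.0
    three = np.array([0.5, 3.5, 7.5])
    assert us.silent_wingbeat_fraction(three, table) == pytest.approx(0.7)


# --------------------------------------------------------------------------
# phase locking test
# --------------------------------------------------------------------------

def test_phase_test_type_one_and_power():
    rng = np.random.default_rng(4)
    # uniform-phase unit: p roughly uniform, locked unit: p at floor
    uni = [rng.uniform(0, 2 * np.pi, 30) for _ in range(5)]
    locked = [np.mod(rng.vonmises(1.0, 4.0, 30), 2 * np.pi)
              for _ in range(5)]
    p_uni = us.phase_locking_test(uni, 200, np.random.default_rng(0))
    p_lock = us.phase_locking_test(locked, 200, np.random.default_rng(0))
    assert p_lock == pytest.approx(1 / 201)
    assert p_uni > 0.05


def test_phase_table_flags_and_fdr(session_and_truth, detected):
    session, gt = session_and_truth
    table, theta = detected
    ph = us.phase_locking_table(session.spikes, session.t, theta,
                                gt.flights, n_shuffles=100, seed=0)
    tested = ph[ph["tested"]]
    by_class = {}
    for row in tested.itertuples():
        cls = gt.units[int(row.unit_id)].unit_class
        by_class.setdefault(cls, []).append(row.sig)
    assert np.mean(by_class["tonic_phase_locked"]) >= 0.95
    assert np.mean(by_class["unmodulated"]) <= 0.15
    # excluded units flagged, not tested
    assert (~ph["tested"] == ph["p"].isna()).all()


# --------------------------------------------------------------------------
# sliding raster
# --------------------------------------------------------------------------

def _uniform_table(n_flights=4, n_cycles=10):
    rows = []
    wid = 0
    for f in range(n_flights):
        t0 = 5.0 * f
        for o in range(n_cycles):
            rows.append(dict(wingbeat_id=wid, flight_id=f,
                             onset=t0 + 0.125 * o, offset=t0 + 0.125 * (o + 1),
                             ordinal=o))
            wid += 1
    return pd.DataFrame(rows)


def test_sliding_raster_constant_rate_flat():
    table = _uniform_table()
    # exactly one spike in every cycle: constant rate, flat zero after
    # z-scoring
    spikes = {0: np.sort(table["onset"].to_numpy() + 0.06)}
    out = us.sliding_phase_raster(spikes, table, [0], window=5, overlap=4)
    assert np.allclose(out, 0.0)


def test_sliding_raster_window_equals_path():
    table = _uniform_table()
    spikes = {0: np.array([0.1, 5.1, 10.1, 15.1])}
    out = us.sliding_phase_raster(spikes, table, [0], window=10, overlap=9)
    assert out.shape == (1, 1)


def test_sliding_raster_peak_at_selective_group():
    table = _uniform_table()
    # unit fires only on ordinal 6 of every flight
    spikes = {0: np.sort(np.array([5.0 * f + 0.125 * 6 + 0.06
                                   for f in range(4)]))}
    out = us.sliding_phase_raster(spikes, table, [0], window=3, overlap=2)
    # windows start at ordinals 0..7; ordinal 6 lies in windows 4,5,6
    assert int(np.argmax(out[0])) in (4, 5, 6)
    with pytest.raises(ValueError):
        us.sliding_phase_raster(spikes, table, [0], window=11, overlap=10)


# --------------------------------------------------------------------------
# cross-path phase decoding
# --------------------------------------------------------------------------

@pytest.fixture(scope="module")
def tonic_units(session_and_truth):
    _, gt = session_and_truth
    return [u for u, s in enumerate(gt.units)
            if s.unit_class == "tonic_phase_locked"]


def test_phase_decoder_transfers_across_paths(session_and_truth, detected,
                                              tonic_units):
    session, gt = session_and_truth
    _, theta = detected
    fl0 = gt.flights[gt.flights["path"] == 0]
    fl1 = gt.flights[gt.flights["path"] == 1]
    res = us.cross_path_phase_decoder(session.spikes, tonic_units,
                                      session.t, theta, fl0, fl1)
    assert res["normed_r2"] >= 0.8
    # within-path CV against itself is ~1 by construction
    res_self = us.cross_path_phase_decoder(session.spikes, tonic_units,
                                           session.t, theta, fl0, fl0)
    assert res_self["normed_r2"] == pytest.approx(1.0, abs=0.15)


def test_phase_decoder_shuffled_units_fail(session_and_truth, detected,
                                           tonic_units):
    session, gt = session_and_truth
    _, theta = detected
    fl0 = gt.flights[gt.flights["path"] == 0]
    fl1 = gt.flights[gt.flights["path"] == 1]
    # derangement (cyclic shift): every unit receives a different unit's
    # test-path spikes
    perm = dict(zip(tonic_units, np.roll(tonic_units, 1)))
    shuffled = {}
    for u in tonic_units:
        keep, donor = session.spikes[u], session.spikes[perm[u]]
        km = np.zeros(len(keep), bool)
        dm = np.zeros(len(donor), bool)
        for fl in fl1.itertuples():
            km |= (keep >= fl.start) & (keep < fl.end)
            dm |= (donor >= fl.start) & (donor < fl.end)
        shuffled[u] = np.sort(np.concatenate([keep[~km], donor[dm]]))
    res = us.cross_path_phase_decoder(shuffled, tonic_units, session.t,
                                      theta, fl0, fl1)
    assert res["r2_cross"] < 0.2
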